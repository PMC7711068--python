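"""Node-, edge- and network-level topological metrics for AANetworks.

Conventions (recorded in every report's metadata because the literature
uses several):

* betweenness and edge betweenness are **unnormalised** shortest-path
  counts (each unordered source–target pair counted once);
* closeness of node v is ``(number of nodes reachable from v) / (sum of
  shortest-path distances from v)`` — an unnormalised 1/average-distance
  form; isolated nodes get 0;
* transitivity is the local clustering coefficient (0 for degree < 2);
* disconnected graphs are handled component-wise: closeness, average
  shortest-path length and L_net run over reachable pairs only, and the
  diameter is the largest finite eccentricity;
* EACEN edge weights are coupling strengths, so path computations use
  length = 1/weight (strong links are short); the network-level diameter
  is always reported in hops so it stays an integer comparable across
  model types;
* node-weighted (NACEN) betweenness/closeness traverse edges with length
  ``(w_i + w_j)/2``; weighted degree of i is the sum of its neighbours'
  weights. Node weights must be strictly positive for the path metrics.
"""

from __future__ import annotations

from typing import Optional

import networkx as nx
import pandas as pd

from .errors import ContractViolation, EmptyNetworkError
from .network_build import AANetwork, DEFAULT_LR_SEP

__all__ = [
    "to_networkx",
    "node_metrics",
    "node_weighted_metrics",
    "edge_metrics",
    "network_metrics",
    "metrics_report",
    "MetricsReport",
]

#: Conventions propagated into run logs alongside results.
CONVENTIONS = {
    "betweenness": "unnormalized shortest-path betweenness",
    "closeness": "reachable-count / sum-of-distances (component-wise)",
    "eacen_path_length": "1/w (edge weight treated as coupling strength)",
    "node_weighted_length": "(w_i + w_j)/2 per traversed edge",
    "diameter": "max finite eccentricity, hop distances",
}


def to_networkx(net: AANetwork, *, lengths: str = "model") -> nx.Graph:
    """AANetwork -> networkx Graph with a ``length`` attribute per edge.

    ``lengths="model"`` applies the model's convention (1/w for EACEN,
    1 otherwise); ``"hop"`` forces unit lengths; ``"node_weight"`` uses
    the NACEN transform (w_i + w_j)/2.
    """
    g = nx.Graph()
    for node in net.nodes:
        g.add_node(node.node_id)
    for e in net.edges:
        if lengths == "node_weight":
            wi = net.node_weights[e.node_i]
            wj = net.node_weights[e.node_j]
            length = (wi + wj) / 2.0
        elif lengths == "model" and net.model_type == "EACEN":
            length = 1.0 / e.weight
        else:
            length = 1.0
        g.add_edge(e.node_i, e.node_j, weight=e.weight, length=length)
    return g


def _weight_arg(net: AANetwork, lengths: str) -> Optional[str]:
    """'length' when path metrics must honour edge lengths, else None."""
    if lengths == "node_weight":
        return "length"
    if lengths == "model" and net.model_type == "EACEN":
        return "length"
    return None


def _closeness_and_avg_path(g: nx.Graph, weight: Optional[str]):
    closeness, avg_path = {}, {}
    for v in g.nodes:
        if weight is None:
            dist = nx.single_source_shortest_path_length(g, v)
        else:
            dist = nx.single_source_dijkstra_path_length(g, v,
                                                         weight=weight)
        dist.pop(v, None)
        total = sum(dist.values())
        reach = len(dist)
        closeness[v] = reach / total if total > 0 else 0.0
        avg_path[v] = total / reach if reach else 0.0
    return closeness, avg_path


def node_metrics(net: AANetwork) -> pd.DataFrame:
    """Per-node degree, betweenness, closeness, transitivity and average
    shortest-path length; one row per node, in node order."""
    if net.n == 0:
        raise EmptyNetworkError("cannot compute metrics on an empty network")
    g = to_networkx(net)
    weight = _weight_arg(net, "model")
    betw = nx.betweenness_centrality(g, normalized=False, weight=weight)
    closeness, avg_path = _closeness_and_avg_path(g, weight)
    clust = nx.clustering(g)  # structural (unweighted) neighbourhoods
    rows = []
    for node in net.nodes:
        v = node.node_id
        rows.append({
            "node_id": v,
            "label": node.label,
            "chain": node.chain_id,
            "seq_pos": node.seq_pos,
            "node_kind": node.node_kind,
            "ss_state": node.ss_state or "",
            "degree": g.degree(v),
            "betweenness": betw[v],
            "closeness": closeness[v],
            "transitivity": clust[v],
            "avg_shortest_path": avg_path[v],
        })
    return pd.DataFrame(rows)


def node_weighted_metrics(net: AANetwork) -> pd.DataFrame:
    """Node-weighted degree/betweenness/closeness for a NACEN.

    Weighted degree sums the neighbours' node weights; betweenness and
    closeness run over edge lengths (w_i + w_j)/2, which requires every
    node weight to be strictly positive and finite.
    """
    if net.model_type != "NACEN" or not net.node_weights:
        raise ContractViolation(
            "node-weighted metrics require a NACEN with node weights"
        )
    bad = [k for k, w in net.node_weights.items()
           if not (w is not None and w > 0 and w == w and abs(w) != float("inf"))]
    if bad:
        raise ContractViolation(
            "node-weighted path metrics need strictly positive finite "
            f"weights; offending nodes: {bad[:5]}"
        )
    g = to_networkx(net, lengths="node_weight")
    betw = nx.betweenness_centrality(g, normalized=False, weight="length")
    closeness, _ = _closeness_and_avg_path(g, "length")
    rows = []
    for node in net.nodes:
        v = node.node_id
        wdeg = sum(net.node_weights[u] for u in g.neighbors(v))
        rows.append({
            "node_id": v,
            "weighted_degree": wdeg,
            "weighted_betweenness": betw[v],
            "weighted_closeness": closeness[v],
        })
    return pd.DataFrame(rows)


def edge_metrics(net: AANetwork, lr_sep: int = DEFAULT_LR_SEP) -> pd.DataFrame:
    """Per-edge shortest-path betweenness and the long-range label.

    An edge is long-range when its endpoints sit in different chains (or
    molecules), or are amino acids of the same chain separated by at
    least ``lr_sep`` positions.
    """
    if net.n == 0:
        raise EmptyNetworkError("cannot compute metrics on an empty network")
    g = to_networkx(net)
    weight = _weight_arg(net, "model")
    ebc = nx.edge_betweenness_centrality(g, normalized=False, weight=weight)
    rows = []
    for e in net.edges:
        a, b = net.node(e.node_i), net.node(e.node_j)
        if a.chain_id != b.chain_id:
            lr = True
        elif a.node_kind == "amino_acid" and b.node_kind == "amino_acid":
            lr = abs(a.seq_pos - b.seq_pos) >= lr_sep
        else:
            lr = False
        key = (e.node_i, e.node_j)
        rows.append({
            "node_i": e.node_i,
            "node_j": e.node_j,
            "weight": e.weight,
            "edge_betweenness": ebc.get(key, ebc.get(key[::-1], 0.0)),
            "long_range": lr,
        })
    return pd.DataFrame(rows)


def network_metrics(net: AANetwork) -> pd.DataFrame:
    """One-row summary: n, m, L_net, density, diameter.

    L_net is the mean shortest-path length over connected node pairs
    (model path lengths, so EACEN averages 1/w distances); density is
    2m/(n(n-1)); the diameter is the largest finite hop eccentricity.
    """
    if net.n == 0:
        raise EmptyNetworkError("cannot compute metrics on an empty network")
    g = to_networkx(net)
    weight = _weight_arg(net, "model")
    total, pairs = 0.0, 0
    diameter = 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if sub.number_of_nodes() < 2:
            continue
        if weight is None:
            dists = dict(nx.all_pairs_shortest_path_length(sub))
        else:
            dists = dict(nx.all_pairs_dijkstra_path_length(sub,
                                                           weight=weight))
        hop = dict(nx.all_pairs_shortest_path_length(sub))
        for v, dmap in dists.items():
            for u, d in dmap.items():
                if u != v:
                    total += d
                    pairs += 1
        diameter = max(
            diameter,
            max(d for dmap in hop.values() for d in dmap.values()),
        )
    l_net = total / pairs if pairs else 0.0
    density = 2.0 * net.m / (net.n * (net.n - 1)) if net.n > 1 else 0.0
    return pd.DataFrame([{
        "structure_id": net.meta.get("structure_id", ""),
        "model_type": net.model_type,
        "n": net.n,
        "m": net.m,
        "L_net": l_net,
        "density": density,
        "diameter": int(diameter),
    }])


class MetricsReport:
    """Node, edge and network metric tables for one network."""

    def __init__(self, net: AANetwork, lr_sep: int = DEFAULT_LR_SEP):
        self.network = net
        self.node_table = node_metrics(net)
        if net.model_type == "NACEN" and net.node_weights:
            weighted = node_weighted_metrics(net)
            self.node_table = self.node_table.merge(weighted, on="node_id")
        self.edge_table = edge_metrics(net, lr_sep=lr_sep)
        self.network_row = network_metrics(net)
        self.conventions = dict(CONVENTIONS)

    def top_nodes(self, by: str, k: int = 10) -> pd.DataFrame:
        """Nodes sorted descending by a node-table column (ties broken by
        node order for determinism)."""
        if by not in self.node_table.columns:
            raise ContractViolation(f"no node metric named {by!r}")
        return (
            self.node_table
            .sort_values([by, "node_id"], ascending=[False, True],
                         kind="mergesort")
            .head(k)
            .reset_index(drop=True)
        )


def metrics_report(net: AANetwork, lr_sep: int = DEFAULT_LR_SEP) -> MetricsReport:
    return MetricsReport(net, lr_sep=lr_sep)
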