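"""Brute-force graph-metric oracle.

Pure-Python reference implementation used only by the tests: Floyd–Warshall
distances plus explicit enumeration of *all* shortest paths per node pair.
Deliberately independent of networkx (and of the package under test) so it
can arbitrate centrality conventions:

* betweenness / edge betweenness: unnormalised, each unordered reachable
  pair counted once, fractional credit per shortest path;
* closeness(v): reachable-node count / sum of distances (0 if isolated);
* transitivity: local clustering coefficient;
* L_net: mean distance over connected pairs; diameter: max finite
  eccentricity (hops).
"""

from __future__ import annotations

import math
from itertools import combinations

_EPS = 1e-12


class BruteGraph:
    """Undirected graph with optional per-edge lengths."""

    def __init__(self, n_nodes, edges, lengths=None):
        self.nodes = list(range(n_nodes))
        self.edges = [tuple(sorted(e)) for e in edges]
        self.lengths = {}
        for idx, (a, b) in enumerate(self.edges):
            l = 1.0 if lengths is None else float(lengths[idx])
            self.lengths[(a, b)] = l
            self.lengths[(b, a)] = l
        self.adj = {v: set() for v in self.nodes}
        for a, b in self.edges:
            self.adj[a].add(b)
            self.adj[b].add(a)
        self._dist = self._floyd_warshall()

    def _floyd_warshall(self):
        n = len(self.nodes)
        d = [[math.inf] * n for _ in range(n)]
        for v in self.nodes:
            d[v][v] = 0.0
        for (a, b), l in self.lengths.items():
            if l < d[a][b]:
                d[a][b] = d[b][a] = l
        for k in range(n):
            dk = d[k]
            for i in range(n):
                dik = d[i][k]
                if dik == math.inf:
                    continue
                di = d[i]
                for j in range(n):
                    alt = dik + dk[j]
                    if alt < di[j]:
                        di[j] = alt
        return d

    def dist(self, s, t):
        return self._dist[s][t]

    def all_shortest_paths(self, s, t):
        """Every shortest s→t path, as node tuples (DFS on distances)."""
        if self._dist[s][t] == math.inf:
            return []
        paths = []

        def extend(prefix, v):
            if v == t:
                paths.append(tuple(prefix))
                return
            for u in self.adj[v]:
                if abs(self._dist[s][v] + self.lengths[(v, u)]
                       + self._dist[u][t] - self._dist[s][t]) < _EPS:
                    extend(prefix + [u], u)

        extend([s], s)
        return paths

    # -- metrics -----------------------------------------------------------

    def betweenness(self):
        b = {v: 0.0 for v in self.nodes}
        for s, t in combinations(self.nodes, 2):
            paths = self.all_shortest_paths(s, t)
            if not paths:
                continue
            for p in paths:
                for v in p[1:-1]:
                    b[v] += 1.0 / len(paths)
        return b

    def edge_betweenness(self):
        eb = {e: 0.0 for e in self.edges}
        for s, t in combinations(self.nodes, 2):
            paths = self.all_shortest_paths(s, t)
            if not paths:
                continue
            for p in paths:
                for a, bnode in zip(p, p[1:]):
                    eb[tuple(sorted((a, bnode)))] += 1.0 / len(paths)
        return eb

    def closeness(self):
        out = {}
        for v in self.nodes:
            ds = [self._dist[v][u] for u in self.nodes
                  if u != v and self._dist[v][u] < math.inf]
            out[v] = len(ds) / sum(ds) if ds and sum(ds) > 0 else 0.0
        return out

    def avg_shortest_path(self):
        out = {}
        for v in self.nodes:
            ds = [self._dist[v][u] for u in self.nodes
                  if u != v and self._dist[v][u] < math.inf]
            out[v] = sum(ds) / len(ds) if ds else 0.0
        return out

    def degree(self):
        return {v: len(self.adj[v]) for v in self.nodes}

    def clustering(self):
        out = {}
        for v in self.nodes:
            k = len(self.adj[v])
            if k < 2:
                out[v] = 0.0
                continue
            links = sum(
                1 for a, b in combinations(sorted(self.adj[v]), 2)
                if b in self.adj[a]
            )
            out[v] = 2.0 * links / (k * (k - 1))
        return out

    def l_net(self):
        ds = [self._dist[s][t] for s, t in combinations(self.nodes, 2)
              if self._dist[s][t] < math.inf]
        return sum(ds) / len(ds) if ds else 0.0

    def density(self):
        n = len(self.nodes)
        return 2.0 * len(self.edges) / (n * (n - 1)) if n > 1 else 0.0

    def diameter_hops(self):
        hop = BruteGraph(len(self.nodes), self.edges)._dist \
            if self.lengths and any(l != 1.0 for l in self.lengths.values()) \
            else self._dist
        finite = [hop[s][t] for s, t in combinations(self.nodes, 2)
                  if hop[s][t] < math.inf]
        return int(max(finite)) if finite else 0
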