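"""Builders for the four amino acid network models.

All four models share the same node/edge container, :class:`AANetwork`:

* **AACEN** — unweighted graph; an edge joins two residues in geometric
  contact whose contact energy e_ij is below the energy threshold
  (default 0, attractive contacts only).
* **NACEN** — the AACEN edge set with a numeric weight attached to every
  node (solvent accessibility, mass, hydrophobicity, polarity or custom),
  enabling node-weighted centralities.
* **EACEN** — the AACEN edge set with each edge carrying the min–max
  normalised magnitude of its contact energy: the weakest contact gets
  0.0001, the strongest gets 1, the rest interpolate linearly in |e_ij|.
* **C-alpha** — pure distance-threshold graph on C-alpha atoms; in
  protein–DNA/RNA complexes each nucleotide contributes up to three nodes
  (P, C4* sugar, C2 base), so nucleic chains enter the graph alongside
  protein residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .energy import EnergyTable, candidate_contacts, contact_energy
from .errors import ContractViolation, EmptyNetworkError
from .structure_io import (
    NodeWeightSpec,
    Residue,
    StructureModel,
    compute_node_weights,
)

__all__ = [
    "ResidueNode",
    "Edge",
    "AANetwork",
    "MIN_EDGE_WEIGHT",
    "normalize_edge_weights",
    "build_aacen",
    "build_nacen",
    "build_eacen",
    "build_calpha",
    "DEFAULT_ENERGY_CUTOFF",
    "DEFAULT_CALPHA_CUTOFF",
    "DEFAULT_LR_SEP",
]

#: Weight assigned to the edge(s) whose |e_ij| equals the network minimum.
MIN_EDGE_WEIGHT = 0.0001

DEFAULT_ENERGY_CUTOFF = 8.0   # Å, candidate-contact cutoff for energy models
DEFAULT_CALPHA_CUTOFF = 7.0   # Å, C-alpha distance network
DEFAULT_LR_SEP = 12           # sequence separation defining a long-range link

#: Sort rank of nucleotide representative atoms within one nucleotide.
_ROLE_RANK = {"": 0, "P": 0, "C4*": 1, "C2": 2}


@dataclass(frozen=True)
class ResidueNode:
    """One network node: an amino acid, or one nucleotide atom group."""

    node_id: str          # "chain:resnum[:icode][:atomrole]"
    label: str            # residue / nucleotide 3(1)-letter name
    node_kind: str        # "amino_acid" | "P" | "C4*" | "C2"
    chain_id: str
    seq_pos: int
    insertion_code: str = ""
    ss_state: Optional[str] = None
    weight: Optional[float] = None

    @property
    def sort_key(self):
        return (
            self.chain_id, self.seq_pos, self.insertion_code,
            _ROLE_RANK.get(self.node_kind if self.node_kind != "amino_acid"
                           else "", 0),
        )


@dataclass(frozen=True)
class Edge:
    node_i: str
    node_j: str
    weight: float
    long_range: bool
    energy: Optional[float] = None  # e_ij for energy-based models


@dataclass
class AANetwork:
    """Nodes + edges + adjacency for one network model instance."""

    model_type: str                   # AACEN | NACEN | EACEN | CALPHA
    nodes: list = field(default_factory=list)
    edges: list = field(default_factory=list)
    node_weights: Optional[dict] = None   # node_id -> weight (NACEN)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = sorted(self.nodes, key=lambda n: n.sort_key)
        self._pos = {n.node_id: i for i, n in enumerate(self.nodes)}
        if len(self._pos) != len(self.nodes):
            raise ContractViolation("duplicate node ids in network")
        canon = []
        seen = set()
        for e in self.edges:
            if e.node_i not in self._pos or e.node_j not in self._pos:
                raise ContractViolation(
                    f"edge ({e.node_i}, {e.node_j}) references unknown node"
                )
            if e.node_i == e.node_j:
                raise ContractViolation(f"self-loop at {e.node_i}")
            a, b = sorted((e.node_i, e.node_j), key=lambda x: self._pos[x])
            if (a, b) in seen:
                raise ContractViolation(f"duplicate edge ({a}, {b})")
            seen.add((a, b))
            canon.append(Edge(a, b, e.weight, e.long_range, e.energy))
        canon.sort(key=lambda e: (self._pos[e.node_i], self._pos[e.node_j]))
        self.edges = canon

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def m(self) -> int:
        return len(self.edges)

    def node(self, node_id: str) -> ResidueNode:
        return self.nodes[self._pos[node_id]]

    def adjacency(self) -> tuple:
        """(node_ids, symmetric zero-diagonal matrix)."""
        am = np.zeros((self.n, self.n))
        for e in self.edges:
            i, j = self._pos[e.node_i], self._pos[e.node_j]
            am[i, j] = am[j, i] = e.weight
        return [n.node_id for n in self.nodes], am


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _amino_node(res: Residue, weight: Optional[float] = None) -> ResidueNode:
    return ResidueNode(
        node_id=res.id_str, label=res.res_name, node_kind="amino_acid",
        chain_id=res.chain_id, seq_pos=res.seq_pos,
        insertion_code=res.insertion_code, ss_state=res.ss_state,
        weight=weight,
    )


def _is_long_range(a: ResidueNode, b: ResidueNode, lr_sep: int) -> bool:
    """Different chains/molecules, or far apart in one protein chain."""
    if a.chain_id != b.chain_id:
        return True
    if a.node_kind == "amino_acid" and b.node_kind == "amino_acid":
        return abs(a.seq_pos - b.seq_pos) >= lr_sep
    return False


def _energy_edges(
    model: StructureModel,
    table: EnergyTable,
    e_thresh: float,
    d_cutoff: float,
    seq_exclusion: int,
    contact_mode: str,
    lr_sep: int,
):
    """Shared AACEN/NACEN/EACEN edge rule: contact AND e_ij < e_thresh."""
    amino = [r for r in model.residues("amino_acid")]
    if not amino:
        raise EmptyNetworkError(
            f"{model.structure_id}: no amino-acid residues"
        )
    nodes = {r.id_str: _amino_node(r) for r in amino}
    contacts = candidate_contacts(
        model, d_cutoff, seq_exclusion=seq_exclusion, mode=contact_mode
    )
    kept = []
    for ri, rj in contacts:
        e_ij = contact_energy(ri, rj, table)
        if e_ij < e_thresh:
            a, b = nodes[ri.id_str], nodes[rj.id_str]
            kept.append((a.node_id, b.node_id, e_ij,
                         _is_long_range(a, b, lr_sep)))
    return list(nodes.values()), kept


def _base_meta(model, **params) -> dict:
    meta = {"structure_id": model.structure_id, "source": model.source}
    meta.update(params)
    return meta


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build_aacen(
    model: StructureModel,
    table: EnergyTable,
    e_thresh: float = 0.0,
    d_cutoff: float = DEFAULT_ENERGY_CUTOFF,
    *,
    seq_exclusion: int = 2,
    contact_mode: str = "calpha",
    lr_sep: int = DEFAULT_LR_SEP,
) -> AANetwork:
    """Amino acid contact energy network: binary adjacency, edge iff the
    residues are in geometric contact and e_ij < ``e_thresh`` (strict)."""
    nodes, kept = _energy_edges(
        model, table, e_thresh, d_cutoff, seq_exclusion, contact_mode, lr_sep
    )
    edges = [Edge(a, b, 1.0, lr, energy=e) for a, b, e, lr in kept]
    return AANetwork(
        "AACEN", nodes, edges,
        meta=_base_meta(
            model, e_thresh=e_thresh, d_cutoff=d_cutoff,
            seq_exclusion=seq_exclusion, contact_mode=contact_mode,
            lr_sep=lr_sep, energy_table=table.provenance,
        ),
    )


def build_nacen(
    model: StructureModel,
    table: EnergyTable,
    e_thresh: float = 0.0,
    d_cutoff: float = DEFAULT_ENERGY_CUTOFF,
    weight_spec: NodeWeightSpec = NodeWeightSpec("polarity"),
    *,
    seq_exclusion: int = 2,
    contact_mode: str = "calpha",
    lr_sep: int = DEFAULT_LR_SEP,
) -> AANetwork:
    """Node-weighted contact energy network: AACEN edge set, one weight
    per node taken from ``weight_spec``."""
    weights = compute_node_weights(model, weight_spec)
    nodes, kept = _energy_edges(
        model, table, e_thresh, d_cutoff, seq_exclusion, contact_mode, lr_sep
    )
    amino = {r.id_str: r for r in model.residues("amino_acid")}
    nodes = [
        ResidueNode(
            node_id=n.node_id, label=n.label, node_kind=n.node_kind,
            chain_id=n.chain_id, seq_pos=n.seq_pos,
            insertion_code=n.insertion_code, ss_state=n.ss_state,
            weight=float(weights[amino[n.node_id].key]),
        )
        for n in nodes
    ]
    edges = [Edge(a, b, 1.0, lr, energy=e) for a, b, e, lr in kept]
    net = AANetwork(
        "NACEN", nodes, edges,
        node_weights={n.node_id: n.weight for n in nodes},
        meta=_base_meta(
            model, e_thresh=e_thresh, d_cutoff=d_cutoff,
            seq_exclusion=seq_exclusion, contact_mode=contact_mode,
            lr_sep=lr_sep, energy_table=table.provenance,
            node_weight_mode=weight_spec.mode,
        ),
    )
    return net


def normalize_edge_weights(energies: Sequence[float]) -> list:
    """Min–max normalisation of edge contact energies to (0, 1] weights.

    The edge(s) whose |e| equals the minimum over the list get exactly
    ``MIN_EDGE_WEIGHT`` (0.0001); every other edge gets
    ``(|e| - |e|_min) / (|e|_max - |e|_min)``, so the strongest contact
    gets exactly 1. All energies must be strictly negative. When all
    energies are equal the range is degenerate and every edge attains the
    minimum, so all weights are 0.0001.
    """
    energies = list(energies)
    if not energies:
        raise ContractViolation("empty energy list")
    if any(e >= 0 for e in energies):
        raise ContractViolation("edge energies must be strictly negative")
    mags = [abs(e) for e in energies]
    lo, hi = min(mags), max(mags)
    if hi == lo:
        return [MIN_EDGE_WEIGHT] * len(mags)
    return [
        MIN_EDGE_WEIGHT if m == lo else (m - lo) / (hi - lo) for m in mags
    ]


def build_eacen(
    model: StructureModel,
    table: EnergyTable,
    e_thresh: float = 0.0,
    d_cutoff: float = DEFAULT_ENERGY_CUTOFF,
    *,
    seq_exclusion: int = 2,
    contact_mode: str = "calpha",
    lr_sep: int = DEFAULT_LR_SEP,
) -> AANetwork:
    """Edge-weighted contact energy network: AACEN edge set; adjacency
    entries hold the normalised |e_ij| weights instead of 1."""
    if e_thresh > 0:
        raise ContractViolation(
            "EACEN requires e_thresh <= 0: its normalisation is defined "
            "for negative edge energies only"
        )
    nodes, kept = _energy_edges(
        model, table, e_thresh, d_cutoff, seq_exclusion, contact_mode, lr_sep
    )
    weights = (
        normalize_edge_weights([e for _, _, e, _ in kept]) if kept else []
    )
    edges = [
        Edge(a, b, w, lr, energy=e)
        for (a, b, e, lr), w in zip(kept, weights)
    ]
    return AANetwork(
        "EACEN", nodes, edges,
        meta=_base_meta(
            model, e_thresh=e_thresh, d_cutoff=d_cutoff,
            seq_exclusion=seq_exclusion, contact_mode=contact_mode,
            lr_sep=lr_sep, energy_table=table.provenance,
        ),
    )


_NUCLEIC_ROLES = (("P", ("P",)), ("C4*", ("C4'", "C4*")), ("C2", ("C2",)))


def build_calpha(
    model: StructureModel,
    d_cutoff: float = DEFAULT_CALPHA_CUTOFF,
    *,
    seq_exclusion: int = 2,
    lr_sep: int = DEFAULT_LR_SEP,
) -> AANetwork:
    """C-alpha distance network, extended to protein–DNA/RNA complexes.

    Amino acids are represented by their C-alpha; each nucleotide by up to
    three nodes at its P, C4* (sugar) and C2 (base) atoms — atoms absent
    from the coordinates (e.g. the 5'-terminal phosphate) are skipped. An
    edge joins two nodes strictly closer than ``d_cutoff``. The
    sequence-adjacency exclusion applies between amino-acid nodes of the
    same chain only; nucleotide-derived nodes always link by distance.
    """
    if d_cutoff <= 0:
        raise ContractViolation("d_cutoff must be positive")
    nodes: list[ResidueNode] = []
    coords: list[np.ndarray] = []
    skipped_atoms = 0
    for res in model.residues():
        if res.kind == "amino_acid":
            if res.ca is None:
                continue
            nodes.append(_amino_node(res))
            coords.append(res.ca.xyz)
        elif res.kind == "nucleotide":
            for role, names in _NUCLEIC_ROLES:
                atom = res.atom(*names)
                if atom is None:
                    skipped_atoms += 1
                    continue
                icode = f":{res.insertion_code}" if res.insertion_code else ""
                nodes.append(ResidueNode(
                    node_id=f"{res.chain_id}:{res.seq_pos}{icode}:{role}",
                    label=res.res_name, node_kind=role,
                    chain_id=res.chain_id, seq_pos=res.seq_pos,
                    insertion_code=res.insertion_code,
                ))
                coords.append(atom.xyz)
    if not nodes:
        raise EmptyNetworkError(
            f"{model.structure_id}: no representable nodes"
        )
    edges = []
    if len(nodes) > 1:
        dmat = squareform(pdist(np.array(coords)))
        ii, jj = np.nonzero(np.triu(dmat < d_cutoff, k=1))
        for a, b in zip(ii.tolist(), jj.tolist()):
            na, nb = nodes[a], nodes[b]
            both_aa = (na.node_kind == "amino_acid"
                       and nb.node_kind == "amino_acid")
            if (both_aa and na.chain_id == nb.chain_id
                    and abs(na.seq_pos - nb.seq_pos) < seq_exclusion):
                continue
            edges.append(Edge(na.node_id, nb.node_id, 1.0,
                              _is_long_range(na, nb, lr_sep)))
    return AANetwork(
        "CALPHA", nodes, edges,
        meta=_base_meta(
            model, d_cutoff=d_cutoff, seq_exclusion=seq_exclusion,
            lr_sep=lr_sep, skipped_nucleotide_atoms=skipped_atoms,
        ),
    )
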