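"""Environment-dependent residue contact energies and candidate contacts.

The contact-energy models use a 60-letter residue alphabet: 20 amino acid
types × 3 secondary-structure states (helix H, strand E, coil C). An
:class:`EnergyTable` is the symmetric 60×60 matrix of pairwise contact
energies e_ij over that alphabet; an edge is later drawn between two
residues in contact when e_ij falls below a threshold (0 by default, i.e.
attractive contacts only).

The table is fully pluggable: any TSV with ``RES_SS``-labelled rows and
columns can be loaded, and the shipped default is a documented stand-in
(see :data:`DEFAULT_TABLE_RESOURCE`). Candidate contacts are geometric:
residue pairs whose representative atoms (C-alpha by default, or the
closest heavy-atom pair) lie within a distance cutoff, excluding
sequence-adjacent pairs in the same chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .errors import ContractViolation, LookupError_, TableValidationError
from .structure_io import AMINO_ACIDS, Residue, StructureModel

__all__ = [
    "SS_CODE",
    "EnergyTable",
    "load_energy_table",
    "contact_energy",
    "candidate_contacts",
    "DEFAULT_TABLE_RESOURCE",
]

SS_CODE = {"helix": "H", "strand": "E", "coil": "C"}
SS_STATES = ("H", "E", "C")

#: Packaged default table: Miyazawa–Jernigan (1996) contact energies
#: replicated over the three secondary-structure states — a synthetic
#: stand-in for an environment-dependent table (see its provenance line).
DEFAULT_TABLE_RESOURCE = "mj60_synthetic.tsv"

LABELS_60 = tuple(f"{aa}_{ss}" for aa in AMINO_ACIDS for ss in SS_STATES)

_SYMMETRY_TOL = 1e-9


@dataclass
class EnergyTable:
    """Symmetric 60×60 contact-energy matrix over (residue type, SS state).

    ``labels`` fixes the row/column order; ``matrix`` holds e_ij values in
    dimensionless contact-energy units; ``provenance`` records where the
    numbers came from and is propagated into run logs.
    """

    labels: tuple
    matrix: np.ndarray
    provenance: str = "unspecified"
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = tuple(self.labels)
        self._index = {lab: i for i, lab in enumerate(self.labels)}
        self.validate()

    def validate(self) -> None:
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise TableValidationError(
                f"matrix shape {self.matrix.shape} != ({n}, {n})"
            )
        missing = set(LABELS_60) - set(self.labels)
        if missing:
            raise TableValidationError(
                f"missing labels: {sorted(missing)[:6]}…"
                if len(missing) > 6 else f"missing labels: {sorted(missing)}"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise TableValidationError("non-finite entries in energy table")
        asym = np.abs(self.matrix - self.matrix.T).max()
        if asym > _SYMMETRY_TOL:
            i, j = np.unravel_index(
                np.abs(self.matrix - self.matrix.T).argmax(),
                self.matrix.shape,
            )
            raise TableValidationError(
                f"table not symmetric: ({self.labels[i]}, {self.labels[j]}) "
                f"differs from its transpose by {asym:g}"
            )

    def lookup(self, res_a: str, ss_a: str, res_b: str, ss_b: str) -> float:
        la = f"{res_a}_{SS_CODE.get(ss_a, ss_a)}"
        lb = f"{res_b}_{SS_CODE.get(ss_b, ss_b)}"
        try:
            return float(self.matrix[self._index[la], self._index[lb]])
        except KeyError as exc:
            raise LookupError_(
                f"pair ({la}, {lb}) absent from energy table"
            ) from exc

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=list(self.labels), columns=list(self.labels)
        )

    def write(self, path) -> None:
        frame = self.to_frame()
        frame.index.name = "RES_SS"
        frame.to_csv(path, sep="\t", float_format="%.6g")


def load_energy_table(source: Optional[str] = None) -> EnergyTable:
    """Load and validate an energy table.

    ``source=None`` loads the packaged default; otherwise ``source`` is a
    TSV file with a ``RES_SS`` header row and column (labels like
    ``ALA_H``, ``GLY_C``).
    """
    if source is None:
        ref = resources.files("anca.data").joinpath(DEFAULT_TABLE_RESOURCE)
        with resources.as_file(ref) as path:
            frame = pd.read_csv(path, sep="\t", index_col=0)
        provenance = (
            "Miyazawa-Jernigan (1996) inter-residue contact energies, "
            "replicated over helix/strand/coil states (synthetic stand-in "
            "for an environment-dependent table); packaged default"
        )
    else:
        path = Path(source)
        if not path.is_file():
            raise TableValidationError(f"energy table not found: {source}")
        frame = pd.read_csv(path, sep="\t", index_col=0)
        provenance = f"user file: {path.name}"
    labels = [str(c) for c in frame.columns]
    if list(frame.index.astype(str)) != labels:
        raise TableValidationError(
            "energy-table row labels do not match column labels"
        )
    return EnergyTable(tuple(labels), frame.to_numpy(dtype=float), provenance)


def contact_energy(i: Residue, j: Residue, table: EnergyTable) -> float:
    """e_ij for two amino-acid residues with assigned secondary structure.

    Depends only on (type, state) of each residue — never on coordinates —
    and is symmetric in its arguments.
    """
    for res in (i, j):
        if res.kind != "amino_acid":
            raise ContractViolation(
                f"{res.id_str} is {res.kind}, not an amino acid"
            )
        if res.ss_state not in SS_CODE:
            raise ContractViolation(
                f"{res.id_str} has no secondary-structure state; call "
                "assign_secondary_structure first"
            )
    return table.lookup(i.res_name, i.ss_state, j.res_name, j.ss_state)


def _sequence_adjacent(a: Residue, b: Residue, seq_exclusion: int) -> bool:
    return (
        a.chain_id == b.chain_id
        and abs(a.seq_pos - b.seq_pos) < seq_exclusion
    )


def candidate_contacts(
    model: StructureModel,
    d_cutoff: float = 8.0,
    *,
    seq_exclusion: int = 2,
    mode: str = "calpha",
) -> list:
    """Unordered amino-acid residue pairs within ``d_cutoff`` Å.

    ``mode="calpha"`` measures C-alpha–C-alpha distance; ``mode="heavy_min"``
    uses the minimum heavy-atom pair distance. Pairs in the same chain with
    sequence separation below ``seq_exclusion`` are excluded (covalent
    neighbours carry no contact information). Distance comparison is
    inclusive (``<= d_cutoff``).
    """
    if d_cutoff <= 0:
        raise ContractViolation("d_cutoff must be positive")
    if mode not in ("calpha", "heavy_min"):
        raise ContractViolation(f"unknown contact mode {mode!r}")
    amino = [r for r in model.residues("amino_acid") if r.ca is not None]
    pairs = []
    if mode == "calpha":
        if len(amino) < 2:
            return []
        coords = np.array([r.ca.xyz for r in amino])
        dmat = squareform(pdist(coords))
        ii, jj = np.nonzero(np.triu(dmat <= d_cutoff, k=1))
        for a, b in zip(ii.tolist(), jj.tolist()):
            if not _sequence_adjacent(amino[a], amino[b], seq_exclusion):
                pairs.append((amino[a], amino[b]))
    else:
        atom_xyz, atom_res = [], []
        for idx, res in enumerate(amino):
            for atom in res.atoms:
                if atom.element.upper() != "H":
                    atom_xyz.append(atom.xyz)
                    atom_res.append(idx)
        if not atom_xyz:
            return []
        tree = cKDTree(np.array(atom_xyz))
        seen = set()
        for a, b in tree.query_pairs(d_cutoff):
            ra, rb = atom_res[a], atom_res[b]
            if ra == rb:
                continue
            key = (min(ra, rb), max(ra, rb))
            if key in seen:
                continue
            if not _sequence_adjacent(amino[key[0]], amino[key[1]],
                                      seq_exclusion):
                seen.add(key)
        pairs = [(amino[a], amino[b]) for a, b in sorted(seen)]
    return pairs
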