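"""Deterministic synthetic structures and toy energy tables.

Every stage of the pipeline is testable offline: this module emits small
PDB-format texts built from ideal covalent geometry (peptide backbones at
chosen phi/psi dihedrals, coarse nucleic-acid helices carrying the P/C4*/C2
representative atoms) and random-but-seeded 60×60 energy tables mixing
attractive and repulsive entries. Identical spec + seed always yields
byte-identical text. The geometry is idealised — no side chains beyond
C-beta-free backbones, no physical base pairing — which is exactly enough
to exercise parsing, secondary-structure assignment, contact detection and
every network builder.
"""

from __future__ import annotations

import math

import numpy as np

from .energy import LABELS_60, EnergyTable
from .errors import ContractViolation

__all__ = [
    "make_peptide",
    "make_two_chain_complex",
    "make_nucleic",
    "make_protein_rna_complex",
    "make_toy_energy_table",
    "FIXTURE_SEQUENCE",
    "SYNTHETIC_PEPTIDE_PDB",
]

#: Residue types cycled through by generated peptides (all 20 once).
FIXTURE_SEQUENCE = (
    "ALA", "CYS", "ASP", "GLU", "PHE", "GLY", "HIS", "ILE", "LYS", "LEU",
    "MET", "ASN", "PRO", "GLN", "ARG", "SER", "THR", "VAL", "TRP", "TYR",
)

# ideal backbone covalent geometry (Engh & Huber averages), Å / degrees
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.5

HELIX_PHI_PSI = (-57.0, -47.0)
EXTENDED_PHI_PSI = (180.0, 180.0)


def _place(p_a, p_b, p_c, bond: float, angle: float, dihedral: float):
    """NeRF atom placement: position D given A-B-C and internal coords."""
    ang, dih = math.radians(angle), math.radians(dihedral)
    bc = p_c - p_b
    bc /= np.linalg.norm(bc)
    n = np.cross(p_b - p_a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.cos(dih) * math.sin(ang),
        bond * math.sin(dih) * math.sin(ang),
    ])
    return p_c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _backbone(length: int, phi: float, psi: float, omega: float = 180.0):
    """(N, CA, C, O) coordinates for each residue of an ideal chain."""
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    residues = [[n0, ca0, c0]]
    for _ in range(1, length):
        n_prev, ca_prev, c_prev = residues[-1]
        n_i = _place(n_prev, ca_prev, c_prev, _B_C_N, _A_CA_C_N, psi)
        ca_i = _place(ca_prev, c_prev, n_i, _B_N_CA, _A_C_N_CA, omega)
        c_i = _place(c_prev, n_i, ca_i, _B_CA_C, _A_N_CA_C, phi)
        residues.append([n_i, ca_i, c_i])
    out = []
    for i, (n_i, ca_i, c_i) in enumerate(residues):
        if i + 1 < length:
            n_next = residues[i + 1][0]
            # O opposite the next N across the carbonyl plane
            o_i = _place(n_i, ca_i, c_i, _B_C_O, _A_CA_C_O, psi + 180.0)
        else:
            o_i = _place(n_i, ca_i, c_i, _B_C_O, _A_CA_C_O, 180.0)
        out.append((n_i, ca_i, c_i, o_i))
    return out


def _pdb_lines(records, chain_id: str, start_serial: int = 1):
    lines = []
    serial = start_serial
    for resnum, resname, atoms in records:
        for name, element, xyz in atoms:
            pad_name = f" {name}" if len(name) < 4 and len(element) == 1 \
                else name
            lines.append(
                f"ATOM  {serial:>5} {pad_name:<4} {resname:<3} {chain_id}"
                f"{resnum:>4}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"  1.00  0.00          {element:>2}"
            )
            serial += 1
    lines.append(f"TER   {serial:>5}")
    return lines, serial + 1


def _peptide_records(kind: str, length: int, rng, jitter: float,
                     offset=np.zeros(3), start_resnum: int = 1):
    if kind == "helix_peptide":
        phi, psi = HELIX_PHI_PSI
    elif kind == "extended_peptide":
        phi, psi = EXTENDED_PHI_PSI
    else:
        raise ContractViolation(f"unknown peptide kind {kind!r}")
    records = []
    backbone = _backbone(length, phi, psi)
    for i, (n, ca, c, o) in enumerate(backbone):
        resname = FIXTURE_SEQUENCE[i % len(FIXTURE_SEQUENCE)]
        atoms = []
        for name, element, xyz in (("N", "N", n), ("CA", "C", ca),
                                   ("C", "C", c), ("O", "O", o)):
            pos = xyz + offset
            if jitter > 0:
                pos = pos + rng.normal(0.0, jitter, size=3)
            atoms.append((name, element, pos))
        records.append((start_resnum + i, resname, atoms))
    return records


def make_peptide(kind: str, length: int, seed: int = 0, *,
                 jitter: float = 0.0, chain_id: str = "A") -> str:
    """PDB text for an ideal helical or extended peptide.

    ``kind`` is ``helix_peptide`` (phi,psi = -57,-47) or
    ``extended_peptide`` (180,180); residue types cycle through all 20
    amino acids. ``jitter`` adds seeded Gaussian coordinate noise (Å).
    """
    if length < 1:
        raise ContractViolation("length must be >= 1")
    rng = np.random.default_rng(seed)
    records = _peptide_records(kind, length, rng, jitter)
    lines, _ = _pdb_lines(records, chain_id)
    return "\n".join(lines) + "\nEND\n"


def make_two_chain_complex(length_a: int = 8, length_b: int = 8,
                           seed: int = 0, *, separation: float = 5.5,
                           jitter: float = 0.0) -> str:
    """Two helical chains laid side by side ``separation`` Å apart, close
    enough for inter-chain contacts at the default cutoffs."""
    rng = np.random.default_rng(seed)
    rec_a = _peptide_records("helix_peptide", length_a, rng, jitter)
    rec_b = _peptide_records("helix_peptide", length_b, rng, jitter,
                             offset=np.array([0.0, separation, 0.0]))
    lines_a, serial = _pdb_lines(rec_a, "A")
    lines_b, _ = _pdb_lines(rec_b, "B", serial)
    return "\n".join(lines_a + lines_b) + "\nEND\n"


_NUCLEOTIDES = ("A", "C", "G", "U")
_RISE, _TWIST = 2.81, 32.7  # Å per step, degrees per step


def _nucleic_records(length: int, rng, jitter: float,
                     drop_5prime_p: bool, offset=np.zeros(3),
                     start_resnum: int = 1):
    records = []
    for i in range(length):
        theta = math.radians(_TWIST * i)
        z = _RISE * i
        p = np.array([9.0 * math.cos(theta), 9.0 * math.sin(theta), z])
        c4 = np.array([8.2 * math.cos(theta + math.radians(25.0)),
                       8.2 * math.sin(theta + math.radians(25.0)), z + 1.0])
        c2 = np.array([5.2 * math.cos(theta + math.radians(45.0)),
                       5.2 * math.sin(theta + math.radians(45.0)), z + 1.6])
        atoms = []
        for name, element, xyz in (("P", "P", p), ("C4'", "C", c4),
                                   ("C2", "C", c2)):
            if name == "P" and i == 0 and drop_5prime_p:
                continue
            pos = xyz + offset
            if jitter > 0:
                pos = pos + rng.normal(0.0, jitter, size=3)
            atoms.append((name, element, pos))
        records.append((start_resnum + i, _NUCLEOTIDES[i % 4], atoms))
    return records


def make_nucleic(kind: str, length: int, seed: int = 0, *,
                 jitter: float = 0.0, drop_5prime_p: bool = False,
                 chain_id: str = "B") -> str:
    """PDB text for a coarse RNA strand: each nucleotide carries P, C4'
    and C2 atoms on an ideal helical lattice. ``drop_5prime_p`` omits the
    5'-terminal phosphate (as in most deposited structures)."""
    if kind not in ("rna_hairpin", "rna_strand"):
        raise ContractViolation(f"unknown nucleic kind {kind!r}")
    if length < 1:
        raise ContractViolation("length must be >= 1")
    rng = np.random.default_rng(seed)
    records = _nucleic_records(length, rng, jitter, drop_5prime_p)
    lines, _ = _pdb_lines(records, chain_id)
    return "\n".join(lines) + "\nEND\n"


def make_protein_rna_complex(protein_length: int = 8, rna_length: int = 4,
                             seed: int = 0, *, jitter: float = 0.0) -> str:
    """A helical peptide (chain A) docked against a coarse RNA strand
    (chain B) so that inter-molecular contacts exist below ~7 Å."""
    rng = np.random.default_rng(seed)
    rec_p = _peptide_records("helix_peptide", protein_length, rng, jitter)
    # place the RNA so its first nucleotides sit next to the peptide axis
    rec_n = _nucleic_records(rna_length, rng, jitter, False,
                             offset=np.array([-6.0, 4.0, -1.0]))
    lines_a, serial = _pdb_lines(rec_p, "A")
    lines_b, _ = _pdb_lines(rec_n, "B", serial)
    return "\n".join(lines_a + lines_b) + "\nEND\n"


def make_toy_energy_table(seed: int = 0, *, negative_only: bool = False,
                          scale: float = 2.0) -> EnergyTable:
    """Seeded symmetric 60×60 table with both attractive (< 0) and
    repulsive (>= 0) entries, so the e < 0 edge rule is exercised.

    ``negative_only=True`` shifts all entries below zero (useful when a
    fixture must turn every candidate contact into an edge, e.g. for
    edge-weight normalisation tests).
    """
    rng = np.random.default_rng(seed)
    raw = rng.normal(0.0, scale, size=(60, 60))
    mat = (raw + raw.T) / 2.0
    if negative_only:
        mat = -np.abs(mat) - 0.01
    else:
        # construction guarantees a mix of signs whatever the seed
        mat[0, 1] = mat[1, 0] = -abs(mat[0, 1]) - 0.5
        mat[2, 3] = mat[3, 2] = abs(mat[2, 3]) + 0.5
    return EnergyTable(
        LABELS_60, mat, provenance=f"toy table (seed={seed})"
    )


#: Frozen output of ``make_peptide("helix_peptide", 6, seed=0)``: a
#: synthetic parser-regression literal (no real PDB entry is bundled),
#: guarding the generator and the parser against format drift.
SYNTHETIC_PEPTIDE_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.422   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       2.910   1.743   0.776  1.00  0.00           O
ATOM      5  N   CYS A   2       1.463   2.263  -0.872  1.00  0.00           N
ATOM      6  CA  CYS A   2       1.899   3.650  -0.974  1.00  0.00           C
ATOM      7  C   CYS A   2       1.768   4.370   0.364  1.00  0.00           C
ATOM      8  O   CYS A   2       2.693   5.057   0.797  1.00  0.00           O
ATOM      9  N   ASP A   3       0.618   4.205   1.008  1.00  0.00           N
ATOM     10  CA  ASP A   3       0.364   4.838   2.297  1.00  0.00           C
ATOM     11  C   ASP A   3       1.421   4.443   3.323  1.00  0.00           C
ATOM     12  O   ASP A   3       1.958   5.298   4.027  1.00  0.00           O
ATOM     13  N   GLU A   4       1.711   3.149   3.398  1.00  0.00           N
ATOM     14  CA  GLU A   4       2.704   2.639   4.337  1.00  0.00           C
ATOM     15  C   GLU A   4       4.057   3.309   4.126  1.00  0.00           C
ATOM     16  O   GLU A   4       4.696   3.743   5.085  1.00  0.00           O
ATOM     17  N   PHE A   5       4.484   3.388   2.870  1.00  0.00           N
ATOM     18  CA  PHE A   5       5.761   4.005   2.531  1.00  0.00           C
ATOM     19  C   PHE A   5       5.830   5.442   3.035  1.00  0.00           C
ATOM     20  O   PHE A   5       6.823   5.846   3.640  1.00  0.00           O
ATOM     21  N   GLY A   6       4.771   6.204   2.781  1.00  0.00           N
ATOM     22  CA  GLY A   6       4.709   7.597   3.208  1.00  0.00           C
ATOM     23  C   GLY A   6       4.899   7.721   4.716  1.00  0.00           C
ATOM     24  O   GLY A   6       4.878   8.825   5.260  1.00  0.00           O
TER      25
END
"""
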