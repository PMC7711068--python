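"""Parse macromolecular structures and derive per-residue attributes.

This module turns a PDB file (or a 4-character PDB code) into a
:class:`StructureModel` — the single in-memory representation every network
builder consumes — and provides the two per-residue annotation steps the
energy-based models need:

* 3-state secondary structure (helix / strand / coil), via DSSP when an
  executable is on PATH, otherwise via a built-in backbone-dihedral
  classifier;
* node weights: relative solvent accessibility (Shrake–Rupley, normalised by
  the Tien et al. theoretical maxima), residue mass, Kyte–Doolittle
  hydrophobicity, Grantham polarity, or a user-supplied plain-text file.

Parsing is delegated to Bio.PDB; only the first model of multi-model (NMR)
entries is kept, waters and unrecognised hetero residues are dropped, and
for disordered atoms the highest-occupancy conformer is used.
"""

from __future__ import annotations

import io
import math
import shutil
import tempfile
import urllib.request
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np

from .errors import (
    AncaError,
    EmptyStructureError,
    FetchError,
    MissingWeightError,
    ParseError,
)

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "StructureModel",
    "NodeWeightSpec",
    "parse_structure",
    "write_pdb",
    "assign_secondary_structure",
    "compute_node_weights",
    "AMINO_ACIDS",
    "RESIDUE_MASS",
    "KYTE_DOOLITTLE",
    "GRANTHAM_POLARITY",
    "MAX_SASA_TIEN",
]

# ---------------------------------------------------------------------------
# residue vocabularies and property scales
# ---------------------------------------------------------------------------

AMINO_ACIDS = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

#: Non-standard residues silently renamed to their parent type.
RESIDUE_ALIASES = {
    "MSE": "MET",   # selenomethionine
    "SEC": "CYS",   # selenocysteine, coarse-grained to CYS
    "HSD": "HIS", "HSE": "HIS", "HSP": "HIS",
    "CYX": "CYS", "HID": "HIS", "HIE": "HIS", "HIP": "HIS",
}

NUCLEOTIDES = {
    "A", "C", "G", "U", "I",
    "DA", "DC", "DG", "DT", "DI", "DU",
}

#: Average residue (monomer-in-chain) masses, Da.
RESIDUE_MASS = {
    "GLY": 57.05, "ALA": 71.08, "SER": 87.08, "PRO": 97.12, "VAL": 99.13,
    "THR": 101.10, "CYS": 103.14, "LEU": 113.16, "ILE": 113.16,
    "ASN": 114.10, "ASP": 115.09, "GLN": 128.13, "LYS": 128.17,
    "GLU": 129.12, "MET": 131.19, "HIS": 137.14, "PHE": 147.18,
    "ARG": 156.19, "TYR": 163.18, "TRP": 186.21,
}

#: Kyte & Doolittle hydropathy index.
KYTE_DOOLITTLE = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5, "MET": 1.9,
    "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8, "TRP": -0.9,
    "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5, "GLN": -3.5,
    "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}

#: Grantham (1974) polarity scale.
GRANTHAM_POLARITY = {
    "ALA": 8.1, "ARG": 10.5, "ASN": 11.6, "ASP": 13.0, "CYS": 5.5,
    "GLN": 10.5, "GLU": 12.3, "GLY": 9.0, "HIS": 10.4, "ILE": 5.2,
    "LEU": 4.9, "LYS": 11.3, "MET": 5.7, "PHE": 5.2, "PRO": 8.0,
    "SER": 9.2, "THR": 8.6, "TRP": 5.4, "TYR": 6.2, "VAL": 5.9,
}

#: Theoretical maximum solvent accessibility (Tien et al. 2013), Å².
MAX_SASA_TIEN = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

PROPERTY_SCALES = {
    "mass": RESIDUE_MASS,
    "hydrophobicity": KYTE_DOOLITTLE,
    "polarity": GRANTHAM_POLARITY,
}

#: Cap on relative accessibility; exposed termini can slightly exceed 1.
RSA_CAP = 1.2


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray  # shape (3,), Å

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)


@dataclass
class Residue:
    """One polymer residue with its atoms and derived annotations."""

    chain_id: str
    seq_pos: int                # author numbering, as printed in the PDB
    insertion_code: str         # "" when absent
    res_name: str               # 3-letter amino acid or nucleotide code
    kind: str                   # "amino_acid" | "nucleotide" | "other"
    atoms: list[Atom] = field(default_factory=list)
    ss_state: Optional[str] = None   # "helix" | "strand" | "coil"
    properties: dict[str, float] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_pos, self.insertion_code)

    @property
    def id_str(self) -> str:
        icode = f":{self.insertion_code}" if self.insertion_code else ""
        return f"{self.chain_id}:{self.seq_pos}{icode}"

    def atom(self, *names: str) -> Optional[Atom]:
        """First atom matching any of ``names`` (e.g. ``"C4'", "C4*"``)."""
        for n in names:
            for a in self.atoms:
                if a.name == n:
                    return a
        return None

    @property
    def ca(self) -> Optional[Atom]:
        return self.atom("CA")


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class StructureModel:
    """Parsed structure: the single source for all network builders."""

    structure_id: str
    chains: list[Chain] = field(default_factory=list)
    source: str = "file"  # "file" | "fetched"

    def residues(self, kind: Optional[str] = None) -> Iterator[Residue]:
        for chain in self.chains:
            for res in chain.residues:
                if kind is None or res.kind == kind:
                    yield res

    @property
    def n_amino(self) -> int:
        return sum(1 for _ in self.residues("amino_acid"))

    @property
    def n_nucleotide(self) -> int:
        return sum(1 for _ in self.residues("nucleotide"))


@dataclass
class NodeWeightSpec:
    """How to assign one numeric weight to every amino-acid node.

    ``mode`` is one of ``sas`` (relative solvent accessibility, structure
    dependent), ``mass``, ``hydrophobicity``, ``polarity`` (per-type
    lookups) or ``custom_file`` (whitespace-separated ``chain resnum
    weight`` lines, ``#`` comments).
    """

    mode: str
    file_path: Optional[str] = None

    MODES = ("sas", "mass", "hydrophobicity", "polarity", "custom_file")

    def __post_init__(self) -> None:
        if self.mode not in self.MODES:
            raise AncaError(f"unknown node-weight mode {self.mode!r}")
        if self.mode == "custom_file" and not self.file_path:
            raise AncaError("custom_file mode requires file_path")


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_PDB_URL = "https://files.rcsb.org/download/{code}.pdb"


def _looks_like_code(source: str) -> bool:
    s = str(source)
    return len(s) == 4 and s.isalnum() and not Path(s).exists()


def _fetch_pdb_text(code: str, timeout: float = 10.0, opener=None) -> str:
    url = _PDB_URL.format(code=code.upper())
    open_fn = opener or urllib.request.urlopen
    try:
        with open_fn(url, timeout=timeout) as fh:  # type: ignore[call-arg]
            data = fh.read()
    except Exception as exc:  # noqa: BLE001 - network errors are diverse
        raise FetchError(f"could not fetch PDB entry {code!r}: {exc}") from exc
    return data.decode() if isinstance(data, bytes) else data


def _classify_resname(name: str, has_ca: bool) -> tuple[str, str]:
    """Return (canonical_name, kind); kind 'other' means drop-with-warning."""
    name = name.strip().upper()
    if name in RESIDUE_ALIASES:
        name = RESIDUE_ALIASES[name]
    if name in RESIDUE_MASS:
        return name, "amino_acid"
    if name in NUCLEOTIDES:
        return name, "nucleotide"
    if name == "UNK" and has_ca:
        return name, "other"
    return name, "other"


def parse_structure(source, *, allow_fetch: bool = True,
                    _opener=None) -> StructureModel:
    """Parse a PDB file path, PDB-format text stream, or 4-character code.

    Waters and unrecognised hetero residues are excluded; non-standard
    amino acids in the alias table (e.g. MSE) are renamed; only the first
    model of multi-model entries is retained.
    """
    from Bio.PDB import PDBParser

    source_kind = "file"
    if hasattr(source, "read"):
        handle, structure_id = source, "structure"
    elif _looks_like_code(str(source)):
        if not allow_fetch:
            raise FetchError(
                f"{source!r} looks like a PDB code but fetching is disabled"
            )
        text = _fetch_pdb_text(str(source), opener=_opener)
        handle, structure_id = io.StringIO(text), str(source).upper()
        source_kind = "fetched"
    else:
        path = Path(source)
        if not path.is_file():
            raise ParseError(f"not a readable PDB file: {source}")
        handle, structure_id = open(path), path.stem

    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bio_struct = parser.get_structure(structure_id, handle)
    except Exception as exc:
        raise ParseError(f"failed to parse {structure_id}: {exc}") from exc
    finally:
        if handle is not source and hasattr(handle, "close"):
            handle.close()

    models = list(bio_struct)
    if not models:
        raise EmptyStructureError(f"{structure_id}: no models in file")
    model = models[0]  # first model only (NMR ensembles)

    out = StructureModel(structure_id=structure_id, source=source_kind)
    dropped: list[str] = []
    for bio_chain in model:
        chain = Chain(chain_id=bio_chain.id.strip() or "A")
        for bio_res in bio_chain:
            hetflag, resnum, icode = bio_res.id
            resname = bio_res.get_resname().strip().upper()
            if resname in ("HOH", "WAT", "DOD"):
                continue
            has_ca = "CA" in bio_res
            canonical, kind = _classify_resname(resname, has_ca)
            if kind == "other":
                if hetflag.strip():  # plain hetero ligand: drop silently-ish
                    dropped.append(f"{chain.chain_id}:{resnum}:{resname}")
                    continue
                dropped.append(f"{chain.chain_id}:{resnum}:{resname}")
                continue
            atoms = []
            for bio_atom in bio_res:
                # DisorderedAtom resolves to the highest-occupancy conformer
                coord = np.asarray(bio_atom.get_coord(), dtype=float)
                if not np.all(np.isfinite(coord)):
                    continue
                element = (bio_atom.element or "").strip() or bio_atom.get_name()[0]
                atoms.append(Atom(bio_atom.get_name().strip(), element, coord))
            if not atoms:
                continue
            res = Residue(
                chain_id=chain.chain_id,
                seq_pos=int(resnum),
                insertion_code=icode.strip(),
                res_name=canonical,
                kind=kind,
                atoms=atoms,
            )
            if kind == "amino_acid" and res.ca is None:
                # an amino acid without CA cannot be a network node
                dropped.append(f"{res.id_str}:{canonical}(no CA)")
                continue
            chain.residues.append(res)
        if chain.residues:
            out.chains.append(chain)

    if dropped:
        warnings.warn(
            f"{structure_id}: dropped {len(dropped)} non-standard/incomplete "
            f"residues: {', '.join(dropped[:8])}"
            + ("…" if len(dropped) > 8 else ""),
            stacklevel=2,
        )
    if out.n_amino == 0 and out.n_nucleotide == 0:
        raise EmptyStructureError(f"{structure_id}: no polymer residues found")
    return out


def write_pdb(model: StructureModel) -> str:
    """Serialise a StructureModel back to PDB-format text (ATOM records)."""
    lines: list[str] = []
    serial = 1
    for chain in model.chains:
        for res in chain.residues:
            for atom in res.atoms:
                name = atom.name
                # PDB atom-name column convention: 1-char elements start col 14
                if len(name) < 4 and len(atom.element) == 1:
                    name = f" {name}"
                lines.append(
                    "ATOM  {serial:>5} {name:<4}{alt}{res:<3} {chain}{num:>4}"
                    "{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
                    "          {elem:>2}".format(
                        serial=serial, name=name, alt=" ",
                        res=res.res_name, chain=chain.chain_id[:1] or "A",
                        num=res.seq_pos, icode=res.insertion_code or " ",
                        x=atom.xyz[0], y=atom.xyz[1], z=atom.xyz[2],
                        occ=1.0, b=0.0, elem=atom.element[:2],
                    )
                )
                serial += 1
        lines.append(f"TER   {serial:>5}")
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# secondary structure
# ---------------------------------------------------------------------------

def _dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees, in (-180, 180]."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.degrees(math.atan2(y, x))


_PEPTIDE_BOND_MAX = 2.5  # Å, C(i)–N(i+1); beyond this the chain is broken


def _phi_psi(residues: list[Residue]):
    """Per-residue (phi, psi) using author order; None at breaks/termini."""
    coords = []
    for res in residues:
        n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
        coords.append(None if None in (n, ca, c) else (n.xyz, ca.xyz, c.xyz))
    phi = [None] * len(residues)
    psi = [None] * len(residues)
    for i in range(len(residues)):
        if coords[i] is None:
            continue
        n_i, ca_i, c_i = coords[i]
        if i > 0 and coords[i - 1] is not None:
            c_prev = coords[i - 1][2]
            if np.linalg.norm(n_i - c_prev) <= _PEPTIDE_BOND_MAX:
                phi[i] = _dihedral(c_prev, n_i, ca_i, c_i)
        if i + 1 < len(residues) and coords[i + 1] is not None:
            n_next = coords[i + 1][0]
            if np.linalg.norm(n_next - c_i) <= _PEPTIDE_BOND_MAX:
                psi[i] = _dihedral(n_i, ca_i, c_i, n_next)
    return phi, psi


def _classify_dihedral(phi: Optional[float], psi: Optional[float]) -> str:
    if phi is None or psi is None:
        return "coil"
    if -100.0 <= phi <= -30.0 and -80.0 <= psi <= -5.0:
        return "helix"
    if (phi <= -90.0 or phi > 160.0) and (psi >= 90.0 or psi < -150.0):
        return "strand"
    return "coil"


_DSSP_TO_3STATE = {
    "H": "helix", "G": "helix", "I": "helix",
    "E": "strand", "B": "strand",
}


def _dssp_executable() -> Optional[str]:
    for name in ("mkdssp", "dssp"):
        if shutil.which(name):
            return name
    return None


def _assign_ss_dssp(model: StructureModel, executable: str) -> bool:
    """Run DSSP on a temporary PDB dump; returns False on any failure."""
    from Bio.PDB import PDBParser
    from Bio.PDB.DSSP import DSSP

    try:
        with tempfile.NamedTemporaryFile(
            "w", suffix=".pdb", delete=False
        ) as fh:
            fh.write(write_pdb(model))
            tmp = fh.name
        parser = PDBParser(QUIET=True)
        bio = parser.get_structure(model.structure_id, tmp)
        dssp = DSSP(next(iter(bio)), tmp, dssp=executable)
    except Exception:  # noqa: BLE001 - fall back to dihedral classifier
        return False
    lookup = {}
    for key in dssp.keys():
        chain_id, (_, resnum, icode) = key
        lookup[(chain_id, resnum, icode.strip())] = dssp[key][2]
    for res in model.residues("amino_acid"):
        code = lookup.get(res.key, "-")
        res.ss_state = _DSSP_TO_3STATE.get(code, "coil")
    return True


def assign_secondary_structure(
    model: StructureModel, method: str = "auto"
) -> StructureModel:
    """Assign 3-state secondary structure to every amino-acid residue.

    ``method``: ``"auto"`` tries DSSP (8-class output collapsed to
    helix/strand/coil) and falls back to the backbone-dihedral classifier;
    ``"dihedral"`` forces the built-in classifier; ``"dssp"`` requires a
    DSSP executable. Residues with missing backbone atoms or at chain
    breaks get coil. Mutates and returns ``model``.
    """
    if method not in ("auto", "dihedral", "dssp"):
        raise AncaError(f"unknown secondary-structure method {method!r}")
    if method in ("auto", "dssp"):
        exe = _dssp_executable()
        if exe is not None and _assign_ss_dssp(model, exe):
            return model
        if method == "dssp":
            raise AncaError("DSSP executable not found or failed")
    for chain in model.chains:
        aa = [r for r in chain.residues if r.kind == "amino_acid"]
        phi, psi = _phi_psi(aa)
        for res, f, y in zip(aa, phi, psi):
            res.ss_state = _classify_dihedral(f, y)
    return model


# ---------------------------------------------------------------------------
# node weights
# ---------------------------------------------------------------------------

def _to_bio_structure(model: StructureModel):
    """Build a Bio.PDB entity from a StructureModel (for SASA)."""
    from Bio.PDB.StructureBuilder import StructureBuilder

    sb = StructureBuilder()
    sb.init_structure(model.structure_id)
    sb.init_model(0)
    sb.init_seg("    ")
    for chain in model.chains:
        sb.init_chain(chain.chain_id[:1] or "A")
        for res in chain.residues:
            sb.init_residue(
                res.res_name, " ", res.seq_pos, res.insertion_code or " "
            )
            for i, atom in enumerate(res.atoms):
                sb.init_atom(
                    atom.name, atom.xyz.astype(np.float64), 0.0, 1.0, " ",
                    atom.name if len(atom.name) == 4 else f" {atom.name}",
                    serial_number=i, element=atom.element.upper() or None,
                )
    return sb.get_structure()


def _relative_sasa(model: StructureModel) -> dict:
    """Shrake–Rupley SASA per residue / Tien et al. theoretical maximum."""
    from Bio.PDB.SASA import ShrakeRupley

    bio = _to_bio_structure(model)
    ShrakeRupley(probe_radius=1.4, n_points=960).compute(bio[0], level="R")
    out = {}
    for bio_chain in bio[0]:
        for bio_res in bio_chain:
            _, resnum, icode = bio_res.id
            key = (bio_chain.id, resnum, icode.strip())
            resname = bio_res.get_resname().strip()
            if resname not in MAX_SASA_TIEN:
                continue
            rsa = float(bio_res.sasa) / MAX_SASA_TIEN[resname]
            out[key] = min(rsa, RSA_CAP)
    return out


def _read_custom_weights(path: str) -> dict:
    weights = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ParseError(
                    f"{path}:{lineno}: expected 'chain resnum weight', "
                    f"got {line!r}"
                )
            chain, resnum_tok, weight_tok = parts
            icode = ""
            if resnum_tok[-1].isalpha():
                resnum_tok, icode = resnum_tok[:-1], resnum_tok[-1].upper()
            try:
                resnum = int(resnum_tok)
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: bad residue number {parts[1]!r}"
                ) from exc
            try:
                weight = float(weight_tok)
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric weight {weight_tok!r}"
                ) from exc
            key = (chain, resnum, icode)
            if key in weights:
                raise ParseError(f"{path}:{lineno}: duplicate entry for {key}")
            weights[key] = weight
    return weights


def compute_node_weights(
    model: StructureModel, spec: NodeWeightSpec
) -> dict:
    """Map every amino-acid residue key to one finite weight.

    ``mass``/``hydrophobicity``/``polarity`` are pure per-residue-type
    lookups; ``sas`` is structure-dependent relative accessibility;
    ``custom_file`` reads ``chain resnum weight`` lines (entries for
    residues absent from the structure are ignored, so one file can cover
    several structures).
    """
    amino = [r for r in model.residues("amino_acid")]
    if spec.mode == "sas":
        rsa = _relative_sasa(model)
        missing = [r.id_str for r in amino if r.key not in rsa]
        if missing:
            raise MissingWeightError(missing)
        result = {r.key: rsa[r.key] for r in amino}
    elif spec.mode == "custom_file":
        table = _read_custom_weights(spec.file_path)
        missing = [r.id_str for r in amino if r.key not in table]
        if missing:
            raise MissingWeightError(missing)
        result = {r.key: table[r.key] for r in amino}
    else:
        scale = PROPERTY_SCALES[spec.mode]
        result = {r.key: scale[r.res_name] for r in amino}
    for res in amino:
        res.properties[spec.mode if spec.mode != "custom_file" else "custom"] \
            = result[res.key]
    return result
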