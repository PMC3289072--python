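"""Structure I/O and interface-contact queries.

Reads fixed-column PDB files into a light residue/atom model, partitions
protein from DNA, and answers the two distance queries the rest of the
pipeline is built on:

* ``binding_residues`` -- protein residues with any atom closer than a
  cutoff (default 4.5 A, strict ``<``) to any DNA atom.
* ``atom_base_contacts`` -- (protein atom, nucleotide residue) pairs within
  a cutoff (default 4.0 A, inclusive).

Hydrogens are dropped on read; alternate locations are resolved to the
highest-occupancy conformer (ties: first encountered).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "StructureModel",
    "StructureError",
    "EmptyStructureError",
    "read_pdb",
    "write_pdb",
    "binding_residues",
    "atom_base_contacts",
    "BINDING_CUTOFF",
    "CONTACT_CUTOFF",
    "STANDARD_AMINO_ACIDS",
]

#: Distance below which a protein residue counts as DNA-binding (strict <).
BINDING_CUTOFF = 4.5
#: Distance within which a protein atom / base contact is recorded (<=).
CONTACT_CUTOFF = 4.0

STANDARD_AMINO_ACIDS = frozenset(
    [
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    ]
)

# PDB dialect drift: modern DA/DC/DG/DT, legacy single letters, and the very
# old three-letter forms all map to one base letter.  Modified bases are
# intentionally absent and are skipped with a warning on read.
NUCLEOTIDE_NAMES = {
    "DA": "A", "DC": "C", "DG": "G", "DT": "T",
    "A": "A", "C": "C", "G": "G", "T": "T",
    "ADE": "A", "CYT": "C", "GUA": "G", "THY": "T",
}

# Atoms that belong to the base moiety (ring + exocyclic), as opposed to the
# sugar-phosphate backbone of a nucleotide.
BASE_MOIETY_ATOMS = frozenset(
    [
        "N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9",
        "O2", "O4", "O6", "N2", "N4", "N6", "C7", "C5M",
    ]
)

_DNA_LIKE_SUFFIXES = ("A", "C", "G", "T", "U")


class StructureError(ValueError):
    """Raised for malformed or unusable structure input."""


class EmptyStructureError(StructureError):
    """Raised when a file contains no coordinate records."""


@dataclass
class AtomRecord:
    serial: int
    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    residue_key: tuple = None  # (chain_id, seq_id, icode), set by parent

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise StructureError(f"atom {self.name!r}: coord must be a finite 3-vector")
        if not self.name:
            raise StructureError("atom name must be non-empty")


@dataclass
class ResidueRecord:
    chain_id: str
    seq_id: int
    res_type: str
    icode: str = ""
    atoms: list = field(default_factory=list)

    @property
    def key(self) -> tuple:
        return (self.chain_id, self.seq_id, self.icode)

    @property
    def kind(self) -> str:
        if self.res_type in STANDARD_AMINO_ACIDS:
            return "protein"
        if self.res_type in NUCLEOTIDE_NAMES:
            return "dna"
        return "other"

    @property
    def base_type(self) -> str | None:
        """One-letter base code for DNA residues, else None."""
        return NUCLEOTIDE_NAMES.get(self.res_type)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float).reshape(-1, 3)

    def base_coords(self) -> np.ndarray:
        """Coordinates of base-moiety atoms (all atoms if none match)."""
        pts = [a.coord for a in self.atoms if a.name in BASE_MOIETY_ATOMS]
        if not pts:
            pts = [a.coord for a in self.atoms]
        return np.array(pts, dtype=float).reshape(-1, 3)

    def centroid(self) -> np.ndarray:
        return self.coords().mean(axis=0)

    def base_centroid(self) -> np.ndarray:
        return self.base_coords().mean(axis=0)


@dataclass
class StructureModel:
    id: str
    residues: list
    source: str = ""

    def __post_init__(self) -> None:
        self._by_key = {r.key: r for r in self.residues}
        for r in self.residues:
            for a in r.atoms:
                a.residue_key = r.key

    def residue(self, key: tuple) -> ResidueRecord:
        return self._by_key[key]

    def __contains__(self, key: tuple) -> bool:
        return key in self._by_key

    @property
    def protein_residues(self) -> list:
        return [r for r in self.residues if r.kind == "protein"]

    @property
    def dna_residues(self) -> list:
        return [r for r in self.residues if r.kind == "dna"]

    def atoms_of(self, kind: str) -> list:
        return [a for r in self.residues if r.kind == kind for a in r.atoms]

    def coords_of(self, kind: str) -> np.ndarray:
        return np.array([a.coord for a in self.atoms_of(kind)], dtype=float).reshape(-1, 3)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a rigidly moved copy: x -> R x + t."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        residues = []
        for r in self.residues:
            atoms = [
                AtomRecord(a.serial, a.name, a.element,
                           rotation @ a.coord + translation,
                           a.occupancy, a.altloc)
                for a in r.atoms
            ]
            residues.append(ResidueRecord(r.chain_id, r.seq_id, r.res_type, r.icode, atoms))
        return StructureModel(self.id, residues, self.source)


def _normalize_resname(raw: str) -> str:
    return raw.strip().upper()


def _looks_like_nucleotide(resname: str) -> bool:
    return len(resname) <= 3 and resname.endswith(_DNA_LIKE_SUFFIXES)


def read_pdb(path, model_index: int = 0) -> StructureModel:
    """Parse a fixed-column PDB file into a :class:`StructureModel`.

    Only ATOM/HETATM records are used; hydrogens are skipped, alternate
    locations are collapsed to the highest-occupancy conformer (ties broken
    by file order).  ``model_index`` selects among MODEL blocks (0-based).
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionWarning

    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        try:
            structure = parser.get_structure(path.stem, str(path))
        except Exception as exc:  # Bio.PDB raises assorted exceptions
            raise StructureError(f"cannot parse PDB file {path}: {exc}") from exc
    models = list(structure)
    if not models:
        raise EmptyStructureError(f"{path}: no coordinate records")
    try:
        model = models[model_index]
    except IndexError:
        raise StructureError(
            f"{path}: model index {model_index} out of range ({len(models)} models)"
        ) from None

    residues: list[ResidueRecord] = []
    n_atoms = 0
    for chain in model:
        for res in chain:
            resname = _normalize_resname(res.get_resname())
            hetflag, seq_id, icode = res.get_id()
            icode = icode.strip()
            if resname == "HOH":
                resname = "HOH"
            elif (
                resname not in STANDARD_AMINO_ACIDS
                and resname not in NUCLEOTIDE_NAMES
                and _looks_like_nucleotide(resname)
            ):
                warnings.warn(
                    f"skipping modified/unknown nucleotide-like residue "
                    f"{resname} {chain.id}:{seq_id}",
                    stacklevel=2,
                )
                continue
            # collapse altlocs: keep highest occupancy per atom name,
            # first-seen wins ties
            best: dict[str, AtomRecord] = {}
            for atom in res.get_unpacked_list():
                elem = (atom.element or "").strip().upper()
                if elem in ("H", "D"):
                    continue
                occ = atom.get_occupancy()
                occ = 1.0 if occ is None else float(occ)
                rec = AtomRecord(
                    serial=atom.get_serial_number() or 0,
                    name=atom.get_name().strip(),
                    element=elem or atom.get_name().strip()[0],
                    coord=np.array(atom.get_coord(), dtype=float),
                    occupancy=occ,
                    altloc=(atom.get_altloc() or "").strip(),
                )
                prev = best.get(rec.name)
                if prev is None or rec.occupancy > prev.occupancy:
                    best[rec.name] = rec
            if not best:
                continue
            rr = ResidueRecord(
                chain_id=chain.id,
                seq_id=int(seq_id),
                res_type=resname,
                icode=icode,
                atoms=list(best.values()),
            )
            residues.append(rr)
            n_atoms += len(rr.atoms)
    if n_atoms == 0:
        raise EmptyStructureError(f"{path}: no ATOM records")
    return StructureModel(id=path.stem, residues=residues, source=str(path))


def _pdb_atom_name_field(name: str, element: str) -> str:
    # Columns 13-16: element symbols of one letter start in column 14.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1 and len(name) <= 3:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(s: StructureModel, path) -> None:
    """Write fixed-column PDB v3-style ATOM/HETATM records (3-decimal Å)."""
    lines = []
    serial = 0
    for r in s.residues:
        record = "ATOM  " if r.kind in ("protein", "dna") else "HETATM"
        resname = r.res_type[:3]
        for a in r.atoms:
            serial += 1
            lines.append(
                f"{record}{serial:>5d} {_pdb_atom_name_field(a.name, a.element)}"
                f" {resname:>3s} {r.chain_id[:1]:1s}{r.seq_id:>4d}{r.icode[:1] or ' '}   "
                f"{a.coord[0]:8.3f}{a.coord[1]:8.3f}{a.coord[2]:8.3f}"
                f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2s}"
            )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _kind_atoms_with_index(s: StructureModel, kind: str):
    atoms = []
    for r in s.residues:
        if r.kind == kind:
            for a in r.atoms:
                atoms.append((a, r))
    return atoms


def binding_residues(s: StructureModel, cutoff: float = BINDING_CUTOFF) -> set:
    """Protein residues with any atom strictly closer than ``cutoff`` to DNA.

    Returns a set of residue keys; empty when the structure has no DNA.
    """
    dna_coords = s.coords_of("dna")
    if dna_coords.size == 0:
        return set()
    tree = cKDTree(dna_coords)
    out = set()
    for r in s.protein_residues:
        coords = r.coords()
        d, _ = tree.query(coords, k=1)
        if np.min(d) < cutoff:
            out.add(r.key)
    return out


def atom_base_contacts(
    s: StructureModel,
    cutoff: float = CONTACT_CUTOFF,
    base_moiety_only: bool = False,
) -> list:
    """(protein atom, nucleotide residue) pairs within ``cutoff`` (inclusive).

    Distance is the minimum from the protein atom to any atom of the
    nucleotide; with ``base_moiety_only`` the backbone sugar/phosphate atoms
    of the nucleotide are excluded from that minimum.
    """
    pairs = []
    bases = s.dna_residues
    if not bases:
        return pairs
    base_coords = []
    for b in bases:
        pts = b.base_coords() if base_moiety_only else b.coords()
        base_coords.append(pts)
    all_pts = np.vstack(base_coords)
    owner = np.concatenate(
        [np.full(len(pts), i) for i, pts in enumerate(base_coords)]
    )
    tree = cKDTree(all_pts)
    for r in s.protein_residues:
        for a in r.atoms:
            idx = tree.query_ball_point(a.coord, cutoff)
            if not idx:
                continue
            for bi in sorted(set(owner[i] for i in idx)):
                pairs.append((a, bases[bi]))
    return pairs
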