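"""Training knowledgebase: propensities, reference frames, geometric models.

Three artifacts are learned from protein-DNA complex structures:

1. A per-amino-acid DNA-binding propensity table — the fraction of residues
   of each type that lie within 4.5 A of DNA (an odds-ratio variant,
   normalized by background amino-acid frequency, is also provided).
2. Per-amino-acid reference frames — the three atoms of each type that touch
   the most distinct bases within 4 A, used to build a canonical residue-local
   coordinate system.
3. Up to 80 geometric models, one per (amino acid, base) pair, holding the
   frame-local coordinates of every base observed in contact with a binding
   residue of that type, plus a precomputed pairwise-RMSD matrix.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structio import (
    BASE_MOIETY_ATOMS as _BASE_ATOMS,
    BINDING_CUTOFF,
    CONTACT_CUTOFF,
    STANDARD_AMINO_ACIDS,
    ResidueRecord,
    StructureModel,
    atom_base_contacts,
    binding_residues,
)

__all__ = [
    "PropensityTable",
    "ReferenceFrameSpec",
    "BaseInstance",
    "GeometricModel",
    "Knowledgebase",
    "compute_propensities",
    "compute_reference_frames",
    "local_frame",
    "build_models",
    "pairwise_instance_rmsd",
    "build_knowledgebase",
    "save_kb",
    "load_kb",
    "DegenerateFrameError",
    "KnowledgebaseFormatError",
]

BASE_TYPES = ("A", "C", "G", "T")
FALLBACK_FRAME = ("CA", "C", "N")
KB_FORMAT_VERSION = 1
#: Minimum shared atoms for a finite instance-pair RMSD.
MIN_SHARED_ATOMS = 3


class DegenerateFrameError(ValueError):
    """Frame atoms are (near-)collinear; no canonical frame exists."""


class KnowledgebaseFormatError(ValueError):
    """Serialized knowledgebase is unreadable or version-incompatible."""


@dataclass
class PropensityTable:
    """Binding/total counts and ratio propensity per standard amino acid."""

    counts: dict  # aa -> (binding, total)

    def propensity(self, aa: str) -> float:
        binding, total = self.counts.get(aa, (0, 0))
        return binding / total if total else 0.0

    @property
    def mean_propensity(self) -> float:
        return sum(self.propensity(a) for a in sorted(STANDARD_AMINO_ACIDS)) / 20.0

    def odds_propensity(self, aa: str) -> float:
        """Alternative odds form: P(binding | aa) / P(binding overall)."""
        total_binding = sum(b for b, _ in self.counts.values())
        total = sum(t for _, t in self.counts.values())
        if not total or not total_binding:
            return 0.0
        background = total_binding / total
        return self.propensity(aa) / background


@dataclass
class ReferenceFrameSpec:
    """Top-3 contact atoms per amino-acid type, with their counts."""

    frames: dict  # aa -> (atom1, atom2, atom3)
    atom_counts: dict = field(default_factory=dict)  # aa -> {atom: n_bases}

    def frame(self, aa: str) -> tuple:
        return self.frames.get(aa, FALLBACK_FRAME)

    def top_atom(self, aa: str) -> str:
        return self.frame(aa)[0]


@dataclass
class BaseInstance:
    source_id: str
    base_key: tuple  # (chain, seq, icode) in the source structure
    base_type: str
    atom_names: list
    coords: np.ndarray  # (n_atoms, 3) in the residue-local frame

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)


@dataclass
class GeometricModel:
    amino_acid: str
    base_type: str
    instances: list = field(default_factory=list)
    pairwise_rmsd: np.ndarray | None = None


@dataclass
class Knowledgebase:
    propensities: PropensityTable
    frames: ReferenceFrameSpec
    models: dict  # (aa, base) -> GeometricModel
    provenance: dict = field(default_factory=dict)

    def model(self, aa: str, base: str) -> GeometricModel:
        return self.models.get((aa, base), GeometricModel(aa, base))


def compute_propensities(
    training, binding_cutoff: float = BINDING_CUTOFF
) -> PropensityTable:
    """Fraction of residues of each type binding DNA (< cutoff) in training."""
    training = list(training)
    if not training:
        raise ValueError("empty training set")
    counts = {aa: [0, 0] for aa in sorted(STANDARD_AMINO_ACIDS)}
    for s in training:
        bound = binding_residues(s, cutoff=binding_cutoff)
        for r in s.protein_residues:
            counts[r.res_type][1] += 1
            if r.key in bound:
                counts[r.res_type][0] += 1
    return PropensityTable({aa: tuple(v) for aa, v in counts.items()})


def compute_reference_frames(
    training, contact_cutoff: float = CONTACT_CUTOFF, base_moiety_only: bool = False
) -> ReferenceFrameSpec:
    """Rank each type's atoms by distinct bases contacted within the cutoff.

    Ties break lexicographically on the PDB atom name; a type observed with
    fewer than three distinct atom names falls back to (CA, C, N).
    """
    training = list(training)
    if not training:
        raise ValueError("empty training set")
    atom_counts: dict = defaultdict(Counter)
    seen_atoms: dict = defaultdict(set)
    for s in training:
        for r in s.protein_residues:
            for a in r.atoms:
                seen_atoms[r.res_type].add(a.name)
        for atom, base in atom_base_contacts(
            s, cutoff=contact_cutoff, base_moiety_only=base_moiety_only
        ):
            res = s.residue(atom.residue_key)
            atom_counts[res.res_type][atom.name] += 1
    frames = {}
    for aa in sorted(STANDARD_AMINO_ACIDS):
        atoms = seen_atoms.get(aa, set())
        if len(atoms) < 3:
            if atoms:
                warnings.warn(
                    f"{aa}: fewer than 3 atoms observed; using fallback frame "
                    f"{FALLBACK_FRAME}",
                    stacklevel=2,
                )
            frames[aa] = FALLBACK_FRAME
            continue
        counts = atom_counts.get(aa, Counter())
        ranked = sorted(atoms, key=lambda name: (-counts.get(name, 0), name))
        frames[aa] = tuple(ranked[:3])
    return ReferenceFrameSpec(
        frames=frames,
        atom_counts={aa: dict(c) for aa, c in atom_counts.items()},
    )


def local_frame(residue: ResidueRecord, spec: ReferenceFrameSpec):
    """World->local rigid transform from the residue's three frame atoms.

    Canonical frame: atom1 at the origin, atom2 on +x, atom3 in the xy
    half-plane with y > 0.  Returns ``(R, origin)`` such that
    ``x_local = R @ (x_world - origin)``; the inverse placement is
    ``x_world = R.T @ x_local + origin``.
    """
    names = spec.frame(residue.res_type)
    atoms = [residue.atom(n) for n in names]
    if any(a is None for a in atoms):
        missing = [n for n, a in zip(names, atoms) if a is None]
        raise KeyError(
            f"residue {residue.res_type} {residue.key} lacks frame atom(s) {missing}"
        )
    a1, a2, a3 = (a.coord for a in atoms)
    v12, v13 = a2 - a1, a3 - a1
    n12, n13 = np.linalg.norm(v12), np.linalg.norm(v13)
    if n12 < 1e-6 or n13 < 1e-6:
        raise DegenerateFrameError(f"coincident frame atoms in {residue.key}")
    cosang = abs(np.dot(v12, v13) / (n12 * n13))
    if cosang > np.cos(np.radians(1.0)):
        raise DegenerateFrameError(
            f"frame atoms of {residue.res_type} {residue.key} are collinear "
            f"(angle < 1 deg)"
        )
    e1 = v12 / n12
    e3 = np.cross(e1, v13)
    e3 /= np.linalg.norm(e3)
    e2 = np.cross(e3, e1)
    rot = np.vstack([e1, e2, e3])
    return rot, a1.copy()


def build_models(
    training,
    frames: ReferenceFrameSpec,
    contact_cutoff: float = CONTACT_CUTOFF,
    binding_cutoff: float = BINDING_CUTOFF,
    base_moiety_only: bool = False,
) -> dict:
    """Frame-local base clouds per (amino acid, base) pair.

    For every binding residue, each base residue with any atom within the
    contact cutoff contributes one instance: the base-moiety atoms of that
    nucleotide expressed in the residue's canonical local frame.
    """
    models: dict = {}
    for s in training:
        bound = binding_residues(s, cutoff=binding_cutoff)
        contacts_by_residue: dict = defaultdict(dict)
        for atom, base in atom_base_contacts(
            s, cutoff=contact_cutoff, base_moiety_only=base_moiety_only
        ):
            contacts_by_residue[atom.residue_key][base.key] = base
        for r in s.protein_residues:
            if r.key not in bound or r.key not in contacts_by_residue:
                continue
            try:
                rot, origin = local_frame(r, frames)
            except (KeyError, DegenerateFrameError) as exc:
                warnings.warn(f"skipping residue {r.key}: {exc}", stacklevel=2)
                continue
            for base in contacts_by_residue[r.key].values():
                b = base.base_type
                if b is None:
                    continue
                names = [a.name for a in base.atoms if a.name in _BASE_ATOMS]
                coords = np.array(
                    [a.coord for a in base.atoms if a.name in _BASE_ATOMS]
                ).reshape(-1, 3)
                if coords.size == 0:
                    names = [a.name for a in base.atoms]
                    coords = base.coords()
                local = (rot @ (coords - origin).T).T
                key = (r.res_type, b)
                model = models.setdefault(key, GeometricModel(r.res_type, b))
                model.instances.append(
                    BaseInstance(
                        source_id=s.id,
                        base_key=base.key,
                        base_type=b,
                        atom_names=names,
                        coords=local,
                    )
                )
    for model in models.values():
        model.pairwise_rmsd = pairwise_instance_rmsd(model)
    return models


def instance_rmsd(a: BaseInstance, b: BaseInstance) -> float:
    """RMSD over shared atom names, no re-superposition; inf if < 3 shared."""
    shared = [n for n in a.atom_names if n in b.atom_names]
    if len(shared) < MIN_SHARED_ATOMS:
        return float("inf")
    ia = [a.atom_names.index(n) for n in shared]
    ib = [b.atom_names.index(n) for n in shared]
    d = a.coords[ia] - b.coords[ib]
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def pairwise_instance_rmsd(m: GeometricModel) -> np.ndarray:
    n = len(m.instances)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = instance_rmsd(m.instances[i], m.instances[j])
    return out


def build_knowledgebase(
    training,
    contact_cutoff: float = CONTACT_CUTOFF,
    binding_cutoff: float = BINDING_CUTOFF,
    base_moiety_only: bool = False,
) -> Knowledgebase:
    training = list(training)
    props = compute_propensities(training, binding_cutoff=binding_cutoff)
    frames = compute_reference_frames(
        training, contact_cutoff=contact_cutoff, base_moiety_only=base_moiety_only
    )
    models = build_models(
        training,
        frames,
        contact_cutoff=contact_cutoff,
        binding_cutoff=binding_cutoff,
        base_moiety_only=base_moiety_only,
    )
    return Knowledgebase(
        propensities=props,
        frames=frames,
        models=models,
        provenance={
            "training": [s.id for s in training],
            "contact_cutoff": contact_cutoff,
            "binding_cutoff": binding_cutoff,
            "base_moiety_only": base_moiety_only,
        },
    )


def save_kb(kb: Knowledgebase, path) -> None:
    """Write the knowledgebase as meta.json + models.tsv in a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "version": KB_FORMAT_VERSION,
        "propensities": {aa: list(v) for aa, v in sorted(kb.propensities.counts.items())},
        "frames": {aa: list(v) for aa, v in sorted(kb.frames.frames.items())},
        "atom_counts": {
            aa: {k: int(v) for k, v in sorted(c.items())}
            for aa, c in sorted(kb.frames.atom_counts.items())
        },
        "provenance": kb.provenance,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    lines = ["amino_acid\tbase_type\tinstance\tsource\tbase_key\tatom\tx\ty\tz"]
    for (aa, b) in sorted(kb.models):
        model = kb.models[(aa, b)]
        for idx, inst in enumerate(model.instances):
            base_key = "{}:{}:{}".format(*inst.base_key)
            for name, xyz in zip(inst.atom_names, inst.coords):
                lines.append(
                    f"{aa}\t{b}\t{idx}\t{inst.source_id}\t{base_key}\t{name}"
                    f"\t{xyz[0]:.6f}\t{xyz[1]:.6f}\t{xyz[2]:.6f}"
                )
    (path / "models.tsv").write_text("\n".join(lines) + "\n")


def load_kb(path) -> Knowledgebase:
    path = Path(path)
    meta_file = path / "meta.json"
    tsv_file = path / "models.tsv"
    if not meta_file.exists() or not tsv_file.exists():
        raise KnowledgebaseFormatError(f"{path}: not a knowledgebase directory")
    try:
        meta = json.loads(meta_file.read_text())
    except json.JSONDecodeError as exc:
        raise KnowledgebaseFormatError(f"{meta_file}: {exc}") from exc
    if meta.get("version") != KB_FORMAT_VERSION:
        raise KnowledgebaseFormatError(
            f"{meta_file}: version {meta.get('version')!r} != {KB_FORMAT_VERSION}"
        )
    props = PropensityTable({aa: tuple(v) for aa, v in meta["propensities"].items()})
    frames = ReferenceFrameSpec(
        frames={aa: tuple(v) for aa, v in meta["frames"].items()},
        atom_counts=meta.get("atom_counts", {}),
    )
    raw: dict = defaultdict(lambda: defaultdict(list))
    lines = tsv_file.read_text().splitlines()
    header = "amino_acid\tbase_type\tinstance\tsource\tbase_key\tatom\tx\ty\tz"
    if not lines or lines[0] != header:
        raise KnowledgebaseFormatError(f"{tsv_file}: line 1: bad header")
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != 9:
            raise KnowledgebaseFormatError(
                f"{tsv_file}: line {lineno}: expected 9 fields, got {len(parts)}"
            )
        aa, b, idx, source, base_key, atom, x, y, z = parts
        try:
            raw[(aa, b)][int(idx)].append(
                (source, base_key, atom, float(x), float(y), float(z))
            )
        except ValueError as exc:
            raise KnowledgebaseFormatError(
                f"{tsv_file}: line {lineno}: {exc}"
            ) from exc
    models = {}
    for key, inst_map in raw.items():
        aa, b = key
        model = GeometricModel(aa, b)
        for idx in sorted(inst_map):
            rows = inst_map[idx]
            chain, seq, icode = rows[0][1].split(":")
            model.instances.append(
                BaseInstance(
                    source_id=rows[0][0],
                    base_key=(chain, int(seq), icode),
                    base_type=b,
                    atom_names=[r[2] for r in rows],
                    coords=np.array([[r[3], r[4], r[5]] for r in rows]),
                )
            )
        model.pairwise_rmsd = pairwise_instance_rmsd(model)
        models[key] = model
    return Knowledgebase(
        propensities=props, frames=frames, models=models,
        provenance=meta.get("provenance", {}),
    )
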