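"""Base-location prediction around a DBU.

Every knowledgebase model instance matching a DBU residue's type is mapped
from that residue's local frame into query coordinates; the resulting base
positions are the sampling space.  A Gaussian density (normalized per
amino-acid type within the DBU) scores each candidate, a protein-core score
over CA atoms plus a 2 A clash stop prunes buried candidates, and a greedy
RMSD > 5 A scan keeps a diverse ranked list, highest density first.

The density and core scores are each isolated behind a single function with
a configurable kernel width so the functional form can be swapped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .knowledgebase import Knowledgebase, local_frame
from .structio import StructureModel

__all__ = [
    "DensityParams",
    "BasePlacement",
    "PredictionResult",
    "place_models",
    "density_score",
    "core_scores",
    "core_filter",
    "diverse_select",
    "predict_base_location",
]


@dataclass
class DensityParams:
    kernel_sigma: float = 2.0
    core_sigma: float = 5.0
    clash_distance: float = 2.0
    diversity_rmsd: float = 5.0

    def __post_init__(self) -> None:
        for name in ("kernel_sigma", "core_sigma", "clash_distance", "diversity_rmsd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class BasePlacement:
    base_type: str
    model_key: tuple  # (amino acid, base)
    instance_index: int
    residue_key: tuple  # DBU residue whose frame placed this instance
    atom_names: list
    coords: np.ndarray  # world coordinates, (n_atoms, 3)
    placement_id: int = 0
    density: float = 0.0
    core_score: float = 0.0
    min_protein_distance: float = float("inf")

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)


@dataclass
class PredictionResult:
    placements: list = field(default_factory=list)
    status: str = "ok"

    @property
    def best(self):
        return self.placements[0] if self.placements else None


def _gauss(d2: np.ndarray, sigma: float) -> np.ndarray:
    return np.exp(-d2 / (2.0 * sigma * sigma))


def place_models(dbu, s: StructureModel, kb: Knowledgebase, base_type: str) -> list:
    """Map model instances of each DBU residue's type into world coordinates."""
    placements = []
    pid = 0
    for key in sorted(dbu.residues):
        r = s.residue(key)
        model = kb.model(r.res_type, base_type)
        if not model.instances:
            continue
        try:
            rot, origin = local_frame(r, kb.frames)
        except Exception as exc:
            warnings.warn(f"no local frame for residue {key}: {exc}", stacklevel=2)
            continue
        for idx, inst in enumerate(model.instances):
            world = (rot.T @ inst.coords.T).T + origin
            placements.append(
                BasePlacement(
                    base_type=base_type,
                    model_key=(r.res_type, base_type),
                    instance_index=idx,
                    residue_key=key,
                    atom_names=list(inst.atom_names),
                    coords=world,
                    placement_id=pid,
                )
            )
            pid += 1
    if not placements:
        warnings.warn(
            f"no model instances available for base {base_type} and this DBU",
            stacklevel=2,
        )
    return placements


def density_score(x, placements, dbu, s: StructureModel, params: DensityParams) -> float:
    """Gaussian-sum density at point ``x`` over all placed base atoms.

    Each DBU residue r contributes its placed atoms weighted by
    1 / (number of DBU residues of type aa(r)); the kernel has unit peak.
    """
    x = np.asarray(x, dtype=float)
    type_counts: dict = {}
    for key in dbu.residues:
        t = s.residue(key).res_type
        type_counts[t] = type_counts.get(t, 0) + 1
    total = 0.0
    for p in placements:
        aa = s.residue(p.residue_key).res_type
        n = type_counts.get(aa, 1)
        d2 = np.sum((p.coords - x) ** 2, axis=1)
        total += float(np.sum(_gauss(d2, params.kernel_sigma))) / n
    return total


def core_scores(points: np.ndarray, s: StructureModel, params: DensityParams) -> np.ndarray:
    """Gaussian-sum burial score of each point against the protein CA atoms."""
    ca = np.array(
        [a.coord for r in s.protein_residues for a in r.atoms if a.name == "CA"]
    ).reshape(-1, 3)
    if ca.size == 0:
        raise ValueError("query protein has no CA atoms")
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    d2 = np.sum((points[:, None, :] - ca[None, :, :]) ** 2, axis=2)
    return _gauss(d2, params.core_sigma).sum(axis=1)


def core_filter(placements, s: StructureModel, params: DensityParams) -> list:
    """Keep placements from least to most buried; stop at the first clash.

    A placement's core score is the max over its atoms; iteration runs in
    ascending core order (stable on placement id) and terminates permanently
    at the first placement whose minimum distance to any protein atom is
    below ``clash_distance`` (that placement is excluded too).
    """
    if not placements:
        return []
    protein = s.coords_of("protein")
    tree = cKDTree(protein) if protein.size else None
    for p in placements:
        p.core_score = float(np.max(core_scores(p.coords, s, params)))
        if tree is not None:
            d, _ = tree.query(p.coords, k=1)
            p.min_protein_distance = float(np.min(d))
    ordered = sorted(placements, key=lambda p: (p.core_score, p.placement_id))
    kept = []
    for p in ordered:
        if p.min_protein_distance < params.clash_distance:
            break
        kept.append(p)
    return kept


def placement_rmsd(a: BasePlacement, b: BasePlacement) -> float:
    """World-coordinate RMSD over shared atom names; inf if < 3 shared."""
    shared = [n for n in a.atom_names if n in b.atom_names]
    if len(shared) < 3:
        return float("inf")
    ia = [a.atom_names.index(n) for n in shared]
    ib = [b.atom_names.index(n) for n in shared]
    d = a.coords[ia] - b.coords[ib]
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def diverse_select(placements, params: DensityParams) -> list:
    """Greedy diversity scan in descending density (stable on placement id).

    A placement is kept iff its RMSD to every previously kept placement
    exceeds ``diversity_rmsd``; the first kept element is the prediction.
    """
    ordered = sorted(placements, key=lambda p: (-p.density, p.placement_id))
    kept: list = []
    for p in ordered:
        if all(placement_rmsd(p, q) > params.diversity_rmsd for q in kept):
            kept.append(p)
    return kept


def predict_base_location(
    dbu,
    s: StructureModel,
    kb: Knowledgebase,
    base_type: str,
    params: DensityParams | None = None,
) -> PredictionResult:
    """place_models -> core_filter -> density at centroids -> diverse_select."""
    params = params or DensityParams()
    placements = place_models(dbu, s, kb, base_type)
    if not placements:
        return PredictionResult(status="no-models")
    surviving = core_filter(placements, s, params)
    if not surviving:
        return PredictionResult(status="all-clashing")
    for p in surviving:
        p.density = density_score(p.centroid, placements, dbu, s, params)
    return PredictionResult(placements=diverse_select(surviving, params))
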