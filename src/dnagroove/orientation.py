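"""Groove-tangent direction prediction by PCA over DBU representative atoms.

Each DBU residue contributes up to three points: its type's top
DNA-contacting atom (rank-1 reference-frame atom) plus the backbone CA and
C.  The first principal axis of the pooled points is reported as an
undirected line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import canonical_direction
from .knowledgebase import ReferenceFrameSpec
from .structio import StructureModel

__all__ = [
    "OrientationPrediction",
    "InsufficientPointsError",
    "representative_atoms",
    "pca_direction",
    "predict_orientation",
]


class InsufficientPointsError(ValueError):
    """Fewer than three usable representative atoms in the DBU."""


@dataclass
class OrientationPrediction:
    anchor: np.ndarray
    direction: np.ndarray  # unit, canonical sign
    explained_fraction: float


def representative_atoms(dbu, s: StructureModel, frames: ReferenceFrameSpec) -> np.ndarray:
    """Up to 3 points per DBU residue: top-propensity atom, CA, C."""
    points = []
    for key in sorted(dbu.residues):
        r = s.residue(key)
        wanted = [frames.top_atom(r.res_type), "CA", "C"]
        seen = set()
        for name in wanted:
            if name in seen:
                continue
            seen.add(name)
            a = r.atom(name)
            if a is None:
                warnings.warn(
                    f"residue {r.res_type} {key} missing atom {name}; skipped",
                    stacklevel=2,
                )
                continue
            points.append(a.coord)
    if len(points) < 3:
        raise InsufficientPointsError(
            f"only {len(points)} representative atoms; need at least 3"
        )
    return np.array(points)


def pca_direction(points: np.ndarray) -> OrientationPrediction:
    """First principal axis of a point cloud as an undirected line."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) < 3:
        raise InsufficientPointsError("need at least 3 points")
    anchor = points.mean(axis=0)
    centered = points - anchor
    if not np.any(np.abs(centered) > 1e-12):
        raise InsufficientPointsError("all points coincident")
    cov = centered.T @ centered / len(points)
    eigvals, eigvecs = np.linalg.eigh(cov)  # ascending
    if eigvals[2] - eigvals[1] < 1e-9:
        warnings.warn(
            "degenerate principal direction (top two eigenvalues equal)",
            stacklevel=2,
        )
    direction = canonical_direction(eigvecs[:, 2])
    explained = float(eigvals[2] / eigvals.sum())
    return OrientationPrediction(
        anchor=anchor, direction=direction, explained_fraction=explained
    )


def predict_orientation(dbu, s: StructureModel, frames: ReferenceFrameSpec) -> OrientationPrediction:
    return pca_direction(representative_atoms(dbu, s, frames))
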