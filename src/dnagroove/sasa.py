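"""Shrake-Rupley solvent accessibility and RSA normalization.

Sphere points are a deterministic golden-section spiral; van der Waals radii
cover the heavy atoms found in protein/DNA structures.  RSA uses the
Tien et al. (2013) theoretical maximum accessible areas.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["shrake_rupley", "residue_sasa", "relative_accessibility", "MAX_ACC"]

PROBE_RADIUS = 1.4
N_SPHERE_POINTS = 256

VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "SE": 1.90,
}
DEFAULT_VDW = 1.70

#: Theoretical maximum accessible surface area per residue type (A^2),
#: Tien et al. 2013.
MAX_ACC = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


def _sphere_points(n: int) -> np.ndarray:
    k = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    theta = phi * k
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def shrake_rupley(
    coords: np.ndarray,
    elements,
    probe: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
) -> np.ndarray:
    """Per-atom accessible surface area (A^2)."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    radii = np.array(
        [VDW_RADII.get(str(e).upper(), DEFAULT_VDW) + probe for e in elements]
    )
    if len(radii) != len(coords):
        raise ValueError("coords and elements length mismatch")
    sphere = _sphere_points(n_points)
    tree = cKDTree(coords)
    out = np.zeros(len(coords))
    max_r = radii.max() if len(radii) else 0.0
    for i, (c, r) in enumerate(zip(coords, radii)):
        pts = c + r * sphere
        neighbors = [j for j in tree.query_ball_point(c, r + max_r) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d = np.linalg.norm(pts - coords[j], axis=1)
            accessible &= d >= radii[j]
        out[i] = 4.0 * np.pi * r * r * accessible.mean()
    return out


def residue_sasa(structure, protein_only: bool = True) -> dict:
    """SASA per residue key, computed over the protein atoms only by default."""
    residues = structure.protein_residues if protein_only else structure.residues
    coords, elements, owner = [], [], []
    for r in residues:
        for a in r.atoms:
            coords.append(a.coord)
            elements.append(a.element)
            owner.append(r.key)
    if not coords:
        return {}
    areas = shrake_rupley(np.array(coords), elements)
    out: dict = {}
    for key, area in zip(owner, areas):
        out[key] = out.get(key, 0.0) + float(area)
    return out


def relative_accessibility(structure, protein_only: bool = True) -> dict:
    """RSA per protein residue; residues without a reference maximum are skipped."""
    sasa = residue_sasa(structure, protein_only=protein_only)
    out = {}
    for r in structure.protein_residues:
        ref = MAX_ACC.get(r.res_type)
        if ref is None or r.key not in sasa:
            continue
        out[r.key] = sasa[r.key] / ref
    return out
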