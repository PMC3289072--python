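"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths (KD-trees, scipy linkage, eigh on
covariance) used by the package: plain double loops, naive agglomeration,
and SVD.
"""

from __future__ import annotations

import math

import numpy as np


def brute_binding_residues(s, cutoff: float) -> set:
    dna_atoms = [a for r in s.residues if r.kind == "dna" for a in r.atoms]
    out = set()
    for r in s.residues:
        if r.kind != "protein":
            continue
        for a in r.atoms:
            for b in dna_atoms:
                if math.dist(a.coord, b.coord) < cutoff:
                    out.add(r.key)
                    break
            else:
                continue
            break
    return out


def brute_atom_base_contacts(s, cutoff: float, base_moiety_only: bool = False) -> set:
    """Set of (protein atom serial, base residue key) pairs."""
    from dnagroove.structio import BASE_MOIETY_ATOMS

    out = set()
    for rp in s.residues:
        if rp.kind != "protein":
            continue
        for a in rp.atoms:
            for rb in s.residues:
                if rb.kind != "dna":
                    continue
                atoms = rb.atoms
                if base_moiety_only:
                    sub = [x for x in atoms if x.name in BASE_MOIETY_ATOMS]
                    atoms = sub or atoms
                if any(math.dist(a.coord, x.coord) <= cutoff for x in atoms):
                    out.add((a.serial, rb.key))
    return out


def brute_average_linkage(coords: np.ndarray, stop: float) -> set:
    """Naive agglomeration; returns partition as a set of frozensets."""
    coords = np.asarray(coords, dtype=float)
    clusters = [frozenset([i]) for i in range(len(coords))]

    def avg(c1, c2):
        return float(
            np.mean([math.dist(coords[i], coords[j]) for i in c1 for j in c2])
        )

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = avg(clusters[i], clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        if d > stop:
            break
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return set(clusters)


def brute_pca_direction(points: np.ndarray) -> np.ndarray:
    """First principal axis via SVD of the centered point matrix."""
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0]


def brute_rmsd(names_a, coords_a, names_b, coords_b) -> float:
    shared = [n for n in names_a if n in names_b]
    if len(shared) < 3:
        return float("inf")
    total = 0.0
    for n in shared:
        pa = coords_a[list(names_a).index(n)]
        pb = coords_b[list(names_b).index(n)]
        total += math.dist(pa, pb) ** 2
    return math.sqrt(total / len(shared))


def brute_density(x, placements, dbu, s, sigma: float) -> float:
    type_counts = {}
    for key in dbu.residues:
        t = s.residue(key).res_type
        type_counts[t] = type_counts.get(t, 0) + 1
    total = 0.0
    for p in placements:
        aa = s.residue(p.residue_key).res_type
        n = type_counts[aa]
        for atom in p.coords:
            d = math.dist(x, atom)
            total += math.exp(-d * d / (2.0 * sigma * sigma)) / n
    return total
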