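"""DNA-binding unit (DBU) discovery.

Pipeline: take a conserved-residue list for the query chain, keep the
solvent-exposed ones (RSA > 0.25 by default), cluster their atoms by
average-linkage agglomeration cut at 11 A, resolve split residues by
majority vote, and keep clusters whose summed propensity beats the
size x mean-propensity expectation, ranked by score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .knowledgebase import PropensityTable
from .sasa import relative_accessibility
from .structio import StructureModel

__all__ = [
    "ConservedSet",
    "DBU",
    "surface_filter",
    "cluster_atoms",
    "rank_dbus",
    "find_dbus",
    "read_conserved_file",
    "RSA_CUTOFF",
    "CLUSTER_STOP",
]

RSA_CUTOFF = 0.25
CLUSTER_STOP = 11.0


@dataclass
class ConservedSet:
    keys: set
    source: str = "all-residues"

    @classmethod
    def all_residues(cls, s: StructureModel, chain: str | None = None) -> "ConservedSet":
        keys = {
            r.key
            for r in s.protein_residues
            if chain is None or r.chain_id == chain
        }
        return cls(keys=keys, source="all-residues")

    def validate(self, s: StructureModel) -> None:
        missing = [k for k in self.keys if k not in s]
        if missing:
            raise KeyError(f"conserved residues absent from structure: {sorted(missing)}")


@dataclass
class DBU:
    residues: frozenset
    score: float
    expectation: float
    centroid: np.ndarray
    rank: int = 0
    members: list = field(default_factory=list)  # sorted residue keys


def read_conserved_file(path, s: StructureModel) -> ConservedSet:
    """Parse 'chain:resseq[:icode]' lines into a ConservedSet."""
    keys = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(":")
        if len(parts) not in (2, 3):
            raise ValueError(f"{path}: line {lineno}: expected chain:resseq[:icode]")
        chain, seq = parts[0], int(parts[1])
        icode = parts[2] if len(parts) == 3 else ""
        keys.add((chain, seq, icode))
    cs = ConservedSet(keys=keys, source=str(path))
    cs.validate(s)
    return cs


def surface_filter(
    s: StructureModel,
    conserved: ConservedSet,
    rsa_cutoff: float = RSA_CUTOFF,
    rsa: dict | None = None,
) -> set:
    """Conserved residues with RSA strictly above the cutoff.

    ``rsa`` may supply precomputed values (e.g. parsed from a DSSP file);
    otherwise an internal Shrake-Rupley pass over the protein atoms is used.
    Residues without an RSA value are dropped with a warning.
    """
    conserved.validate(s)
    if rsa is None:
        rsa = relative_accessibility(s)
    out = set()
    for key in conserved.keys:
        if key not in rsa:
            warnings.warn(f"no RSA available for residue {key}; dropped", stacklevel=2)
            continue
        if rsa[key] > rsa_cutoff:
            out.add(key)
    return out


def _atom_cluster_labels(coords: np.ndarray, stop_distance: float) -> np.ndarray:
    """Average-linkage labels; merges with linkage > stop_distance not applied."""
    n = len(coords)
    if n == 1:
        return np.zeros(1, dtype=int)
    z = linkage(pdist(coords), method="average")
    return fcluster(z, t=stop_distance, criterion="distance")


def cluster_atoms(
    s: StructureModel, residues, stop_distance: float = CLUSTER_STOP
) -> list:
    """Cluster residues via average-linkage agglomeration of their atoms.

    Atoms are merged in ascending linkage order until the next merge would
    exceed ``stop_distance``.  A residue whose atoms land in several atom
    clusters is assigned by majority vote; ties go to the cluster holding
    its CA, then to the larger cluster, then to the smaller cluster label.
    Returns a list of sorted residue-key lists (deterministic order).
    """
    keys = sorted(residues)
    if not keys:
        return []
    coords, owner, ca_label_idx = [], [], {}
    for key in keys:
        r = s.residue(key)
        for a in r.atoms:
            if a.name == "CA":
                ca_label_idx[key] = len(coords)
            coords.append(a.coord)
            owner.append(key)
    labels = _atom_cluster_labels(np.asarray(coords), stop_distance)
    cluster_sizes = {lab: int(np.sum(labels == lab)) for lab in set(labels)}
    assignment = {}
    for key in keys:
        votes: dict = {}
        for lab, k in zip(labels, owner):
            if k == key:
                votes[lab] = votes.get(lab, 0) + 1
        best = max(votes.values())
        tied = sorted(lab for lab, v in votes.items() if v == best)
        if len(tied) > 1 and key in ca_label_idx:
            ca_lab = labels[ca_label_idx[key]]
            if ca_lab in tied:
                tied = [ca_lab]
        if len(tied) > 1:
            tied.sort(key=lambda lab: (-cluster_sizes[lab], lab))
        assignment[key] = tied[0]
    clusters: dict = {}
    for key, lab in assignment.items():
        clusters.setdefault(lab, []).append(key)
    out = [sorted(v) for v in clusters.values()]
    out.sort(key=lambda c: c[0])
    return out


def rank_dbus(clusters, prop: PropensityTable, s: StructureModel) -> list:
    """Score clusters and keep those strictly above expectation.

    score = sum of member propensities; expectation = size x mean propensity
    over the 20 standard types.  Sorted by score descending; ties prefer the
    larger cluster, then the smallest member key.
    """
    mean = prop.mean_propensity
    accepted = []
    for members in clusters:
        score = sum(prop.propensity(s.residue(k).res_type) for k in members)
        expectation = len(members) * mean
        if score > expectation:
            coords = np.vstack([s.residue(k).coords() for k in members])
            accepted.append(
                DBU(
                    residues=frozenset(members),
                    score=score,
                    expectation=expectation,
                    centroid=coords.mean(axis=0),
                    members=sorted(members),
                )
            )
    accepted.sort(key=lambda d: (-d.score, -len(d.residues), d.members[0]))
    for i, d in enumerate(accepted, start=1):
        d.rank = i
    return accepted


def find_dbus(
    s: StructureModel,
    conserved: ConservedSet,
    prop: PropensityTable,
    rsa_cutoff: float = RSA_CUTOFF,
    stop_distance: float = CLUSTER_STOP,
    rsa: dict | None = None,
) -> list:
    """surface_filter -> cluster_atoms -> rank_dbus composition."""
    surf = surface_filter(s, conserved, rsa_cutoff=rsa_cutoff, rsa=rsa)
    if not surf:
        return []
    clusters = cluster_atoms(s, surf, stop_distance=stop_distance)
    return rank_dbus(clusters, prop, s)
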