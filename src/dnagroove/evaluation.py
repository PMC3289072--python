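"""Scoring predictions against a reference protein-DNA complex.

Conventions: a predicted base location is compared to the centroid of the
closest base (failure beyond 6 A); the reference groove tangent is the
chord of backbone phosphates i-3 -> i-4 (major groove; i -> i+1 for the
minor groove) on either strand, with the better-matching strand reported;
orientation error is the undirected angle, successful below cos > 0.9
(~25.8 deg).  Residue-level precision/sensitivity use the 4.5 A contact
definition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import canonical_direction, angle_between_lines, unit
from .structio import BINDING_CUTOFF, StructureModel, binding_residues

__all__ = [
    "EvaluationResult",
    "LOCATION_FAILURE_CUTOFF",
    "ORIENTATION_SUCCESS_COSINE",
    "location_error",
    "reference_tangent",
    "orientation_error",
    "residue_metrics",
    "evaluate_prediction",
]

LOCATION_FAILURE_CUTOFF = 6.0
ORIENTATION_SUCCESS_COSINE = 0.9


@dataclass
class EvaluationResult:
    location_error: float
    success_location: bool
    groove_type: str  # "major" | "minor" | "NA"
    orientation_error: float | None  # degrees in [0, 90], None when NA
    success_orientation: bool | None


def location_error(pred, ref: StructureModel) -> float:
    """Distance from the predicted centroid to the nearest base centroid."""
    centroid = pred.centroid if hasattr(pred, "centroid") else np.asarray(pred, float)
    bases = ref.dna_residues
    if not bases:
        raise ValueError("reference structure contains no DNA")
    centroids = np.array([b.base_centroid() for b in bases])
    return float(np.min(np.linalg.norm(centroids - centroid, axis=1)))


def _dna_chains(ref: StructureModel) -> dict:
    """Ordered nucleotide lists per chain (author 5'->3' order)."""
    chains: dict = {}
    for r in ref.dna_residues:
        chains.setdefault(r.chain_id, []).append(r)
    return chains


def _pair_partner(ref: StructureModel, nucleotide):
    """Nearest base (ring-centroid) on another chain: the Watson-Crick mate."""
    c = nucleotide.base_centroid()
    best, best_d = None, np.inf
    for r in ref.dna_residues:
        if r.chain_id == nucleotide.chain_id:
            continue
        d = float(np.linalg.norm(r.base_centroid() - c))
        if d < best_d:
            best, best_d = r, d
    return best


def _phosphate_chord(chain_list, pos_a: int, pos_b: int):
    if pos_a < 0 or pos_b < 0 or pos_a >= len(chain_list) or pos_b >= len(chain_list):
        return None
    pa = chain_list[pos_a].atom("P")
    pb = chain_list[pos_b].atom("P")
    if pa is None or pb is None:
        return None
    return canonical_direction(pb.coord - pa.coord)


def reference_tangent(ref: StructureModel, dbu) -> tuple:
    """(groove_type, candidate tangents) for the DBU's center base pair.

    The center pair is the DBU-contacted pair whose centroid lies nearest
    the DBU centroid (ties: smaller chain/seq).  Groove type compares the
    DBU centroid against the two groove-floor points derived from the
    pair's phosphates: the narrow-groove point is the P(i)/P(j) midpoint
    and the wide-groove point is its reflection through the pair centroid.
    Candidates come from both strands; callers report the better one.
    """
    dbu_coords = np.vstack([ref.residue(k).coords() for k in sorted(dbu.residues)])
    dbu_centroid = dbu_coords.mean(axis=0)
    chains = _dna_chains(ref)
    if not chains:
        raise ValueError("reference structure contains no DNA")

    # bases contacted by the DBU (any atom within the binding cutoff)
    contacted = []
    for r in ref.dna_residues:
        d = np.min(
            np.linalg.norm(
                r.coords()[:, None, :] - dbu_coords[None, :, :], axis=2
            )
        )
        if d < BINDING_CUTOFF:
            contacted.append(r)
    if not contacted:
        warnings.warn("DBU contacts no DNA in the reference; using nearest base",
                      stacklevel=2)
        contacted = sorted(
            ref.dna_residues,
            key=lambda r: float(np.min(np.linalg.norm(
                r.coords()[:, None, :] - dbu_coords[None, :, :], axis=2))),
        )[:1]

    best = None
    for r in sorted(contacted, key=lambda r: r.key):
        partner = _pair_partner(ref, r)
        if partner is None:
            continue
        pair_centroid = 0.5 * (r.base_centroid() + partner.base_centroid())
        d = float(np.linalg.norm(pair_centroid - dbu_centroid))
        if best is None or d < best[0] - 1e-12:
            best = (d, r, partner, pair_centroid)
    if best is None:
        warnings.warn("no base pair identifiable in reference", stacklevel=2)
        return "NA", []
    _, center, partner, pair_centroid = best

    p_i = center.atom("P")
    p_j = partner.atom("P")
    if p_i is None or p_j is None:
        warnings.warn(
            f"missing phosphate on pair {center.key}/{partner.key}; groove "
            f"type undetermined", stacklevel=2,
        )
        return "NA", []
    narrow_point = 0.5 * (p_i.coord + p_j.coord)
    wide_point = pair_centroid + (pair_centroid - narrow_point)
    groove = (
        "major"
        if np.linalg.norm(dbu_centroid - wide_point)
        <= np.linalg.norm(dbu_centroid - narrow_point)
        else "minor"
    )

    candidates = []
    for nucleotide in (center, partner):
        chain_list = chains[nucleotide.chain_id]
        pos = next(
            i for i, r in enumerate(chain_list) if r.key == nucleotide.key
        )
        if groove == "major":
            chord = _phosphate_chord(chain_list, pos - 3, pos - 4)
        else:
            chord = _phosphate_chord(chain_list, pos, pos + 1)
        if chord is None:
            warnings.warn(
                f"phosphates for tangent around {nucleotide.key} unavailable",
                stacklevel=2,
            )
            continue
        candidates.append(chord)
    if not candidates:
        return "NA", []
    return groove, candidates


def orientation_error(pred_direction, truth_direction) -> float:
    """Undirected angle between prediction and truth, degrees in [0, 90]."""
    return angle_between_lines(unit(pred_direction), unit(truth_direction))


def residue_metrics(
    predicted, ref: StructureModel, cutoff: float = BINDING_CUTOFF
) -> tuple:
    """(precision, sensitivity) of predicted residues vs true DNA contacts.

    Precision is 0 when nothing is predicted; sensitivity is None when the
    reference has no contact residues.
    """
    contacts = binding_residues(ref, cutoff=cutoff)
    predicted = set(predicted)
    tp = len(predicted & contacts)
    precision = tp / len(predicted) if predicted else 0.0
    sensitivity = tp / len(contacts) if contacts else None
    return precision, sensitivity


def evaluate_prediction(placement, orientation, dbu, ref: StructureModel) -> EvaluationResult:
    """Full per-DBU scorecard; orientation fields are NA when location fails."""
    err = location_error(placement, ref)
    ok_loc = err <= LOCATION_FAILURE_CUTOFF
    if not ok_loc:
        return EvaluationResult(err, False, "NA", None, None)
    groove, candidates = reference_tangent(ref, dbu)
    if not candidates:
        return EvaluationResult(err, True, groove, None, None)
    angle = min(orientation_error(orientation.direction, c) for c in candidates)
    ok_orient = np.cos(np.radians(angle)) > ORIENTATION_SUCCESS_COSINE
    return EvaluationResult(err, True, groove, angle, bool(ok_orient))
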