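"""Synthetic protein-DNA complexes with known ground truth.

Builds an idealized two-strand DNA duplex (constant rise/twist helix with
phosphate, C1' and base-ring pseudo-atoms) and plants small residue clusters
in a chosen groove, recording the true groove-tangent direction so that every
downstream stage (contacts, knowledgebase, clustering, orientation, base
placement, evaluation) can be exercised without any external data.

Geometry constants (documented, self-consistent rather than chemically
accurate):

* rise 3.38 A / twist 36 deg per base pair, helix along +z before the
  requested axis/origin are applied;
* phosphates at radius 8.9 A, azimuth +/-126 deg from the base-pair azimuth
  (strand X positive, strand Y negative).  This phase makes the two strands'
  wide-groove phosphate chords (residues i-3 -> i-4 and j-3 -> j-4) exactly
  parallel, both tangent to the wide-groove helix at azimuth offset 0;
* C1' at radius 5.2 A, azimuth +/-90 deg; base rings lie along the
  C1'--C1' chord so the paired ring centroids sit < 3 A apart near the axis;
* wide ("major") groove floor at azimuth offset 0 deg, narrow ("minor")
  floor at 180 deg.  The narrow-groove phosphate chords (i -> i+1, j -> j+1)
  straddle the groove tangent at roughly +/-30 deg by construction.

Strand X holds nucleotides 1..n 5'->3' in +z; strand Y is antiparallel with
residue j pairing base pair index i = n + 1 - j.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import canonical_direction, rotation_aligning, unit
from .structio import AtomRecord, ResidueRecord, StructureModel, StructureError

__all__ = [
    "HelixParams",
    "PlantedDBUSpec",
    "DBUGroundTruth",
    "build_bdna",
    "plant_dbu",
    "true_groove_tangent",
    "strip_dna",
    "write_ground_truth",
    "read_ground_truth",
    "MissingPhosphateError",
    "RISE",
    "TWIST",
    "P_RADIUS",
    "P_PHASE_DEG",
    "C1_RADIUS",
    "MAJOR_GROOVE_PHASE_DEG",
    "MINOR_GROOVE_PHASE_DEG",
]

RISE = 3.38
TWIST = 36.0
P_RADIUS = 8.9
P_PHASE_DEG = 126.0
C1_RADIUS = 5.2
C1_PHASE_DEG = 90.0
#: Azimuth offsets of the groove floors relative to the base-pair azimuth.
MAJOR_GROOVE_PHASE_DEG = 0.0
MINOR_GROOVE_PHASE_DEG = 180.0
#: Distance of a base-ring centroid from its own C1' along the C1'-C1' chord.
PURINE_CENTROID_OFFSET = 4.2
PYRIMIDINE_CENTROID_OFFSET = 3.7

#: Radial placement of planted residue atoms (groove-floor side).
TIP_RADIUS = 5.0
CB_RADIUS = 6.8
CA_RADIUS = 9.0
CA_C_BOND = 1.52
CA_N_BOND = 1.46

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PURINES = frozenset("AG")

# In-plane ring templates (u toward the partner C1', v perpendicular); each
# is centered on its ring centroid in build_bdna.
_PURINE_RING = {
    "N9": (0.0, 0.0),
    "C8": (1.1, 1.0),
    "N7": (2.4, 0.7),
    "C5": (2.5, -0.7),
    "C4": (1.2, -1.1),
    "N3": (1.5, -2.4),
    "C2": (2.8, -2.8),
    "N1": (3.9, -2.0),
    "C6": (3.8, -0.6),
}
_PYRIMIDINE_RING = {
    "N1": (0.0, 1.35),
    "C2": (1.17, 0.675),
    "N3": (1.17, -0.675),
    "C4": (0.0, -1.35),
    "C5": (-1.17, -0.675),
    "C6": (-1.17, 0.675),
}

#: Side-chain reference ("tip") atom planted per residue type.
TIP_ATOM = {
    "ARG": "NH1", "LYS": "NZ", "ASN": "ND2", "GLN": "NE2", "SER": "OG",
    "THR": "OG1", "TYR": "OH", "HIS": "NE2", "ASP": "OD1", "GLU": "OE1",
    "TRP": "NE1", "CYS": "SG", "MET": "SD", "PHE": "CZ", "LEU": "CD1",
    "ILE": "CD1", "VAL": "CG1", "PRO": "CG", "ALA": "CB", "GLY": "CA",
}


class MissingPhosphateError(KeyError):
    """A required backbone phosphate is absent from the duplex."""


@dataclass
class HelixParams:
    n_bp: int
    sequence: str = ""
    rise: float = RISE
    twist: float = TWIST
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if self.n_bp < 6:
            raise ValueError(f"duplex needs at least six base pairs, got {self.n_bp}")
        if not self.sequence:
            self.sequence = ("ACGT" * ((self.n_bp + 3) // 4))[: self.n_bp]
        self.sequence = self.sequence.upper()
        if len(self.sequence) != self.n_bp:
            raise ValueError("sequence length must equal n_bp")
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"sequence must be over ACGT: {self.sequence!r}")
        self.axis = unit(np.asarray(self.axis, dtype=float))
        self.origin = np.asarray(self.origin, dtype=float)


@dataclass
class PlantedDBUSpec:
    residue_types: list
    groove: str = "major"
    center_bp: int = 8
    offset: float = 0.0
    jitter_sd: float = 0.0
    seed: int = 0
    #: Spacing of consecutive planted residues along the groove, in base-pair
    #: units; < 1 keeps a whole DBU compact under the 11 A clustering stop.
    spacing: float = 0.7

    def __post_init__(self) -> None:
        if self.groove not in ("major", "minor"):
            raise ValueError(f"groove must be 'major' or 'minor', got {self.groove!r}")
        if not self.residue_types:
            raise ValueError("residue_types must be non-empty")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")


@dataclass
class DBUGroundTruth:
    residue_keys: list
    center_bp: int
    groove: str
    tangent: np.ndarray
    seed: int

    def to_dict(self) -> dict:
        return {
            "residue_keys": [list(k) for k in self.residue_keys],
            "center_bp": self.center_bp,
            "groove": self.groove,
            "tangent": [float(x) for x in self.tangent],
            "seed": self.seed,
        }


def _frame(params: HelixParams):
    """Rotation + translation placing the canonical +z helix on the axis."""
    rot = rotation_aligning(np.array([0.0, 0.0, 1.0]), params.axis)
    return rot, params.origin


def _bp_azimuth(params: HelixParams, i: int) -> float:
    """Base-pair azimuth (radians) for 1-based pair index ``i``."""
    return np.radians((i - 1) * params.twist)


def _bp_z(params: HelixParams, i: int) -> float:
    return (i - 1) * params.rise


def _cyl(radius: float, azimuth: float, z: float) -> np.ndarray:
    return np.array([radius * np.cos(azimuth), radius * np.sin(azimuth), z])


def _nucleotide_atoms(params: HelixParams, i: int, strand: int) -> tuple:
    """Atoms (canonical frame) and base letter for pair i on strand +1/-1."""
    theta = _bp_azimuth(params, i)
    z = _bp_z(params, i)
    sgn = 1.0 if strand > 0 else -1.0
    base = params.sequence[i - 1] if strand > 0 else COMPLEMENT[params.sequence[i - 1]]
    p = _cyl(P_RADIUS, theta + sgn * np.radians(P_PHASE_DEG), z)
    c1 = _cyl(C1_RADIUS, theta + sgn * np.radians(C1_PHASE_DEG), z)
    partner_c1 = _cyl(C1_RADIUS, theta - sgn * np.radians(C1_PHASE_DEG), z)
    u = unit(partner_c1 - c1)
    v = np.cross(np.array([0.0, 0.0, sgn]), u)
    ring = _PURINE_RING if base in PURINES else _PYRIMIDINE_RING
    d = PURINE_CENTROID_OFFSET if base in PURINES else PYRIMIDINE_CENTROID_OFFSET
    pts = np.array(list(ring.values()), dtype=float)
    pts -= pts.mean(axis=0)
    atoms = [("P", p, "P"), ("C1'", c1, "C")]
    centroid = c1 + d * u
    for name, (du, dv) in zip(ring.keys(), pts):
        atoms.append((name, centroid + du * u + dv * v, name[0]))
    return atoms, base


def build_bdna(params: HelixParams) -> StructureModel:
    """Idealized antiparallel duplex; strand X = chain 'X', strand Y = 'Y'.

    Strand X nucleotide ``i`` (1-based) pairs with strand Y nucleotide
    ``n_bp + 1 - i``.
    """
    rot, origin = _frame(params)
    residues = []
    serial = 0
    base_name = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}
    for i in range(1, params.n_bp + 1):
        atoms, base = _nucleotide_atoms(params, i, +1)
        recs = []
        for name, coord, elem in atoms:
            serial += 1
            recs.append(AtomRecord(serial, name, elem, rot @ coord + origin))
        residues.append(ResidueRecord("X", i, base_name[base], "", recs))
    for j in range(1, params.n_bp + 1):
        i = params.n_bp + 1 - j
        atoms, base = _nucleotide_atoms(params, i, -1)
        recs = []
        for name, coord, elem in atoms:
            serial += 1
            recs.append(AtomRecord(serial, name, elem, rot @ coord + origin))
        residues.append(ResidueRecord("Y", j, base_name[base], "", recs))
    model = StructureModel(id=f"bdna{params.n_bp}", residues=residues)
    model.helix_params = params
    return model


def _helix_params_of(dna: StructureModel) -> HelixParams:
    params = getattr(dna, "helix_params", None)
    if params is None:
        raise StructureError("structure was not produced by build_bdna")
    return params


def true_groove_tangent(dna: StructureModel, center_bp: int, groove: str) -> tuple:
    """Ground-truth groove tangents from backbone phosphates.

    Major groove: chords P(i-3) -> P(i-4) on strand X and P(j-3) -> P(j-4)
    on strand Y (j = n+1-i).  Minor groove: P(i) -> P(i+1) and
    P(j) -> P(j+1).  Returns a pair of unit vectors (one per strand) with
    canonical sign; on this ideal duplex the major-groove pair is parallel.
    """
    params = _helix_params_of(dna)
    n = params.n_bp
    j = n + 1 - center_bp
    if groove == "major":
        picks = [("X", center_bp - 3, center_bp - 4), ("Y", j - 3, j - 4)]
    elif groove == "minor":
        picks = [("X", center_bp, center_bp + 1), ("Y", j, j + 1)]
    else:
        raise ValueError(f"unknown groove {groove!r}")
    out = []
    for chain, a, b in picks:
        pa = _phosphate(dna, chain, a)
        pb = _phosphate(dna, chain, b)
        out.append(canonical_direction(pb - pa))
    return tuple(out)


def _phosphate(dna: StructureModel, chain: str, seq: int) -> np.ndarray:
    key = (chain, seq, "")
    if key not in dna:
        raise MissingPhosphateError(f"nucleotide {chain}:{seq} absent from duplex")
    atom = dna.residue(key).atom("P")
    if atom is None:
        raise MissingPhosphateError(f"nucleotide {chain}:{seq} has no phosphate")
    return atom.coord


def _groove_phase(groove: str) -> float:
    return np.radians(
        MAJOR_GROOVE_PHASE_DEG if groove == "major" else MINOR_GROOVE_PHASE_DEG
    )


def groove_floor_point(dna: StructureModel, bp: int, groove: str, radius: float = TIP_RADIUS) -> np.ndarray:
    """Point on the groove floor at base pair ``bp`` (world coordinates)."""
    params = _helix_params_of(dna)
    rot, origin = _frame(params)
    az = _bp_azimuth(params, bp) + _groove_phase(groove)
    return rot @ _cyl(radius, az, _bp_z(params, bp)) + origin


def plant_dbu(dna: StructureModel, spec: PlantedDBUSpec) -> tuple:
    """Append a residue cluster tracking one groove; returns (model, truth).

    Residues are laid consecutively along the groove around ``center_bp``,
    one per entry of ``spec.residue_types``.  Each gets N/CA/C backbone-like
    atoms at the groove rim, a CB, and a type-specific tip atom pointing at
    the groove floor, all jittered by ``spec.jitter_sd`` (seeded).  The
    input model is not modified.
    """
    params = _helix_params_of(dna)
    k = len(spec.residue_types)
    first = spec.center_bp - spec.spacing * (k - 1) / 2.0
    last = first + spec.spacing * (k - 1)
    lo = 5 if spec.groove == "major" else 1
    hi = params.n_bp if spec.groove == "major" else params.n_bp - 1
    if first < lo or last > hi or not (1 <= spec.center_bp <= params.n_bp):
        raise ValueError(
            f"planted DBU spans base pairs {first:.1f}..{last:.1f}, outside the "
            f"usable range {lo}..{hi} of a {params.n_bp}-bp duplex"
        )
    rng = np.random.default_rng(spec.seed)
    rot, origin = _frame(params)
    phase = _groove_phase(spec.groove)

    existing = [r for r in dna.residues]
    next_seq = 1 + max(
        (r.seq_id for r in existing if r.chain_id == "A"), default=0
    )
    serial = max((a.serial for r in existing for a in r.atoms), default=0)
    residues = list(existing)
    keys = []
    for idx, res_type in enumerate(spec.residue_types):
        bp = first + idx * spec.spacing
        az = _bp_azimuth(params, bp) + phase
        z = _bp_z(params, bp)
        radial = np.array([np.cos(az), np.sin(az), 0.0])
        tangent = unit(
            np.array([-np.sin(az), np.cos(az), 0.0]) * CA_RADIUS * np.radians(params.twist)
            + np.array([0.0, 0.0, params.rise])
        )
        tip = radial * (TIP_RADIUS + spec.offset)
        cb = radial * (CB_RADIUS + spec.offset)
        ca = radial * (CA_RADIUS + spec.offset)
        tip[2] = cb[2] = ca[2] = z
        c = ca + CA_C_BOND * tangent
        n = ca - CA_N_BOND * tangent + 0.3 * radial
        tip_name = TIP_ATOM.get(res_type, "CB")
        local_atoms = [("N", n, "N"), ("CA", ca, "C"), ("C", c, "C")]
        if res_type != "GLY":
            local_atoms.append(("CB", cb, "C"))
        if tip_name not in [a[0] for a in local_atoms]:
            local_atoms.append((tip_name, tip, tip_name[0]))
        recs = []
        for name, coord, elem in local_atoms:
            serial += 1
            jitter = rng.normal(scale=spec.jitter_sd, size=3) if spec.jitter_sd > 0 else 0.0
            recs.append(AtomRecord(serial, name, elem[0], rot @ (coord + jitter) + origin))
        rr = ResidueRecord("A", next_seq + idx, res_type, "", recs)
        residues.append(rr)
        keys.append(rr.key)

    model = StructureModel(id=dna.id + "+dbu", residues=residues)
    model.helix_params = params
    tangents = true_groove_tangent(model, spec.center_bp, spec.groove)
    truth = DBUGroundTruth(
        residue_keys=keys,
        center_bp=spec.center_bp,
        groove=spec.groove,
        tangent=tangents[0],
        seed=spec.seed,
    )
    return model, truth


def strip_dna(s: StructureModel) -> StructureModel:
    """Unbound-protein view: drop all DNA residues (truth stays external)."""
    residues = [r for r in s.residues if r.kind != "dna"]
    model = StructureModel(id=s.id + ":unbound", residues=residues, source=s.source)
    if hasattr(s, "helix_params"):
        model.helix_params = s.helix_params
    return model


def write_ground_truth(truths, path) -> None:
    payload = [t.to_dict() for t in truths]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_ground_truth(path):
    payload = json.loads(Path(path).read_text())
    out = []
    for d in payload:
        out.append(
            DBUGroundTruth(
                residue_keys=[tuple(k) for k in d["residue_keys"]],
                center_bp=d["center_bp"],
                groove=d["groove"],
                tangent=np.array(d["tangent"], dtype=float),
                seed=d["seed"],
            )
        )
    return out
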