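"""Small shared geometry helpers (unit vectors, undirected lines, rotations)."""

from __future__ import annotations

import numpy as np

__all__ = [
    "unit",
    "canonical_direction",
    "angle_between_lines",
    "rotation_about_axis",
    "rotation_aligning",
    "random_rotation",
]


def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector has no direction")
    return v / n


def canonical_direction(v: np.ndarray) -> np.ndarray:
    """Unit vector with canonical sign: largest-magnitude component >= 0."""
    u = unit(v)
    i = int(np.argmax(np.abs(u)))
    return -u if u[i] < 0 else u


def angle_between_lines(u: np.ndarray, v: np.ndarray) -> float:
    """Angle in degrees between two undirected lines, folded to [0, 90]."""
    c = abs(float(np.dot(unit(u), unit(v))))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about ``axis`` by ``angle_rad``."""
    a = unit(axis)
    k = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * k + (1 - np.cos(angle_rad)) * (k @ k)


def rotation_aligning(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector ``src`` onto ``dst``."""
    s, d = unit(src), unit(dst)
    c = float(np.dot(s, d))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        # pick any perpendicular axis for the half-turn
        helper = np.array([1.0, 0.0, 0.0])
        if abs(s[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        axis = unit(np.cross(s, helper))
        return rotation_about_axis(axis, np.pi)
    axis = np.cross(s, d)
    return rotation_about_axis(axis, float(np.arctan2(np.linalg.norm(axis), c)))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation via QR of a Gaussian matrix."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
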