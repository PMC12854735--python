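"""Small geometry utilities: internal-coordinate placement and dihedrals."""

from __future__ import annotations

import numpy as np

__all__ = ["place_atom", "angle_between", "dihedral_angle", "min_image"]


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Place atom d from internal coordinates (NeRF construction).

    d is placed so that |c-d| = bond, the angle b-c-d equals `angle` and the
    dihedral a-b-c-d equals `dihedral` (both in radians).
    """
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = bond * np.array([
        -np.cos(angle),
        np.sin(angle) * np.cos(dihedral),
        np.sin(angle) * np.sin(dihedral),
    ])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def angle_between(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in radians."""
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(cosang, -1.0, 1.0)))


def dihedral_angle(a, b, c, d) -> float:
    """Signed dihedral a-b-c-d in radians, in (-pi, pi]."""
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m, n2)
    return float(np.arctan2(y, x))


def min_image(d: np.ndarray, box_edge: float | None) -> np.ndarray:
    """Minimum-image displacement(s) for a cubic periodic box."""
    if box_edge is None:
        return d
    return d - box_edge * np.round(d / box_edge)
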