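"""Low-level vector geometry: internal-coordinate atom placement, torsions,
rotations and least-squares planes.  All coordinates are in nm, all angles
in degrees unless noted.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "place_atom",
    "dihedral",
    "bond_angle",
    "rotate_about_axis",
    "fit_plane",
    "frame_from_three_points",
]


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D given chain A-B-C (NeRF construction).

    ``bond`` is |C-D|, ``angle_deg`` the B-C-D angle and ``dihedral_deg``
    the A-B-C-D torsion.
    """
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([
        -np.cos(ang),
        np.sin(ang) * np.cos(tor),
        np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    ang = np.degrees(np.arctan2(y, x))
    return float(ang) if ang != -180.0 else 180.0


def bond_angle(p0, p1, p2) -> float:
    """Angle p0-p1-p2 in degrees."""
    u = np.asarray(p0) - np.asarray(p1)
    v = np.asarray(p2) - np.asarray(p1)
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def rotate_about_axis(points: np.ndarray, origin: np.ndarray,
                      axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation of ``points`` about the line (origin, axis)."""
    k = np.asarray(axis, dtype=float)
    k = k / np.linalg.norm(k)
    theta = np.deg2rad(angle_deg)
    p = points - origin
    rot = (p * np.cos(theta)
           + np.cross(k, p) * np.sin(theta)
           + np.outer(p @ k, k) * (1.0 - np.cos(theta)))
    return rot + origin


def fit_plane(points: np.ndarray):
    """Least-squares plane through ``points``.

    Returns (centroid, unit normal).  The normal is the singular vector of
    the centered coordinates with the smallest singular value.
    """
    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    return centroid, vt[-1]


def frame_from_three_points(p0, p1, p2) -> np.ndarray:
    """Right-handed orthonormal frame (3x3, rows) anchored at p1.

    e1 along p1->p0, e3 normal to the (p0, p1, p2) plane, e2 = e3 x e1.
    """
    u = np.asarray(p0, dtype=float) - np.asarray(p1, dtype=float)
    v = np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)
    e1 = u / np.linalg.norm(u)
    w = np.cross(u, v)
    e3 = w / np.linalg.norm(w)
    e2 = np.cross(e3, e1)
    return np.stack([e1, e2, e3])
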