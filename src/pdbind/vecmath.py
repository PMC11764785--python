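"""Small geometric primitives: dihedrals, internal-coordinate atom placement,
axis rotations and rigid superposition."""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    """Angle between two vectors in degrees."""
    c = np.dot(unit(a), unit(b))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def dihedral_deg(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees (IUPAC convention)."""
    b1 = np.asarray(p1) - np.asarray(p0)
    b2 = np.asarray(p2) - np.asarray(p1)
    b3 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), unit(b2))
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(a, b, c, bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Position atom D bonded to C with |CD| = bond, angle(B,C,D) = angle and
    dihedral(A,B,C,D) = dihedral (degrees). Natural-extension (NeRF) scheme."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    theta = np.radians(angle)
    phi = np.radians(dihedral)
    d_local = bond * np.array([-np.cos(theta),
                               np.sin(theta) * np.cos(phi),
                               np.sin(theta) * np.sin(phi)])
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.column_stack([bc, np.cross(n, bc), n])
    return c + m @ d_local


def rotation_about_axis(axis: np.ndarray, angle_degrees: float) -> np.ndarray:
    """3x3 right-handed rotation matrix about an arbitrary axis."""
    return Rotation.from_rotvec(
        np.radians(angle_degrees) * unit(np.asarray(axis, float))).as_matrix()


def kabsch(mobile: np.ndarray, target: np.ndarray):
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns (R, t, rmsd) with target ~= mobile @ R.T + t.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if mobile.shape != target.shape or len(mobile) < 3:
        raise ValueError("need >= 3 matched points of identical shape")
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tc, mobile - mc)
    R = rot.as_matrix()
    t = tc - mc @ R.T
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return R, t, rmsd
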