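"""Small vector-geometry helpers (nm units throughout).

Dihedral sign follows the IUPAC convention: looking down the b->c axis,
a positive angle means the far bond (c->d) is rotated clockwise from the
near bond (b->a projection).
"""

from __future__ import annotations

import numpy as np


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Signed dihedral angle a-b-c-d in degrees, in (-180, 180]."""
    b0 = a - b
    b1 = c - b
    b2 = d - c
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 exactly onto +180 so the range is (-180, 180]
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c (vertex at b) in degrees, in [0, 180]."""
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    bond_angle: float,
    torsion: float,
) -> np.ndarray:
    """Place atom d with |c-d| = bond, angle(b,c,d) = bond_angle and
    dihedral(a,b,c,d) = torsion (NeRF internal-to-Cartesian step).

    Angles in degrees, lengths in nm.
    """
    th = np.radians(bond_angle)
    ph = np.radians(torsion)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        # a,b,c collinear: any perpendicular will do; torsion is then arbitrary
        n = np.cross(bc, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(n) < 1e-12:
            n = np.cross(bc, np.array([0.0, 1.0, 0.0]))
        nn = np.linalg.norm(n)
    n = n / nn
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(th),
            bond * np.sin(th) * np.cos(ph),
            bond * np.sin(th) * np.sin(ph),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def random_rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3x3 rotation matrix (via normalized quaternion)."""
    q = rng.normal(size=4)
    q = q / np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a rotation of angle_deg about a (unit) axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    th = np.radians(angle_deg)
    k = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + np.sin(th) * k + (1 - np.cos(th)) * (k @ k)
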