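"""Small internal-coordinate geometry helpers (NeRF atom placement,
bond/angle/dihedral measurement) used by the fixture generator and the
model builder."""

from __future__ import annotations

import numpy as np


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def bond_length(a, b) -> float:
    return float(np.linalg.norm(np.asarray(b) - np.asarray(a)))


def bond_angle(a, b, c) -> float:
    """Angle a-b-c in radians."""
    u = _unit(np.asarray(a) - np.asarray(b))
    v = _unit(np.asarray(c) - np.asarray(b))
    return float(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0)))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion p1-p2-p3-p4 in radians, IUPAC sign convention."""
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b3 = np.asarray(p4) - np.asarray(p3)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.arctan2(y, x))


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D given A, B, C such that |C-D| = bond, angle(B,C,D) =
    ``angle`` and dihedral(A,B,C,D) = ``torsion`` (radians)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        -bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def amide_h_position(n, ca, c_prev) -> np.ndarray:
    """Rebuild the backbone amide hydrogen: 1.01 A from N along the
    outward bisector of the N-CA and N-C(prev) directions."""
    n = np.asarray(n, dtype=float)
    direction = _unit(_unit(np.asarray(ca) - n) + _unit(np.asarray(c_prev) - n))
    return n - 1.01 * direction
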