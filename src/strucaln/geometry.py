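"""Small vector-geometry helpers shared by the feature computations and the
synthetic-structure builders."""
from __future__ import annotations

import numpy as np


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u, v = unit(a - b), unit(c - b)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """IUPAC torsion p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, unit(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond_length: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension placement: return d bonded to c with the given b-c-d
    angle and a-b-c-d torsion."""
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = bond_length * np.array([
        -np.cos(ang),
        np.sin(ang) * np.cos(tor),
        -np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-section spiral of ``n`` points on the unit sphere.

    A fixed point set makes every sampled-surface quantity (SASA, depth)
    bit-reproducible across runs without any random seed.
    """
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = phi * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def kabsch(P: np.ndarray, Q: np.ndarray, weights: np.ndarray | None = None
           ) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t minimising Σ w ||R p + t - q||².

    Returns ``(R, t)`` with R proper (det +1).  ``P`` and ``Q`` are (n, 3)
    paired coordinates; ``weights`` default to uniform.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if weights is None:
        w = np.full(len(P), 1.0)
    else:
        w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    pc = (w[:, None] * P).sum(axis=0)
    qc = (w[:, None] * Q).sum(axis=0)
    P0 = P - pc
    Q0 = Q - qc
    H = (w[:, None] * P0).T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t
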