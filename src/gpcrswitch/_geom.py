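"""Small rigid-body helpers shared across modules."""

from __future__ import annotations

import numpy as np


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares superposition of ``mobile`` onto ``reference``.

    Returns (R, t) such that ``mobile @ R.T + t`` minimizes the RMSD to
    ``reference``.  Proper rotation enforced (det R = +1).
    """
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    H = (mobile - mob_c).T @ (reference - ref_c)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ref_c - R @ mob_c
    return R, t


def apply_rigid(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return coords @ R.T + t


def rotation_matrix_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Right-handed rotation matrix about a unit ``axis`` by ``angle_deg``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    x, y, z = axis
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(axis, axis)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, sign-fixed)."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
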