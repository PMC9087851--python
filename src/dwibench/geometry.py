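"""Rigid/eddy transform parametrization and volume resampling.

Convention: a transform (M, t) maps input coordinates x' to output coordinates
x = M (x' - c) + c + t, with c the grid center; ``apply_affine`` resamples a
volume accordingly (pulling values via the inverse map). Rotations compose as
R = Rz Ry Rx from per-axis angles.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def rotation_zyx(angles_rad) -> np.ndarray:
    rx, ry, rz = angles_rad
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def angles_zyx(R: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rotation_zyx` (radians), assuming |ry| < pi/2."""
    ry = np.arcsin(-np.clip(R[2, 0], -1, 1))
    rx = np.arctan2(R[2, 1], R[2, 2])
    rz = np.arctan2(R[1, 0], R[0, 0])
    return np.array([rx, ry, rz])


def rotation_angle_deg(R: np.ndarray) -> float:
    """Total rotation angle of a 3x3 rotation matrix, in degrees."""
    return float(np.rad2deg(np.arccos(np.clip((np.trace(R) - 1) / 2, -1, 1))))


def eddy_matrix(scale: float, shear_a: float, shear_b: float, axis: int = 1) -> np.ndarray:
    """Linear eddy-current distortion: scale along the phase-encode axis plus
    shears of that coordinate with respect to the two others."""
    E = np.eye(3)
    others = [i for i in range(3) if i != axis]
    E[axis, axis] = 1.0 + scale
    E[axis, others[0]] = shear_a
    E[axis, others[1]] = shear_b
    return E


def rotation_to_axis(axis) -> np.ndarray:
    """Rotation matrix mapping the z unit vector onto ``axis``."""
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, a)
    c = float(z @ a)
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def apply_affine(vol: np.ndarray, M: np.ndarray, t, order: int = 3) -> np.ndarray:
    """Resample ``vol`` under the transform x = M (x' - c) + c + t."""
    c = (np.asarray(vol.shape, float) - 1) / 2.0
    Minv = np.linalg.inv(M)
    offset = c - Minv @ (c + np.asarray(t, float))
    return ndimage.affine_transform(vol, Minv, offset=offset, order=order, mode="constant")


def transform_params(M: np.ndarray, t) -> dict:
    """Decompose M = R E into rotation angles and eddy terms via polar-like
    factorization (exact when M was built as R @ E with small eddy terms)."""
    # R from the QR-like structure: E is unit lower/upper mixed; use polar decomposition
    U, _, Vt = np.linalg.svd(M)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        R = U @ np.diag([1, 1, -1]) @ Vt
    E = R.T @ M
    return {
        "rotation_deg": np.rad2deg(angles_zyx(R)),
        "translation_vox": np.asarray(t, float),
        "eddy": E,
        "rotation": R,
    }
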