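"""Quaternion algebra for rigid-body kinematics.

Unit quaternions represent the orientation of a molecular (body) frame MF
with respect to the laboratory frame LF.  Convention: Hamilton product,
scalar-first storage ``(w, x, y, z)``, right-handed rotations.  A vector is
rotated from the molecular frame into the laboratory frame by
``v_LF = q * v * conj(q)``; the backward rotation exchanges ``q`` with its
conjugate (for unit quaternions the conjugate is the inverse).

All functions accept batched input: the quaternion arguments broadcast over
leading axes with the last axis of length 4 (vectors: length 3).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "MF_TO_LF",
    "LF_TO_MF",
    "QuaternionError",
    "quat_identity",
    "quat_conjugate",
    "quat_multiply",
    "quat_normalize",
    "quat_rotate",
    "quat_from_rotation_matrix",
    "quat_to_rotation_matrix",
    "quat_from_axis_angle",
    "random_unit_quaternion",
]

MF_TO_LF = "mf->lf"
LF_TO_MF = "lf->mf"

#: maximum allowed |q|-1 before rotation input is rejected
_UNIT_TOL = 1e-9


class QuaternionError(ValueError):
    """Invalid quaternion input (non-unit, degenerate, or unstable)."""


def quat_identity() -> np.ndarray:
    return np.array([1.0, 0.0, 0.0, 0.0])


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product ``a ⊗ b`` (scalar-first), broadcasting over batches."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    aw, ax, ay, az = (a[..., i] for i in range(4))
    bw, bx, by, bz = (b[..., i] for i in range(4))
    return np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )


def quat_normalize(q: np.ndarray, instability_threshold: float | None = None) -> np.ndarray:
    """Return ``q / |q|``.

    Parameters
    ----------
    instability_threshold
        If given, a deviation ``| |q| - 1 | > instability_threshold`` raises
        :class:`QuaternionError`: during dynamics a quaternion drifting that
        far from unit norm signals an unstable integration, not a value that
        should be silently repaired.
    """
    q = np.asarray(q, dtype=float)
    norm = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(norm == 0.0):
        raise QuaternionError("zero quaternion cannot be normalized")
    if instability_threshold is not None:
        dev = np.abs(norm - 1.0)
        if np.any(dev > instability_threshold):
            raise QuaternionError(
                f"quaternion norm deviates from 1 by {float(dev.max()):.3g} "
                f"(> {instability_threshold:g}): unstable system"
            )
    return q / norm


def quat_rotate(q: np.ndarray, v: np.ndarray, direction: str = MF_TO_LF) -> np.ndarray:
    """Rotate vector(s) ``v`` between the molecular and laboratory frames.

    ``mf->lf`` applies ``q v q*``; ``lf->mf`` applies the inverse rotation.
    """
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(q, axis=-1)
    if np.any(np.abs(norm - 1.0) > _UNIT_TOL):
        raise QuaternionError("quat_rotate requires unit quaternions (|q|-1 > 1e-9)")
    if direction == LF_TO_MF:
        q = quat_conjugate(q)
    elif direction != MF_TO_LF:
        raise ValueError(f"unknown rotation direction {direction!r}")
    w = q[..., :1]
    u = q[..., 1:]
    # v' = v + 2w (u x v) + 2 u x (u x v)
    t = 2.0 * np.cross(u, v)
    return v + w * t + np.cross(u, t)


def quat_to_rotation_matrix(q: np.ndarray) -> np.ndarray:
    """3x3 matrix R with ``R v_MF = v_LF`` (batched over leading axes)."""
    q = np.asarray(q, dtype=float)
    w, x, y, z = (q[..., i] for i in range(4))
    row0 = np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)], axis=-1)
    row1 = np.stack([2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)], axis=-1)
    row2 = np.stack([2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)], axis=-1)
    return np.stack([row0, row1, row2], axis=-2)


def _canonicalize(q: np.ndarray) -> np.ndarray:
    # enforce w >= 0 (double cover); if w == 0, first nonzero component positive
    if q[0] < 0:
        return -q
    if q[0] == 0.0:
        for c in q[1:]:
            if c != 0.0:
                return q if c > 0 else -q
    return q


def quat_from_rotation_matrix(R: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Convert a proper rotation matrix to a unit quaternion (w >= 0).

    Uses the numerically stable largest-pivot (Shepperd) branching.
    """
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise QuaternionError(f"expected 3x3 matrix, got {R.shape}")
    if not np.allclose(R @ R.T, np.eye(3), atol=tol):
        raise QuaternionError("matrix is not orthogonal")
    if np.linalg.det(R) < 0:
        raise QuaternionError("matrix is a reflection (det < 0), not a rotation")
    tr = np.trace(R)
    # pick the largest of (trace, R00, R11, R22) as pivot
    choices = [tr, R[0, 0], R[1, 1], R[2, 2]]
    case = int(np.argmax(choices))
    if case == 0:
        s = np.sqrt(tr + 1.0) * 2.0
        q = np.array(
            [0.25 * s, (R[2, 1] - R[1, 2]) / s, (R[0, 2] - R[2, 0]) / s, (R[1, 0] - R[0, 1]) / s]
        )
    elif case == 1:
        s = np.sqrt(1.0 + R[0, 0] - R[1, 1] - R[2, 2]) * 2.0
        q = np.array(
            [(R[2, 1] - R[1, 2]) / s, 0.25 * s, (R[0, 1] + R[1, 0]) / s, (R[0, 2] + R[2, 0]) / s]
        )
    elif case == 2:
        s = np.sqrt(1.0 - R[0, 0] + R[1, 1] - R[2, 2]) * 2.0
        q = np.array(
            [(R[0, 2] - R[2, 0]) / s, (R[0, 1] + R[1, 0]) / s, 0.25 * s, (R[1, 2] + R[2, 1]) / s]
        )
    else:
        s = np.sqrt(1.0 - R[0, 0] - R[1, 1] + R[2, 2]) * 2.0
        q = np.array(
            [(R[1, 0] - R[0, 1]) / s, (R[0, 2] + R[2, 0]) / s, (R[1, 2] + R[2, 1]) / s, 0.25 * s]
        )
    return _canonicalize(quat_normalize(q))


def quat_from_axis_angle(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise QuaternionError("zero rotation axis")
    half = 0.5 * angle_rad
    return np.concatenate([[np.cos(half)], np.sin(half) * axis / n])


def random_unit_quaternion(rng: np.random.Generator, size: int | None = None) -> np.ndarray:
    """Uniform sample(s) on SO(3) via normalized 4-d Gaussians."""
    shape = (4,) if size is None else (size, 4)
    q = rng.standard_normal(shape)
    return q / np.linalg.norm(q, axis=-1, keepdims=True)
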