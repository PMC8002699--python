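"""Quaternion and rigid-pose arithmetic for 6-DoF tracking.

Quaternions are stored as arrays ``(w, x, y, z)`` with the scalar part first.
All operations broadcast over leading axes, so a single call handles one
quaternion or a whole particle population.  A pose carries position,
orientation and both velocities (14 scalar components in total); the
rotational velocity is itself kept as a four-component quaternion increment,
which is treated as a velocity — it is never renormalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Pose",
    "quat_identity",
    "quat_multiply",
    "quat_conjugate",
    "quat_inverse",
    "quat_normalize",
    "nlerp",
    "angular_difference",
    "integrate_pose",
]

_UNIT_TOL = 1e-6


def quat_identity() -> np.ndarray:
    """The identity rotation (1, 0, 0, 0)."""
    return np.array([1.0, 0.0, 0.0, 0.0])


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product ``a ⊗ b`` (broadcasts over leading axes)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    aw, ax, ay, az = a[..., 0], a[..., 1], a[..., 2], a[..., 3]
    bw, bx, by, bz = b[..., 0], b[..., 1], b[..., 2], b[..., 3]
    return np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def quat_inverse(q: np.ndarray) -> np.ndarray:
    """Multiplicative inverse: conjugate over squared norm.

    Raises ``ValueError`` for a (numerically) zero quaternion.
    """
    q = np.asarray(q, dtype=float)
    n2 = np.sum(q * q, axis=-1, keepdims=True)
    if np.any(n2 < 1e-300):
        raise ValueError("cannot invert a zero quaternion")
    return quat_conjugate(q) / n2


def quat_normalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(n < 1e-300):
        raise ValueError("cannot normalize a zero quaternion")
    return q / n


def nlerp(q0: np.ndarray, q1: np.ndarray, t: float) -> np.ndarray:
    """Normalized linear interpolation between two rotations.

    The sign of ``q1`` is flipped first when ``dot(q0, q1) < 0`` so the
    interpolation takes the shorter of the two great-circle arcs (q and -q
    encode the same rotation).  Raises ``ValueError`` when the interpolants
    cancel to the zero vector (antipodal midpoint).
    """
    q0 = quat_normalize(q0)
    q1 = quat_normalize(q1)
    dot = np.sum(q0 * q1, axis=-1, keepdims=True)
    q1 = np.where(dot < 0.0, -q1, q1)
    mix = (1.0 - t) * q0 + t * q1
    n = np.linalg.norm(mix, axis=-1)
    if np.any(n < 1e-12):
        raise ValueError("degenerate interpolation: interpolants cancel")
    return mix / n[..., None]


def angular_difference(q_est: np.ndarray, q_true: np.ndarray) -> float | np.ndarray:
    """Angle (rad) between two unit-quaternion rotations, in [0, pi].

    Computed as ``2·acos(|scalar part of q_est ⊗ q_true⁻¹|)``.  The absolute
    value folds the quaternion double cover, so q and -q compare as equal
    rotations.  Non-unit inputs raise ``ValueError``.
    """
    q_est = np.asarray(q_est, dtype=float)
    q_true = np.asarray(q_true, dtype=float)
    for q in (q_est, q_true):
        if np.any(np.abs(np.linalg.norm(q, axis=-1) - 1.0) > _UNIT_TOL):
            raise ValueError("angular_difference expects unit quaternions")
    rel = quat_multiply(q_est, quat_inverse(q_true))
    w = np.clip(np.abs(rel[..., 0]), -1.0, 1.0)
    ang = 2.0 * np.arccos(w)
    return float(ang) if ang.ndim == 0 else ang


@dataclass
class Pose:
    """Rigid-body state: position, orientation and both velocities.

    ``p`` is the position in meters (camera frame), ``q`` the unit
    orientation quaternion, ``v_trans`` the translational velocity in m/s
    and ``v_rot`` the rotational velocity increment as a quaternion.
    """

    p: np.ndarray = field(default_factory=lambda: np.zeros(3))
    q: np.ndarray = field(default_factory=quat_identity)
    v_trans: np.ndarray = field(default_factory=lambda: np.zeros(3))
    v_rot: np.ndarray = field(default_factory=lambda: np.zeros(4))

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float).reshape(3)
        self.q = quat_normalize(np.asarray(self.q, dtype=float).reshape(4))
        self.v_trans = np.asarray(self.v_trans, dtype=float).reshape(3)
        self.v_rot = np.asarray(self.v_rot, dtype=float).reshape(4)

    def as_vector(self) -> np.ndarray:
        """The 14-component state vector (p, q, v_trans, v_rot)."""
        return np.concatenate([self.p, self.q, self.v_trans, self.v_rot])

    def copy(self) -> "Pose":
        return Pose(self.p.copy(), self.q.copy(), self.v_trans.copy(), self.v_rot.copy())


def integrate_pose(pose: Pose, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """One backward-Euler step of the kinematic model.

    Returns the new position ``p + v_trans·dt`` and the new orientation
    ``normalize(q + 0.5·(q ⊗ v_rot)·dt)`` — the renormalized linear blend of
    the old orientation with the rotational-velocity increment.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p_new = pose.p + pose.v_trans * dt
    q_new = quat_normalize(pose.q + 0.5 * quat_multiply(pose.q, pose.v_rot) * dt)
    return p_new, q_new
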