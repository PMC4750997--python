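"""Planar tendon-driven limb geometry and muscle routing.

The workhorse model is a two-link revolute arm (shoulder ``theta1``, elbow
``theta2``) whose muscles pull on the joints through a signed moment-arm
matrix ``R`` (joints x muscles).  A column of ``R`` is a muscle's lever about
each joint: positive entries produce flexor torque.  The same container also
describes single-joint limbs (one row in ``R``), which are useful for
low-dimensional geometric illustrations of activation-space constraints.

Angles are radians internally; user-facing constructors and reports use
degrees because that is how limb postures are conventionally quoted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ArmModel",
    "Posture",
    "SingularPostureError",
    "UnreachableEndpointError",
    "forward_kinematics",
    "inverse_kinematics",
    "jacobian",
    "posture_grid",
]

#: |sin(theta2)| below which the two-link Jacobian is treated as singular.
SINGULARITY_TOL = 1e-9


class SingularPostureError(ValueError):
    """Raised when an operation needs an invertible Jacobian but the elbow
    angle is at (or numerically on top of) 0 or 180 degrees."""


class UnreachableEndpointError(ValueError):
    """Raised when an endpoint lies outside the reachable annulus."""


@dataclass(frozen=True)
class Posture:
    """Joint configuration of the two-link arm.

    Parameters
    ----------
    theta : tuple of float
        Joint angles in radians, ``(shoulder, elbow)``.
    """

    theta: tuple[float, float]

    def __post_init__(self) -> None:
        t = tuple(float(v) for v in self.theta)
        if len(t) != 2 or not all(math.isfinite(v) for v in t):
            raise ValueError("posture needs two finite joint angles")
        object.__setattr__(self, "theta", t)

    @classmethod
    def from_degrees(cls, theta1_deg: float, theta2_deg: float) -> "Posture":
        return cls((math.radians(theta1_deg), math.radians(theta2_deg)))

    @property
    def theta_deg(self) -> tuple[float, float]:
        return (math.degrees(self.theta[0]), math.degrees(self.theta[1]))

    def is_singular(self, tol: float = SINGULARITY_TOL) -> bool:
        return abs(math.sin(self.theta[1])) < tol


def _default_moment_arms() -> np.ndarray:
    # Muscle order: shoulder flexor, shoulder extensor, elbow flexor,
    # elbow extensor, bi-articular flexor, bi-articular extensor.
    return np.array(
        [
            [1.0, -1.0, 0.0, 0.0, 1.0, -1.0],
            [0.0, 0.0, 1.0, -1.0, 1.0, -1.0],
        ]
    )


@dataclass(frozen=True)
class ArmModel:
    """Geometry, routing and strength parameters of a planar limb.

    Parameters
    ----------
    link_lengths : array-like
        Positive link lengths; two entries for the planar arm, empty for a
        single-joint limb (which has no endpoint geometry of its own).
    moment_arms : ndarray
        Signed joints x muscles matrix ``R`` with ``tau = R F``.
    f_max : ndarray
        Per-muscle maximal force scale (positive).
    alpha : float
        Stiffness-per-force scale: an active muscle's stiffness is
        ``alpha * f_max * a``.
    joint_limits : ndarray
        Per-joint ``[min, max]`` angle range in radians.
    """

    link_lengths: np.ndarray = field(default_factory=lambda: np.ones(2))
    moment_arms: np.ndarray = field(default_factory=_default_moment_arms)
    f_max: np.ndarray | None = None
    alpha: float = 1.0
    joint_limits: np.ndarray | None = None

    def __post_init__(self) -> None:
        ll = np.atleast_1d(np.asarray(self.link_lengths, dtype=float))
        R = np.atleast_2d(np.asarray(self.moment_arms, dtype=float))
        if R.shape[0] not in (1, 2):
            raise ValueError("moment_arms must have 1 or 2 joint rows")
        if np.any(np.all(R == 0.0, axis=0)):
            raise ValueError("every muscle must act on at least one joint")
        if R.shape[0] == 2 and ll.shape != (2,):
            raise ValueError("a two-joint arm needs exactly two link lengths")
        if np.any(ll <= 0):
            raise ValueError("link lengths must be positive")
        fm = np.ones(R.shape[1]) if self.f_max is None else np.asarray(self.f_max, dtype=float)
        if fm.shape != (R.shape[1],) or np.any(fm <= 0):
            raise ValueError("f_max must be positive, one entry per muscle")
        if float(self.alpha) <= 0:
            raise ValueError("alpha must be positive")
        if self.joint_limits is None:
            # Plausible planar workspace keeping the elbow clear of the
            # fully-extended and fully-folded singularities.
            jl = np.array([[0.0, math.radians(160.0)], [math.radians(5.0), math.radians(175.0)]])
            jl = jl[: R.shape[0]]
        else:
            jl = np.atleast_2d(np.asarray(self.joint_limits, dtype=float))
        if jl.shape != (R.shape[0], 2) or np.any(jl[:, 0] >= jl[:, 1]):
            raise ValueError("joint_limits must be per-joint [min, max] with min < max")
        object.__setattr__(self, "link_lengths", ll)
        object.__setattr__(self, "moment_arms", R)
        object.__setattr__(self, "f_max", fm)
        object.__setattr__(self, "alpha", float(self.alpha))
        object.__setattr__(self, "joint_limits", jl)

    @property
    def n_joints(self) -> int:
        return self.moment_arms.shape[0]

    @property
    def n_muscles(self) -> int:
        return self.moment_arms.shape[1]


def forward_kinematics(arm: ArmModel, posture: Posture) -> np.ndarray:
    """Endpoint position of the two-link arm at ``posture``."""
    _require_two_link(arm)
    l1, l2 = arm.link_lengths
    t1, t2 = posture.theta
    return np.array(
        [l1 * math.cos(t1) + l2 * math.cos(t1 + t2), l1 * math.sin(t1) + l2 * math.sin(t1 + t2)]
    )


def inverse_kinematics(arm: ArmModel, endpoint, branch: str = "elbow_positive") -> Posture:
    """Joint angles placing the endpoint at ``endpoint``.

    ``branch`` selects the elbow sign: ``"elbow_positive"`` (elbow flexed
    counter-clockwise) or ``"elbow_negative"`` (mirror configuration).
    """
    _require_two_link(arm)
    if branch not in ("elbow_positive", "elbow_negative"):
        raise ValueError(f"unknown IK branch {branch!r}")
    l1, l2 = arm.link_lengths
    x, y = (float(v) for v in endpoint)
    r = math.hypot(x, y)
    r_min, r_max = abs(l1 - l2), l1 + l2
    if not (r_min - 1e-12 <= r <= r_max + 1e-12):
        raise UnreachableEndpointError(
            f"endpoint ({x:g}, {y:g}) at radius {r:g} is outside the reachable "
            f"annulus [{r_min:g}, {r_max:g}]"
        )
    c2 = (r * r - l1 * l1 - l2 * l2) / (2.0 * l1 * l2)
    c2 = min(1.0, max(-1.0, c2))
    t2 = math.acos(c2)
    if branch == "elbow_negative":
        t2 = -t2
    t1 = math.atan2(y, x) - math.atan2(l2 * math.sin(t2), l1 + l2 * math.cos(t2))
    return Posture((t1, t2))


def jacobian(arm: ArmModel, posture: Posture) -> np.ndarray:
    """Manipulator Jacobian mapping joint to endpoint velocities.

    For a single-joint limb the map is the identity (the joint coordinate is
    the endpoint coordinate), keeping the stiffness pipeline uniform.
    """
    if arm.n_joints == 1:
        return np.eye(1)
    l1, l2 = arm.link_lengths
    t1, t2 = posture.theta
    s1, c1 = math.sin(t1), math.cos(t1)
    s12, c12 = math.sin(t1 + t2), math.cos(t1 + t2)
    return np.array([[-l1 * s1 - l2 * s12, -l2 * s12], [l1 * c1 + l2 * c12, l2 * c12]])


def posture_grid(arm: ArmModel, n1: int, n2: int, tol: float = SINGULARITY_TOL) -> list[Posture]:
    """Uniform ``n1 x n2`` grid over the joint limits, singular rows dropped.

    Postures whose elbow angle makes the Jacobian numerically singular
    (``|sin theta2| < tol``) are excluded.
    """
    _require_two_link(arm)
    if n1 < 2 or n2 < 2:
        raise ValueError("grid needs at least 2 points per joint")
    t1s = np.linspace(arm.joint_limits[0, 0], arm.joint_limits[0, 1], n1)
    t2s = np.linspace(arm.joint_limits[1, 0], arm.joint_limits[1, 1], n2)
    grid = [
        Posture((float(t1), float(t2)))
        for t2 in t2s
        if abs(math.sin(t2)) >= tol
        for t1 in t1s
    ]
    if not grid:
        raise ValueError("no non-singular postures left after filtering the grid")
    return grid


def _require_two_link(arm: ArmModel) -> None:
    if arm.n_joints != 2:
        raise ValueError("this operation requires the two-link planar arm")
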