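"""Activation-to-stiffness maps and ellipse summaries.

The chain is: activation ``a`` (one entry per muscle, each in [0, 1]) sets
each muscle's stiffness ``k_i = alpha * f_max_i * a_i``; the moment-arm
matrix pulls those out to a joint-stiffness matrix ``K_joint = R diag(k) R^T``;
the inverse-transpose Jacobian maps that to endpoint stiffness
``K_end = J^-T K_joint J^-1``.  Because every step is linear in ``a``, the
upper triangle of ``K_end`` is a single matrix-vector product ``M a``; that
3 x M operator is what turns "produce this endpoint stiffness" into linear
equality constraints on the activation vector.

A symmetric positive-definite ``K_end`` is summarized as an ellipse:
size (trace), shape (condition number, major/minor eigenvalue ratio) and
orientation (major-axis angle from the x-axis, degrees in [0, 180)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .arm import ArmModel, Posture, SingularPostureError, jacobian

__all__ = [
    "StiffnessEllipse",
    "LinearStiffnessMap",
    "muscle_stiffness",
    "joint_stiffness",
    "endpoint_stiffness",
    "build_linear_map",
    "ellipse_of",
    "desired_stiffness",
    "vectorize_stiffness",
    "unvectorize_stiffness",
]

#: relative eigenvalue gap below which an ellipse counts as a circle and its
#: orientation is reported as undefined
ISOTROPY_TOL = 1e-9


def validate_activation(arm: ArmModel, a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.shape != (arm.n_muscles,):
        raise ValueError(f"activation must have {arm.n_muscles} entries, got shape {a.shape}")
    if np.any(a < -1e-12) or np.any(a > 1.0 + 1e-12):
        raise ValueError("activations must lie in [0, 1]")
    return np.clip(a, 0.0, 1.0)


def muscle_stiffness(arm: ArmModel, a) -> np.ndarray:
    """Diagonal muscle stiffnesses ``k_i = alpha * f_max_i * a_i``."""
    a = validate_activation(arm, a)
    return arm.alpha * arm.f_max * a


def joint_stiffness(arm: ArmModel, a) -> np.ndarray:
    """Joint stiffness ``R diag(k) R^T`` (sum of rank-1 muscle contributions)."""
    k = muscle_stiffness(arm, a)
    R = arm.moment_arms
    return (R * k) @ R.T


def endpoint_stiffness(arm: ArmModel, posture: Posture | None, a) -> np.ndarray:
    """Endpoint stiffness ``J^-T K_joint J^-1`` at ``posture``.

    Symmetric by construction (no neural feedback pathways are modeled, and
    the endpoint carries no external force).
    """
    J = _invertible_jacobian(arm, posture)
    Kj = joint_stiffness(arm, a)
    Jinv = np.linalg.inv(J)
    K = Jinv.T @ Kj @ Jinv
    return 0.5 * (K + K.T)  # scrub rounding asymmetry


@dataclass(frozen=True)
class LinearStiffnessMap:
    """Linear operator sending activations to vectorized endpoint stiffness.

    ``matrix`` is n_stiff x M with row order ``(K_xx, K_xy, K_yy)`` for the
    planar arm (a single row for a one-joint limb); ``matrix @ a`` equals the
    vectorized upper triangle of ``endpoint_stiffness(arm, posture, a)``.
    """

    matrix: np.ndarray
    posture: Posture | None

    @property
    def n_constraints(self) -> int:
        return self.matrix.shape[0]

    def __call__(self, a) -> np.ndarray:
        return self.matrix @ np.asarray(a, dtype=float)


def build_linear_map(arm: ArmModel, posture: Posture | None) -> LinearStiffnessMap:
    """Build the activation -> vectorized-endpoint-stiffness operator.

    Column ``i`` is the vectorized rank-1 stiffness of muscle ``i`` at full
    activation: with ``u_i = J^-T rho_i`` (``rho_i`` the moment-arm column),
    the column is ``alpha * f_max_i * vec(u_i u_i^T)``.
    """
    J = _invertible_jacobian(arm, posture)
    U = np.linalg.solve(J.T, arm.moment_arms)  # J^-T R, joints x muscles
    w = arm.alpha * arm.f_max
    if arm.n_joints == 1:
        M = (U[0] * U[0] * w)[None, :]
    else:
        M = np.vstack([U[0] * U[0] * w, U[0] * U[1] * w, U[1] * U[1] * w])
    return LinearStiffnessMap(matrix=M, posture=posture)


def vectorize_stiffness(K: np.ndarray) -> np.ndarray:
    """Upper triangle of a symmetric 2x2 (or 1x1) matrix as (xx, xy, yy)."""
    K = np.atleast_2d(np.asarray(K, dtype=float))
    if K.shape == (1, 1):
        return K[0]
    return np.array([K[0, 0], K[0, 1], K[1, 1]])


def unvectorize_stiffness(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape == (1,):
        return v[None, :]
    return np.array([[v[0], v[1]], [v[1], v[2]]])


@dataclass(frozen=True)
class StiffnessEllipse:
    """Eigen-summary of a symmetric positive-definite endpoint stiffness.

    Attributes
    ----------
    size : float
        Trace of the matrix (sum of principal stiffnesses).
    shape : float
        Condition number, major/minor eigenvalue ratio; >= 1.
    orientation_deg : float or None
        Major-axis angle from the x-axis in degrees, folded into [0, 180);
        ``None`` when the ellipse is a circle (orientation undefined).
    area : float
        ``pi * sqrt(lambda1 * lambda2)``, an alternate size measure.
    """

    size: float
    shape: float
    orientation_deg: float | None
    area: float

    @property
    def is_isotropic(self) -> bool:
        return self.orientation_deg is None


def ellipse_of(K, tol: float = ISOTROPY_TOL) -> StiffnessEllipse:
    """Summarize a symmetric positive-definite 2x2 stiffness as an ellipse."""
    K = np.asarray(K, dtype=float)
    if K.shape != (2, 2) or abs(K[0, 1] - K[1, 0]) > 1e-9 * (1.0 + abs(K[0, 1])):
        raise ValueError("stiffness matrix must be symmetric 2x2")
    if np.all(K == 0.0):
        raise ValueError("zero stiffness matrix has no ellipse")
    lam, vec = np.linalg.eigh(K)
    lo, hi = float(lam[0]), float(lam[1])
    if lo <= 0.0:
        raise ValueError(f"stiffness matrix is not positive definite (min eigenvalue {lo:g})")
    shape = hi / lo
    if hi - lo <= tol * hi:
        orient = None
    else:
        vx, vy = vec[:, 1]
        orient = math.degrees(math.atan2(vy, vx)) % 180.0
    return StiffnessEllipse(
        size=float(np.trace(K)), shape=shape, orientation_deg=orient, area=math.pi * math.sqrt(lo * hi)
    )


def desired_stiffness(shape: float, orientation_deg: float, scale: float = 1.0) -> np.ndarray:
    """Vectorized (xx, xy, yy) target stiffness with the given ellipse summary.

    Builds ``scale * Rot(phi) diag(shape, 1) Rot(phi)^T`` so that
    ``ellipse_of`` recovers ``shape`` and ``orientation_deg`` exactly.
    """
    if shape < 1.0:
        raise ValueError("shape (condition number) must be >= 1")
    if scale <= 0.0:
        raise ValueError("scale must be positive")
    phi = math.radians(orientation_deg)
    c, s = math.cos(phi), math.sin(phi)
    Rot = np.array([[c, -s], [s, c]])
    K = scale * (Rot @ np.diag([shape, 1.0]) @ Rot.T)
    return vectorize_stiffness(K)


def _invertible_jacobian(arm: ArmModel, posture: Posture | None) -> np.ndarray:
    if arm.n_joints == 1:
        return np.eye(1)
    if posture is None:
        raise ValueError("a posture is required for the two-link arm")
    if posture.is_singular():
        raise SingularPostureError(
            f"Jacobian is singular at elbow angle {posture.theta_deg[1]:.6g} deg"
        )
    return jacobian(arm, posture)
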