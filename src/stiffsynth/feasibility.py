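"""Feasible activation sets and energy extremization.

A static task fixes two things at once: the net joint torque must vanish
(the posture is in equilibrium) and the endpoint stiffness must equal a
desired matrix.  Both are linear in the activation vector, so together they
form an equality system ``A_eq a = b_eq``; intersecting its affine solution
set with the activation hypercube ``[0, 1]^M`` yields the feasible activation
set.  For the six-muscle arm the system generically has rank 5, so the
feasible set is a line segment (6 - 2 - 3 = 1 free dimension).

Feasibility is decided by exact affine geometry — solve the equality system,
intersect the solution line with the box — rather than by trusting a QP
solver's status code; this gives an exact realizability boundary.  Energy
(sum of squared muscle forces) is a convex quadratic along the segment, so
its minimum is the clamped 1-D stationary point and its maximum sits at a
segment endpoint.  Degenerate systems with a solution space of dimension two
or more fall back to vertex enumeration of the polytope.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .arm import ArmModel, Posture
from .stiffness import build_linear_map, desired_stiffness

__all__ = [
    "TaskConstraints",
    "FeasibleSegment",
    "EnergyRange",
    "assemble_constraints",
    "feasible_segment",
    "is_realizable",
    "auto_scale",
    "min_energy",
    "max_energy",
    "energy_range",
    "energy_reduction_pct",
    "oracle_energy_bracket",
    "realizable_fraction",
]

#: default residual tolerance for the equality system
EQ_TOL = 1e-8
#: default tolerance on the [0, 1] activation box
BOX_TOL = 1e-9


@dataclass(frozen=True)
class TaskConstraints:
    """Stacked linear equality constraints of a stiffness task.

    ``A_eq`` stacks the torque-equilibrium rows ``R diag(f_max)`` (one per
    joint, right-hand side zero) on top of the stiffness rows of the linear
    activation-to-stiffness map; ``b_eq`` carries zeros and the desired
    vectorized stiffness.  Activations are bounded to ``[0, 1]`` per muscle.
    """

    A_eq: np.ndarray
    b_eq: np.ndarray
    n_equilibrium: int
    f_max: np.ndarray

    @property
    def n_muscles(self) -> int:
        return self.A_eq.shape[1]


@dataclass(frozen=True)
class FeasibleSegment:
    """The feasible activation set when it is (at most) a line segment.

    Points are ``a0 + t * direction`` for ``t`` in ``t_range``.  ``empty``
    marks an unrealizable task; ``null_dim`` reports the dimension of the
    solution space of the equality system (before the box); ``degenerate``
    flags null spaces of dimension >= 2, for which ``vertices`` holds the
    polytope vertices used by the fallback energy extremization.
    """

    a0: np.ndarray
    direction: np.ndarray
    t_range: tuple[float, float]
    empty: bool
    null_dim: int
    degenerate: bool = False
    vertices: np.ndarray | None = field(default=None, repr=False)

    def point(self, t: float) -> np.ndarray:
        return self.a0 + t * self.direction

    @property
    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        return self.point(self.t_range[0]), self.point(self.t_range[1])


@dataclass(frozen=True)
class EnergyRange:
    """Extremes of the sum-of-squared-forces cost over a feasible set.

    ``reduction_pct = 100 * (e_max - e_min) / e_max`` is the headroom the
    controller has to economize without changing the endpoint stiffness;
    it is undefined (None) when ``e_max == 0``.
    """

    e_min: float
    e_max: float
    a_min: np.ndarray
    a_max: np.ndarray

    @property
    def reduction_pct(self) -> float | None:
        if self.e_max <= 0.0:
            return None
        return energy_reduction_pct(self.e_min, self.e_max)


def energy_reduction_pct(e_min: float, e_max: float) -> float:
    """Percent energy reduction available between the extremes.

    ``100 * (e_max - e_min) / e_max``; e.g. extremes of 0.5 and 0.35 leave a
    30% maximum reduction.
    """
    if e_max <= 0.0:
        raise ValueError("reduction is undefined when the maximal energy is zero")
    if e_min < -1e-12 or e_min > e_max + 1e-12:
        raise ValueError("need 0 <= e_min <= e_max")
    return 100.0 * (e_max - e_min) / e_max


def assemble_constraints(arm: ArmModel, posture: Posture | None, desired) -> TaskConstraints:
    """Stack equilibrium and desired-stiffness rows for one task.

    ``desired`` is the vectorized target stiffness: ``(K_xx, K_xy, K_yy)``
    for the planar arm, a single value for a one-joint limb.
    """
    desired = np.atleast_1d(np.asarray(desired, dtype=float))
    smap = build_linear_map(arm, posture)
    if desired.shape != (smap.n_constraints,):
        raise ValueError(
            f"desired stiffness must have {smap.n_constraints} entries, got {desired.shape}"
        )
    equil = arm.moment_arms * arm.f_max  # R diag(f_max)
    A = np.vstack([equil, smap.matrix])
    b = np.concatenate([np.zeros(arm.n_joints), desired])
    return TaskConstraints(A_eq=A, b_eq=b, n_equilibrium=arm.n_joints, f_max=arm.f_max)


def feasible_segment(
    c: TaskConstraints, eq_tol: float = EQ_TOL, box_tol: float = BOX_TOL
) -> FeasibleSegment:
    """Intersect the equality solution set with the activation box.

    Returns an empty segment when the equality system is inconsistent or the
    affine solution set misses the box.  Generic tasks have a 1-D null space
    and yield an exact parameter interval; 0-D solutions are returned as
    single-point segments; null spaces of dimension >= 2 are flagged
    degenerate and carry the polytope vertices instead.
    """
    A, b = c.A_eq, c.b_eq
    m = c.n_muscles
    a0, *_ = np.linalg.lstsq(A, b, rcond=None)
    resid = np.linalg.norm(A @ a0 - b)
    if resid > eq_tol * (1.0 + np.linalg.norm(b)):
        return _empty(m, null_dim=-1)
    N = scipy.linalg.null_space(A)
    dim = N.shape[1]
    if dim == 0:
        inside = np.all(a0 >= -box_tol) and np.all(a0 <= 1.0 + box_tol)
        if not inside:
            return _empty(m, null_dim=0)
        return FeasibleSegment(
            a0=np.clip(a0, 0.0, 1.0), direction=np.zeros(m), t_range=(0.0, 0.0),
            empty=False, null_dim=0,
        )
    if dim == 1:
        d = N[:, 0]
        lo, hi = _line_box_interval(a0, d, box_tol)
        if lo is None:
            return _empty(m, null_dim=1)
        # report the tight interval; the slack above only decides emptiness,
        # so touching constraints collapse to a point instead of leaking
        # energy through the box tolerance
        lo_t, hi_t = _line_box_interval(a0, d, 0.0)
        if lo_t is None or lo_t > hi_t:
            mid = 0.5 * (lo + hi)
            lo_t = hi_t = mid
        return FeasibleSegment(a0=a0, direction=d, t_range=(lo_t, hi_t), empty=False, null_dim=1)
    verts = _polytope_vertices(A, b, N, a0, eq_tol, box_tol)
    if verts.size == 0:
        return _empty(m, null_dim=dim, degenerate=True)
    return FeasibleSegment(
        a0=a0, direction=np.zeros(m), t_range=(0.0, 0.0), empty=False,
        null_dim=dim, degenerate=True, vertices=verts,
    )


def auto_scale(c: TaskConstraints, target_max: float = 0.5) -> float:
    """Scale for the desired stiffness so the task sits clear of saturation.

    Realizability of a shape/orientation pair is a property of the equality
    solution line alone once the stiffness is small enough that the upper
    activation bounds never bind: scaling the target by ``s`` scales the
    whole line by ``s`` while the nonnegativity constraints are scale-free.
    This picks an interior nonnegative point of the solution line (when one
    exists) and returns the ``s`` that places its largest activation at
    ``target_max``, so the finite-scale verdict coincides with the
    vanishing-scale one.  Falls back to scaling the minimum-norm solution
    when the line has no nonnegative point (any scale is then infeasible) or
    the system is degenerate; returns 1.0 for an inconsistent system or a
    zero target (scaling cannot help either).
    """
    a_mn, *_ = np.linalg.lstsq(c.A_eq, c.b_eq, rcond=None)
    resid = np.linalg.norm(c.A_eq @ a_mn - c.b_eq)
    if resid > EQ_TOL * (1.0 + np.linalg.norm(c.b_eq)):
        return 1.0
    anchor = a_mn
    N = scipy.linalg.null_space(c.A_eq)
    if N.shape[1] == 1:
        d = N[:, 0]
        lo, hi = -math.inf, math.inf
        feasible = True
        for ai, di in zip(a_mn, d):
            if abs(di) < 1e-14:
                if ai < -BOX_TOL:
                    feasible = False
                continue
            t = -ai / di
            if di > 0:
                lo = max(lo, t)
            else:
                hi = min(hi, t)
        if feasible and lo <= hi + BOX_TOL:
            if not math.isfinite(lo):
                lo = hi - 1.0
            if not math.isfinite(hi):
                hi = lo + 1.0
            anchor = a_mn + 0.5 * (lo + hi) * d
    peak = float(np.max(np.abs(anchor)))
    if peak < 1e-12:
        return 1.0
    return target_max / peak


def scaled(c: TaskConstraints, s: float) -> TaskConstraints:
    """Same task with the desired stiffness (hence ``b_eq``) scaled by ``s``."""
    return TaskConstraints(A_eq=c.A_eq, b_eq=s * c.b_eq, n_equilibrium=c.n_equilibrium, f_max=c.f_max)


def is_realizable(
    arm: ArmModel,
    posture: Posture | None,
    shape: float,
    orientation_deg: float,
    scale: float | str = "auto",
) -> bool:
    """Whether a desired ellipse (shape, orientation) is achievable.

    ``scale="auto"`` picks the saturation-safe size via :func:`auto_scale`,
    which makes the verdict a property of shape and orientation alone.
    """
    desired = desired_stiffness(shape, orientation_deg, 1.0)
    c = assemble_constraints(arm, posture, desired)
    s = auto_scale(c) if scale == "auto" else float(scale)
    return not feasible_segment(scaled(c, s)).empty


def _energy_quadratic(seg: FeasibleSegment, f_max: np.ndarray):
    w0 = f_max * seg.a0
    wd = f_max * seg.direction
    return float(wd @ wd), 2.0 * float(w0 @ wd), float(w0 @ w0)


def _energy_of(a: np.ndarray, f_max: np.ndarray) -> float:
    F = f_max * a
    return float(F @ F)


def min_energy(c: TaskConstraints, seg: FeasibleSegment | None = None):
    """Minimize the sum of squared muscle forces over the feasible set.

    Returns ``(activation, e_min)``; ``(None, None)`` when the task is
    unrealizable.  On a segment the minimizer is the clamped stationary
    point of the 1-D quadratic; degenerate polytopes are handled by a
    bounded quadratic solve over the null-space coordinates.
    """
    seg = feasible_segment(c) if seg is None else seg
    if seg.empty:
        return None, None
    if seg.degenerate:
        a = _degenerate_min(c, seg)
        return a, _energy_of(a, c.f_max)
    c2, c1, c0 = _energy_quadratic(seg, c.f_max)
    lo, hi = seg.t_range
    t = -c1 / (2.0 * c2) if c2 > 0 else lo
    t = min(hi, max(lo, t))
    a = np.clip(seg.point(t), 0.0, 1.0)
    return a, _energy_of(a, c.f_max)


def max_energy(c: TaskConstraints, seg: FeasibleSegment | None = None):
    """Maximize the convex energy over the feasible set.

    A convex function on a segment peaks at an endpoint, so both endpoints
    are evaluated and the larger wins; degenerate polytopes take the maximum
    over their vertices (a convex function on a polytope peaks at a vertex).
    """
    seg = feasible_segment(c) if seg is None else seg
    if seg.empty:
        return None, None
    if seg.degenerate:
        energies = [_energy_of(v, c.f_max) for v in seg.vertices]
        i = int(np.argmax(energies))
        return seg.vertices[i], energies[i]
    a_lo, a_hi = (np.clip(a, 0.0, 1.0) for a in seg.endpoints)
    e_lo, e_hi = _energy_of(a_lo, c.f_max), _energy_of(a_hi, c.f_max)
    return (a_hi, e_hi) if e_hi >= e_lo else (a_lo, e_lo)


def energy_range(c: TaskConstraints, seg: FeasibleSegment | None = None) -> EnergyRange | None:
    """Energy extremes and available percent reduction for one task."""
    seg = feasible_segment(c) if seg is None else seg
    if seg.empty:
        return None
    a_min, e_min = min_energy(c, seg)
    a_max, e_max = max_energy(c, seg)
    e_min = min(e_min, e_max)  # guard rounding inversions
    return EnergyRange(e_min=e_min, e_max=e_max, a_min=a_min, a_max=a_max)


def oracle_energy_bracket(
    c: TaskConstraints, n_samples: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Sampled energy extremes along the feasible segment (verification aid).

    Draws ``n_samples`` uniform parameters on the segment (endpoints always
    included) and returns the extreme energies; deterministic for a fixed
    seed.  Brackets the true extremes from the inside.
    """
    seg = feasible_segment(c)
    if seg.empty:
        raise ValueError("cannot sample an empty feasible set")
    rng = np.random.default_rng(seed)
    lo, hi = seg.t_range
    ts = np.concatenate([[lo, hi], rng.uniform(lo, hi, size=max(0, n_samples - 2))])
    energies = [_energy_of(seg.point(t), c.f_max) for t in ts]
    return float(np.min(energies)), float(np.max(energies))


def realizable_fraction(
    arm: ArmModel,
    posture: Posture | None,
    shape: float,
    scale: float | str = "auto",
    step_deg: float = 5.0,
) -> float:
    """Fraction of major-axis orientations achievable at a given shape.

    Orientations are tested on a grid from 0 (inclusive) to 180 degrees
    (exclusive) in ``step_deg`` increments; ``step_deg`` must divide 180.
    """
    if shape <= 1.0:
        raise ValueError("orientation fraction needs shape > 1 (orientation undefined for circles)")
    n = 180.0 / step_deg
    if abs(n - round(n)) > 1e-9:
        raise ValueError("step_deg must divide 180")
    n = int(round(n))
    hits = sum(
        is_realizable(arm, posture, shape, i * step_deg, scale=scale) for i in range(n)
    )
    return hits / n


def _empty(m: int, null_dim: int, degenerate: bool = False) -> FeasibleSegment:
    return FeasibleSegment(
        a0=np.full(m, np.nan), direction=np.zeros(m), t_range=(math.nan, math.nan),
        empty=True, null_dim=null_dim, degenerate=degenerate,
    )


def _line_box_interval(a0: np.ndarray, d: np.ndarray, box_tol: float):
    """Parameter interval for which ``a0 + t d`` stays in ``[0, 1]^M``."""
    lo, hi = -math.inf, math.inf
    for ai, di in zip(a0, d):
        if abs(di) < 1e-14:
            if ai < -box_tol or ai > 1.0 + box_tol:
                return None, None
            continue
        t0, t1 = (-box_tol - ai) / di, (1.0 + box_tol - ai) / di
        if t0 > t1:
            t0, t1 = t1, t0
        lo, hi = max(lo, t0), min(hi, t1)
    if lo > hi:
        return None, None
    return lo, hi


def _polytope_vertices(A, b, N, a0, eq_tol: float, box_tol: float) -> np.ndarray:
    """Vertices of ``{a0 + N t} ∩ [0, 1]^M`` by facet-combination enumeration.

    Only exercised for non-generic arms (null-space dimension >= 2); the
    muscle counts involved keep the combinatorics tiny.
    """
    m, k = N.shape
    # inequality rows in t-space: -N t <= a0 (lower) and N t <= 1 - a0 (upper)
    G = np.vstack([-N, N])
    h = np.concatenate([a0, 1.0 - a0])
    verts = []
    for rows in itertools.combinations(range(2 * m), k):
        Gk = G[list(rows)]
        if np.linalg.matrix_rank(Gk) < k:
            continue
        try:
            t = np.linalg.solve(Gk, h[list(rows)])
        except np.linalg.LinAlgError:
            continue
        if np.all(G @ t <= h + box_tol):
            a = np.clip(a0 + N @ t, 0.0, 1.0)
            if not any(np.allclose(a, v, atol=1e-9) for v in verts):
                verts.append(a)
    return np.array(verts) if verts else np.empty((0, m))


def _degenerate_min(c: TaskConstraints, seg: FeasibleSegment) -> np.ndarray:
    """Bounded least-squares energy minimum over a >=2-D feasible polytope."""
    from scipy.optimize import LinearConstraint, minimize

    A, b = c.A_eq, c.b_eq
    N = scipy.linalg.null_space(A)
    a0 = seg.a0
    W = np.diag(c.f_max)

    def fun(t):
        F = W @ (a0 + N @ t)
        return float(F @ F)

    def grad(t):
        a = a0 + N @ t
        return 2.0 * N.T @ (c.f_max**2 * a)

    lc = LinearConstraint(N, -a0, 1.0 - a0)
    t0 = np.mean([np.linalg.lstsq(N, v - a0, rcond=None)[0] for v in seg.vertices], axis=0)
    res = minimize(fun, t0, jac=grad, constraints=[lc], method="SLSQP")
    return np.clip(a0 + N @ res.x, 0.0, 1.0)
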