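"""Muscle synergies as activation-space constraints.

A synergy basis is a nonnegative muscles x synergies weight matrix ``W``;
the controller commands the synergy activations ``c >= 0`` and the muscles
receive ``a = W c``.  Because ``W`` restricts ``a`` to a low-dimensional
cone, synergies shrink the feasible activation set for any task.

The shipped two-synergy basis follows the grouping observed by Osu and Gomi
in EMG of static arm postures: a shoulder synergy driving both mono-articular
shoulder muscles with unity weight, and an elbow synergy driving the
mono-articular elbow muscles with unity weight and the bi-articular muscles
with weight one-half (bi-articular co-contraction contributed about half the
elbow stiffness of the mono-articular elbow muscles).  On this manifold one
free parameter — the elbow/shoulder activation ratio — controls both the
shape and the orientation of the endpoint stiffness ellipse, so the two are
obligatorily coupled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.optimize import linprog

from .arm import ArmModel, Posture
from .feasibility import BOX_TOL, EQ_TOL, TaskConstraints, assemble_constraints, auto_scale, scaled
from .stiffness import StiffnessEllipse, ellipse_of, endpoint_stiffness, unvectorize_stiffness

__all__ = [
    "SynergyBasis",
    "SynergyRealizability",
    "osu_gomi_basis",
    "synergy_activation",
    "ratio_sweep",
    "orientation_range",
    "constrained_realizability",
    "synergy_fraction",
    "manifold_shapes",
]


@dataclass(frozen=True)
class SynergyBasis:
    """Nonnegative muscles x synergies weight matrix with synergy names."""

    W: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        W = np.atleast_2d(np.asarray(self.W, dtype=float))
        if np.any(W < 0):
            raise ValueError("synergy weights must be nonnegative")
        if np.any(np.all(W == 0.0, axis=0)):
            raise ValueError("every synergy must drive at least one muscle")
        if len(self.names) != W.shape[1]:
            raise ValueError("need one name per synergy")
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "names", tuple(self.names))

    @property
    def n_muscles(self) -> int:
        return self.W.shape[0]

    @property
    def n_synergies(self) -> int:
        return self.W.shape[1]


def osu_gomi_basis() -> SynergyBasis:
    """The two-synergy shoulder/elbow basis for the default muscle ordering
    (shoulder flexor/extensor, elbow flexor/extensor, bi-articular
    flexor/extensor)."""
    W = np.array(
        [
            [1.0, 0.0],
            [1.0, 0.0],
            [0.0, 1.0],
            [0.0, 1.0],
            [0.0, 0.5],
            [0.0, 0.5],
        ]
    )
    return SynergyBasis(W=W, names=("shoulder", "elbow"))


def synergy_activation(basis: SynergyBasis, c) -> np.ndarray:
    """Muscle activation ``a = W c`` for synergy commands ``c >= 0``.

    Raises if any muscle saturates (``a_i > 1``), naming the muscle.
    """
    c = np.asarray(c, dtype=float)
    if c.shape != (basis.n_synergies,):
        raise ValueError(f"need {basis.n_synergies} synergy activations")
    if np.any(c < 0):
        raise ValueError("synergy activations must be nonnegative")
    a = basis.W @ c
    over = np.nonzero(a > 1.0 + 1e-12)[0]
    if over.size:
        raise ValueError(f"synergy command saturates muscle(s) {over.tolist()} (activation > 1)")
    return a


def ratio_sweep(
    arm: ArmModel,
    posture: Posture,
    basis: SynergyBasis,
    ratios=None,
    base_total: float = 0.5,
) -> list[tuple[float, StiffnessEllipse]]:
    """Endpoint-stiffness ellipses along the two-synergy activation manifold.

    For each ratio ``r = c_elbow / c_shoulder`` the commands are normalized
    to ``c_s + c_e = base_total`` (shape and orientation depend only on the
    ratio, so the normalization is display-only); commands that would
    saturate a muscle are scaled down, which leaves shape and orientation
    untouched.  Default ratio grid: 200 log-spaced points spanning
    [0.1, 10] (two orders of magnitude).
    """
    if basis.n_synergies != 2:
        raise ValueError("ratio_sweep needs a two-synergy basis")
    if ratios is None:
        ratios = np.logspace(-1.0, 1.0, 200)
    ratios = np.asarray(ratios, dtype=float)
    if np.any(ratios <= 0):
        raise ValueError("ratios must be positive")
    out: list[tuple[float, StiffnessEllipse]] = []
    for r in ratios:
        c = base_total * np.array([1.0, r]) / (1.0 + r)
        peak = float(np.max(basis.W @ c))
        if peak > 1.0:  # saturation guard: pure rescaling, ellipse shape unchanged
            c = c * (1.0 / peak)
        a = synergy_activation(basis, c)
        K = endpoint_stiffness(arm, posture, a)
        out.append((float(r), ellipse_of(K)))
    return out


def orientation_range(sweep: list[tuple[float, StiffnessEllipse]]) -> tuple[float, float]:
    """Circular span of ellipse orientations covered by a sweep.

    Orientations live on a 180-degree-periodic axis; the range is 180 minus
    the largest empty arc between consecutive sampled orientations.  Returns
    ``(range_deg, range_deg / 180)``.
    """
    angles = sorted(
        e.orientation_deg for _, e in sweep if e.orientation_deg is not None
    )
    if len(angles) < 2:
        raise ValueError("need at least two sweep points with defined orientation")
    gaps = [b - a for a, b in zip(angles, angles[1:])]
    gaps.append(angles[0] + 180.0 - angles[-1])  # wrap-around arc
    rng = 180.0 - max(gaps)
    return rng, rng / 180.0


@dataclass(frozen=True)
class SynergyRealizability:
    """Outcome of a realizability test under a synergy constraint."""

    realizable: bool
    solution_dim: int
    c: np.ndarray | None
    a: np.ndarray | None


def constrained_realizability(
    arm: ArmModel,
    posture: Posture | None,
    desired,
    basis: SynergyBasis,
    scale: float | str = "auto",
) -> SynergyRealizability:
    """Test a desired stiffness with activations restricted to ``a = W c``.

    Substitutes the synergy map into the task's equality system and solves in
    synergy space with ``c >= 0`` and ``W c <= 1``; reports the dimension of
    the equality solution set there.  An identity ``W`` reproduces the
    unconstrained test.
    """
    task = assemble_constraints(arm, posture, desired)
    if scale == "auto":
        scale = auto_scale(task)
    task = scaled(task, float(scale))
    AW = task.A_eq @ basis.W
    b = task.b_eq
    c0, *_ = np.linalg.lstsq(AW, b, rcond=None)
    if np.linalg.norm(AW @ c0 - b) > EQ_TOL * (1.0 + np.linalg.norm(b)):
        return SynergyRealizability(False, -1, None, None)
    N = scipy.linalg.null_space(AW)
    dim = N.shape[1]
    if dim == 0:
        ok = _command_in_box(basis, c0)
        return SynergyRealizability(ok, 0, c0 if ok else None, basis.W @ c0 if ok else None)
    # feasibility of {c0 + N t : c >= 0, W c <= 1} via LP (any objective)
    G = np.vstack([-N, -basis.W @ N, basis.W @ N])
    h = np.concatenate([c0, basis.W @ c0, 1.0 - basis.W @ c0])
    res = linprog(np.zeros(dim), A_ub=G, b_ub=h + BOX_TOL, bounds=[(None, None)] * dim)
    if not res.success:
        return SynergyRealizability(False, dim, None, None)
    c = c0 + N @ res.x
    c = np.maximum(c, 0.0)
    return SynergyRealizability(True, dim, c, np.clip(basis.W @ c, 0.0, 1.0))


def synergy_fraction(
    arm: ArmModel, posture: Posture, basis: SynergyBasis, ratios=None
) -> tuple[float, float]:
    """Orientation range (deg) and fraction of 180 covered on the synergy
    manifold at one posture (convenience wrapper around the sweep)."""
    sweep = ratio_sweep(arm, posture, basis, ratios=ratios)
    return orientation_range(sweep)


def manifold_shapes(
    arm: ArmModel, posture: Posture, basis: SynergyBasis, ratios=(0.1, 1.0, 10.0)
) -> list[float]:
    """Ellipse condition numbers produced on the synergy manifold at the
    given elbow/shoulder ratios (used as reference ellipse shapes)."""
    sweep = ratio_sweep(arm, posture, basis, ratios=np.asarray(ratios, dtype=float))
    return [e.shape for _, e in sweep]


def _command_in_box(basis: SynergyBasis, c: np.ndarray) -> bool:
    a = basis.W @ c
    return bool(
        np.all(c >= -BOX_TOL) and np.all(a >= -BOX_TOL) and np.all(a <= 1.0 + BOX_TOL)
    )
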