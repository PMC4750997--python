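"""Reference and randomized limb models.

Three families: the nominal six-muscle planar arm (unit links, unit moment
arms, unit maximal forces) used for all headline analyses; a one-joint
three-muscle limb whose feasible activation set can be drawn in 3-D, handy
for illustrating how equality constraints cut the activation cube down to a
line; and seeded random arms for property testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arm import ArmModel

__all__ = ["FixtureSpec", "make_default_arm", "make_single_joint_limb", "make_random_arm"]


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a random arm: seeded, so the same spec always yields the
    same model.  Moment-arm magnitudes are drawn uniformly in
    ``magnitude_range`` (bounded away from zero to avoid near-singular test
    systems)."""

    seed: int = 0
    muscle_count: int = 6
    joint_count: int = 2
    magnitude_range: tuple[float, float] = (0.3, 1.5)


def make_default_arm(**overrides) -> ArmModel:
    """The nominal six-muscle planar arm.

    Unit link lengths, unit-magnitude moment arms, ``f_max`` identity and
    stiffness scale ``alpha = 1``.  Muscle order: shoulder flexor/extensor,
    elbow flexor/extensor, bi-articular flexor/extensor — the bi-articular
    muscles flex (or extend) both joints together, never one of each.
    """
    return ArmModel(**overrides)


def make_single_joint_limb(moment_arms=(1.0, 2.0, -1.0), f_max=None, alpha: float = 1.0) -> ArmModel:
    """One rotational joint driven by three muscles.

    This synthetic illustration limb (the specific moment arms are a
    convenient stand-in, not measured values) supports equilibrium with
    positive stiffness as long as the moment arms carry mixed signs; with
    all arms of one sign the torque constraint forces zero activation and a
    construction warning is raised.
    """
    r = np.asarray(moment_arms, dtype=float)
    if r.ndim != 1 or np.any(r == 0.0):
        raise ValueError("need a flat vector of nonzero moment arms")
    if np.all(r > 0) or np.all(r < 0):
        import warnings

        warnings.warn(
            "all moment arms share one sign: equilibrium forces zero activation, "
            "so no positive stiffness is realizable",
            stacklevel=2,
        )
    return ArmModel(
        link_lengths=np.array([1.0]),
        moment_arms=r[None, :],
        f_max=f_max,
        alpha=alpha,
        joint_limits=np.array([[-np.pi, np.pi]]),
    )


def make_random_arm(spec: FixtureSpec) -> ArmModel:
    """Seeded random arm with a full-rank moment-arm matrix.

    Each joint gets at least one muscle pulling each way (antagonist
    coverage), so a strictly positive equilibrium activation exists and the
    torque rows have full rank.  Rejection-sampled; raises after a bounded
    number of failed draws.
    """
    if spec.muscle_count < 2 * spec.joint_count:
        raise ValueError("need at least two muscles (an antagonist pair) per joint")
    lo, hi = spec.magnitude_range
    if not (0 < lo < hi):
        raise ValueError("magnitude_range must be 0 < lo < hi")
    rng = np.random.default_rng(spec.seed)
    for _ in range(200):
        mags = rng.uniform(lo, hi, size=(spec.joint_count, spec.muscle_count))
        signs = np.where(rng.random((spec.joint_count, spec.muscle_count)) < 0.5, -1.0, 1.0)
        # guarantee antagonist coverage: first 2*J columns form +/- pairs per joint
        for j in range(spec.joint_count):
            signs[j, 2 * j] = 1.0
            signs[j, 2 * j + 1] = -1.0
            mags[j, 2 * j + 1] = mags[j, 2 * j]  # matched pair magnitudes
        R = mags * signs
        # silence muscles' cross-joint action for the designated pairs
        for j in range(spec.joint_count):
            for jj in range(spec.joint_count):
                if jj != j:
                    R[jj, 2 * j] = R[jj, 2 * j + 1] = 0.0
        if np.linalg.matrix_rank(R) == spec.joint_count and not np.any(
            np.all(R == 0.0, axis=0)
        ):
            link_lengths = np.ones(2) if spec.joint_count == 2 else np.ones(1)
            return ArmModel(link_lengths=link_lengths, moment_arms=R)
    raise RuntimeError("failed to draw a full-rank arm within the attempt budget")
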