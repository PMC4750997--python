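# Methods

## Model and assumptions

The limb is a planar two-link arm with revolute shoulder and elbow, each
link of length 1 (dimensionless units throughout), driven by M = 6 muscles
through a signed moment-arm matrix `R` (joints × muscles, `τ = R F`).
Positive entries are flexor torques. The default routing is two
mono-articular shoulder muscles (±1, 0), two mono-articular elbow muscles
(0, ±1), and a bi-articular pair (+1, +1) / (−1, −1) — bi-articular columns
never mix signs, mirroring the anatomy of arms, which have no muscle
flexing one joint while extending the other. Muscle order is fixed and
documented: shoulder flexor, shoulder extensor, elbow flexor, elbow
extensor, bi-articular flexor, bi-articular extensor.

Muscle stiffness is a lumped, activation-proportional scalar per
musculotendon: `k_i = α f_max,i a_i` with `a_i ∈ [0, 1]`, `α = 1` and
`F_max = I` by default. This is the standard mechanical-analogue treatment
of active musculotendon stiffness; passive stiffness, reflex (time-delayed)
stiffness, force–length/velocity properties and signal-dependent noise are
deliberately out of scope, and only the zero-external-force form of the
endpoint map is used, under which `K_end = J⁻ᵀ R diag(k) Rᵀ J⁻¹` is exactly
symmetric.

Angles are radians internally and degrees at every user surface. The
stiffness vectorization order is `(K_xx, K_xy, K_yy)`; any consistent order
gives identical results.

## Feasibility by affine geometry

A task stacks `R F_max a = 0` (2 rows) and the linearized stiffness rows
`M a = K̃_desired` (3 rows) into `A_eq a = b_eq`, bounded by the activation
box. Rather than trusting a QP solver's status code, feasibility is decided
exactly: the minimum-norm solution and the null space of `A_eq` come from
SVD (lstsq / `scipy.linalg.null_space`); for the generic one-dimensional
null space the solution line is intersected with `[0,1]^M` in closed form.
Equality-consistency tolerance is 1e-8 (relative to `‖b‖`), box tolerance
1e-9; both only decide emptiness — the reported parameter interval is
tight, so touching constraints collapse to a point rather than leaking
through the tolerance. Null spaces of dimension ≥ 2 (non-generic arms,
e.g. duplicated muscles) fall back to vertex enumeration of the polytope
(energy maximum over vertices, since a convex function on a polytope peaks
at a vertex) and a bounded SLSQP solve for the minimum, and are flagged.

**Stiffness scale.** The size of the desired stiffness is not part of the
shape/orientation realizability question: scaling the target by `s` scales
the whole solution line by `s` while the nonnegativity constraints are
scale-free, so below saturation the verdict is scale-invariant. The default
`scale="auto"` picks an interior nonnegative point of the solution line
(midpoint of the nonnegative parameter interval) and sizes the target so
that point's largest activation is 0.5. This makes the finite-scale verdict
coincide with the vanishing-scale one and keeps energy quantities well
inside the box; a fixed numeric scale can be passed instead. Percent energy
reduction is invariant to the scale below saturation because both extremes
scale as `s²`.

## Energy extremization

Effort is `Σ (f_max,i a_i)²`. Along the feasible segment it is a 1-D convex
quadratic: the minimum is its stationary point clamped to the interval, the
maximum is the larger endpoint. No iterative solver is involved in the
generic path; a generic SLSQP solve and a dense-sampling bracket
(`oracle_energy_bracket`, seeded and deterministic) serve as independent
cross-checks in the tests, not as the implementation.

## Synergies

A synergy basis is a nonnegative muscles × synergies matrix `W`;
activations are `a = W c`, `c ≥ 0`. The shipped basis follows the
experimentally reported shoulder/elbow grouping: shoulder column
(1, 1, 0, 0, 0, 0), elbow column (0, 0, 1, 1, 0.5, 0.5) — the bi-articular
weight of one-half reflects that bi-articular co-contraction contributed
about half the elbow stiffness of the mono-articular elbow muscles. On the
default arm this basis drives antagonist pairs equally, so every manifold
point satisfies equilibrium exactly, and one parameter — the ratio
`c_elbow/c_shoulder` — controls both ellipse shape and orientation.

The ratio sweep uses 200 log-spaced ratios in [0.1, 10] by default (the
sampling density is a package choice; the reported range changes by < 1°
at double density). Commands are normalized to `c_s + c_e = 0.5`
(display-only: shape and orientation depend only on the ratio), and
saturating commands are rescaled down, which cannot change shape or
orientation. Orientation ranges are circular on the 180°-periodic axis:
range = 180° minus the largest empty arc between sampled orientations.

Constrained realizability substitutes `a = W c` into the task equalities
and solves in synergy space (`c ≥ 0`, `W c ≤ 1`), reporting the equality
solution-space dimension there; a one-joint three-muscle limb with the tie
`a₁ = 2 a₂` pins the solution to a single point (dimension zero).

## Workspace maps

Maps run on a joint-angle grid (default 25×25, a package choice) over the
configured joint limits, excluding Jacobian-singular elbow angles; each
record also carries the endpoint coordinates for workspace rendering, which
avoids inverse-kinematics branch ambiguity. Joint limits default to
θ₁ ∈ [0°, 160°], θ₂ ∈ [5°, 175°] — a plausible planar human workspace
bounded away from the elbow singularities; they are config-overridable and
are a documented choice, not a measured workspace. The orientation grid is
36 steps of 5° starting at 0° inclusive, 180° exclusive. The
energy-reduction map aggregates per posture as the **maximum over
realizable orientations** of the percent reduction (the natural "best case
at any orientation" reading); postures with no realizable orientation are
flagged rather than valued.

## Monotonicity of orientability in eccentricity

The realizable vectorized stiffnesses form a convex cone (the image of the
nonnegative, equilibrium-satisfying activations under the linear map).
Since a target with condition number `c` at orientation φ is
`I + (c−1) uuᵀ` up to scale, it is a positive combination of the isotropic
matrix and any more-eccentric target at the same orientation. Hence
*wherever the circle is realizable*, the fraction of realizable
orientations is non-increasing in the condition number. At postures where
the isotropic stiffness itself is unrealizable this guarantee vanishes, and
the fraction can genuinely increase with eccentricity (e.g. at
θ = (60°, 60°) the default arm realizes no orientation at condition number
1.2 but a quarter of them at 8). Tests assert the pointwise monotone trend
only under the circle-realizability gate, plus the map-level decrease of
the workspace-mean fraction.

## Numerical choices and degenerate inputs

* Jacobian singularity: `|sin θ₂| < 1e-9` raises a named error where an
  inverse is required; grid construction drops such rows.
* Ellipse extraction uses the symmetric eigendecomposition (identical to
  SVD for symmetric PSD matrices); an eigenvalue gap below 1e-9 relative
  flags the orientation as undefined (circle) instead of returning an
  arbitrary angle. Zero or non-PD matrices are rejected.
* Unrealizable tasks are results, not exceptions: segment queries return an
  empty segment, energy queries return `None`, and the CLI exits 0 with
  `"realizable": false`.
* All randomness (random arms, the sampling oracle) is
  `numpy.random.default_rng` under explicit seeds; CLI outputs format
  floats at 12 significant digits so reruns are byte-identical.

## What the generators emulate — and what they do not

The nominal arm reproduces the idealized model used across the planar
arm-stiffness literature: unit geometry, equal moment arms, equal muscle
strengths, linear activation-to-stiffness gain. Random arms (seeded,
moment-arm magnitudes uniform in ±[0.3, 1.5] with guaranteed antagonist
pairs) exist to property-test the algebra, not to represent anatomy.
Passing tests therefore validate the constraint geometry and optimization
exactly, but say nothing about physiological moment-arm asymmetries,
nonlinear muscle mechanics, reflex contributions, or dynamic conditions —
all of which would move the numbers while leaving the structural
conclusions (synergies shrink the feasible set; posture reshapes it)
intact.

## Known limitations

* The fraction-of-orientations summary for the three synergy-manifold
  shapes includes the ratio-0.1 shape (condition number ≈ 9.3 at the
  reference posture), which is fully orientable nowhere near that posture —
  only 3 of 36 orientations are realizable there; the mean fraction over
  the three shapes is therefore ≈ 0.69 rather than 1.
* Vertex enumeration is combinatorial in the null-space dimension and is
  intended only for small non-generic systems.
* Single-joint limbs reuse the same pipeline with an identity Jacobian;
  they have one stiffness constraint and no posture dependence.
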