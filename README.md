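# stiffsynth

Feasible endpoint-stiffness synthesis and energy analysis for tendon-driven
planar limbs.

## The problem

When a human (or robot) arm holds a posture, neural drive to the muscles
sets not only the joint torques but also the *stiffness* of the hand: the
2×2 symmetric matrix `K_end` relating a small hand displacement to the
restoring force, usually visualized as an ellipse with a size (trace), a
shape (condition number, the major/minor eigenvalue ratio) and an
orientation (major-axis angle). How freely can a controller choose that
ellipse, given that muscles can only pull, that activations saturate, and
that the posture must stay in equilibrium? And once an ellipse is fixed, how
much freedom is left to spend less (or more) metabolic effort producing it?
These questions matter for interpreting conflicting experimental reports on
stiffness control, and for understanding what muscle synergies — obligatory
correlated activation of muscle groups — take away from the controller.

`stiffsynth` answers them for a planar two-link, six-muscle arm (two
mono-articular muscle pairs and one bi-articular pair) by exact
constraint geometry rather than black-box optimization.

## The model

With activation `a ∈ [0,1]^M`, muscle stiffness is `k_i = α f_max,i a_i`,
joint stiffness is `K_joint = R diag(k) Rᵀ` (R the signed joints×muscles
moment-arm matrix), and endpoint stiffness is `K_end = J⁻ᵀ K_joint J⁻¹`
(J the posture-dependent Jacobian). Because each step is linear in `a`,
the upper triangle `(K_xx, K_xy, K_yy)` is a single 3×M matrix applied to
`a`. A static task therefore imposes linear equalities on `a`:

* equilibrium: `R F_max a = 0` (2 rows),
* desired stiffness: `M a = K̃_desired` (3 rows),
* bounds: `0 ≤ a ≤ 1`.

For six muscles the solution set is generically a **line segment** in the
activation hypercube (6 − 2 − 3 = 1 free dimension). A desired ellipse is
*realizable* iff that segment is non-empty — decided here by exactly
intersecting the solution line with the box. Effort is the sum of squared
muscle forces `Σ (f_max,i a_i)²`, a convex quadratic along the segment: its
minimum is the clamped 1-D stationary point, its maximum sits at a segment
endpoint, and `100·(e_max − e_min)/e_max` is the percent energy reduction
available without changing the ellipse. A synergy basis `W ≥ 0` restricts
`a = W c`, shrinking the feasible set; the shipped two-synergy
shoulder/elbow basis (unity weights on the mono-articular groups, one-half
on the bi-articular pair) leaves a single ratio `c_elbow/c_shoulder`
controlling both ellipse shape and orientation.

## Worked example

Orientation coverage under the shoulder/elbow synergies, with the hand at
(0, 1) for unit links (shoulder 30°, elbow 120°):

```sh
$ stiffsynth synergy-sweep --out demo
demo/synergy_sweep.json
```

The summary reports

```
"orientation_range_deg": 71.8246597721,
"realizable_fraction":   0.399025887623,
```

meaning that sweeping the elbow/shoulder activation ratio over two decades
(0.1 to 10, 200 log-spaced points) rotates the ellipse's major axis through
only ≈72° of the 180° circle — about 40% coverage, with shape and
orientation covarying along the way. Without synergies, all 36 orientations
tested every 5° are realizable at this posture for moderate shapes.

Energy headroom for one task (shape 1.5, major axis at 90°, same posture):

```sh
$ stiffsynth energy --shape 1.5 --orientation 90 --out demo2
```

```
"e_min": 0.826530612245,
"e_max": 1.31632653061,
"reduction_pct": 37.2093023256,
```

so the controller could produce this exact ellipse while spending 37% less
effort than the most wasteful feasible activation.

The same library surface is importable (`stiffsynth.is_realizable`,
`stiffsynth.energy_range`, `stiffsynth.ratio_sweep`,
`stiffsynth.realizable_fraction_map`, …); the CLI also offers
`check`, `fraction-map`, `reduction-map`, `synergy-map` and `fixtures`.

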