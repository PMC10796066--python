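# Methods

## Model

Skin inflammation is represented by two diffusible fields on a 2D
periodic patch of skin: the pro-inflammatory mediator concentration
`a(x, y, t)` (the proxy for visible erythema) and the anti-inflammatory
mediator `i(x, y, t)`. In nondimensional form (concentrations scaled by
the Hill thresholds, time by the inhibitor clearance rate):

    da/dt = p_a + q_a a^n / ((a^n + 1)(i + 1)) - r_a a + D_a ∆a
    di/dt = p_i + q_i a^n i^n / ((a^n + 1)(i^n + 1)) - i + D_i ∆i

The activator autoactivates through a saturating Hill term (cooperativity
`n`, default 2), is repressed hyperbolically by the inhibitor, and both
species have basal production (`p_a`, `p_i`), saturable feedback-driven
production (`q_a`, `q_i`) and linear clearance (`r_a` relative to the
inhibitor's unit rate). The two diffusion coefficients are equal by
default (`D_a = D_i = 0.3`), reflecting the similar molecular weights of
the mediators; equal diffusion shifts the whole linear spectrum rigidly
(`λ(k) = λ(0) − D k²`), so no Turing (diffusion-driven) instability is
possible, and none is observed. The spatial coordinate is treated as
already nondimensional: the diffusion scaling carries no explicit length
scale, so `D` is interpreted in units of the simulation grid.

Hill terms are evaluated as `1 / (1 + x^(−n))` for `x > 1` so that large
transient concentrations cannot overflow. The Jacobian of the reaction
terms is supplied analytically (and cross-checked against central finite
differences in the tests) because stability classification near
bifurcation points needs accurate eigenvalues.

## Well-mixed analysis

Steady states are enumerated by reducing the 2D root problem to scalar
scans along the activator nullcline, which has the closed form
`i(a) = q_a a^n / ((a^n + 1)(r_a a − p_a)) − 1` for `r_a a > p_a`
(for `r_a a ≤ p_a` the activator rate is strictly positive, so all
steady states lie on this branch). Two complementary parametrizations
— by `a` (with logarithmic refinement near the pole at `a = p_a/r_a`,
where the branch is near-vertical) and by `i` (through the
degree-(n+1) polynomial in `a`, which also handles the feedback-free
limit `q_a → 0`) — are scanned for sign changes of the inhibitor rate;
each bracket is solved by Brent's method, polished with a 2D
quasi-Newton step, deduplicated at radius 1e−6, and classified by the
Jacobian eigenvalues. Eigenvalue real parts within 1e−8 of zero are
reported "marginal" and excluded from the regime census, so sweep
cells sitting numerically on a bifurcation do not get misclassified.
The tests validate the finder against a brute-force oracle (dense sign
scan of both nullcline families over the invariant box
`[0, (p_a+q_a)/r_a] × [0, p_i+q_i]`).

Census classes: one attractor plus two unstable states is *excitable*
(healthy state `S_H`, threshold state `S_T` = the unstable state nearest
`S_H`); two attractors separated by one unstable state is *bistable*
(healthy `S_H`, inflamed `S_I`, threshold `S_T`); a lone attractor is
*monostable_plain*; anything else is *other*. At strongly depleted
anti-inflammatory production the census genuinely holds five roots (two
stable, three unstable) — functionally bistable, but reported as
*other* to keep the census honest; the classifier's threshold logic
(below) handles this case uniformly.

Two empirical findings from this package's own phase-plane analysis are
worth flagging because they differ from a naive reading of the
qualitative literature:

1. **The printed "baseline" parameter point is oscillatory.** At
   `p_a=0.05, q_a=3.0, r_a=0.8, p_i=0.12, q_i=6.0` the high-concentration
   unstable state is an unstable focus surrounded by a stable limit
   cycle: a supra-threshold well-mixed trajectory from `(a, i) = (1, 0.01)`
   settles into sustained oscillations rather than returning to `S_H`.
   Spatially this manifests as autonomous target-wave emission — the
   wood-grain (gyrate-like) morphology. The package therefore uses this
   point as the *census baseline* and *gyrate* preset, and places the
   healthy *fading* preset at lower activator production (`q_a = 2.45`),
   where excursions genuinely return and stimulated waves fail to
   propagate.
2. **Shrinkage occurs with the threshold near the inflamed state.** At
   the fully printed shrinkage set (`p_a=0.03, q_a=2.0, r_a=0.99,
   p_i=0.02, q_i=6.0`) the computed states give `d(S_H, S_T) = 0.754 >
   d(S_T, S_I) = 0.400`, and the simulated supra-threshold disk indeed
   retreats. This is the ordering classical bistable front theory
   predicts for a retreating front (the inflamed state is the weakly
   stable one); the package reports the computed distances and ties
   shrinkage to `d_HT > d_TI`.

Well-mixed trajectories use fixed-step classic RK4 with `dt = 0.01`,
mirroring the PDE stepper; an adaptive integrator serves as a test
oracle only. A transient stimulation pulse is an additive constant
source on `da/dt` over `[t_on, t_off)` (defaults 10 and 11); clamping
the concentration instead was rejected because it suppresses the
feedback dynamics during the pulse.

## Spatial simulation

Square periodic grid, 5-point Laplacian, classic RK4 in time.
Defaults: `dx = 1.0`, `dt = 0.01` with an enforced stability guard
`dt ≤ dx²/(8 max(D_a, D_i))`, grid 128–192² depending on the
experiment. The cell size is deliberately of the order of the
diffusion length: pattern diversity in this model lives near the
propagation margin, where the discrete coupling `D/dx²` decides
whether excitation fronts propagate, break into arcs, or die — the
finer-grid continuum limit at these parameters supports propagation
almost everywhere and loses the fading regime. This makes `dx` a
modelling choice (effective cell-to-cell coupling between skin
regions), not a numerical convergence parameter; the homogeneous and
smooth-field tests confirm the integrator itself is fourth-order.

Initial condition: both fields uniform at 0.01. Stimulation is an
instantaneous additive update of the activator field at the step
nearest `apply_time` (default 1.0): Gaussian seeds of width `σ = 1.0`
and amplitude 1.0 at one or three centers, the same cross-profile along
a line segment, or along the edges of a random Voronoi reticulum
(capillary-like network; seeded RNG). Stimuli never touch the
inhibitor field. Overlapping deposits take the maximum rather than the
sum, so geometric overlaps do not double-dose.

## Pattern classification

Activity masks are `a > S_T` (the threshold-state level from the
census; for censuses without a clean `S_T`, the lowest unstable state
above the healthy attractor). The mask series is unwrapped (rolled so
the emptiest row/column becomes the cut) before topological analysis,
converting toroidal topology to planar. Per 8-connected component the
classifier measures: area; 4-connected enclosed holes (closed-ring
test); curve-likeness (skeleton length ≥ 2.5 × mean width); skeleton
endpoints (open vs closed curves); total tangent rotation along the
longest skeleton path (smoothed, unwrapped — ~π for a "C", > 2π for a
spiral); and ring nesting depth.

Decision list, first match wins: empty → *none*; open curve winding
beyond 2π, or interlocking C-pairs → *gyrate*; ≥ 2 nested rings →
*polycyclic*; a closed ring → *annular*; open curve-like components →
*arcuate*; filled hole-free blobs → *circular*; else *other*.

Time-series rules: if the suprathreshold area vanishes, the series is
*fading* when the outer radius stayed within 20% of its maximum until
the area fell below 10% of its peak (interior-first clearing), and
*shrinking* when the outer radius contracted monotonically. If the
area still grows over the last half of the series, the label comes
from the final snapshot's morphology. Chronically inflamed interiors
sit *above* the activity threshold, which would hide ring structure;
when the final field's peak exceeds the inflamed plateau `a_I` by more
than 30%, morphology is read from a brighter mask at `(a_I + peak)/2`
(redness contrast against the chronic plateau). The 20%, 10%, "last
half", and 30% constants are package choices exposed as keyword
arguments; the clinical descriptors they formalize are verbal.

## Parameter presets

The reference point `p_a=0.05, r_a=0.8, q_i=6.0, q_a=3.0, p_i=0.12`
(`D_a=D_i=0.3`, `n=2`) anchors the parameter plane, together with the
shrinkage set `p_a=0.03, q_a=2.0, r_a=0.99, p_i=0.02, q_i=6.0`. The
per-pattern simulation points are calibrated synthetic stand-ins:
each was located once by scanning the production plane around the
anchor and fixed thereafter —

| preset | change from anchor | regime | morphology |
|---|---|---|---|
| fading_fast | q_a = 2.3 | excitable | seeds decay quickly |
| fading | q_a = 2.45 | excitable | interior-first disappearance |
| arcuate | q_a = 2.5 | excitable | broken ring fragments |
| polycyclic | q_a = 2.54 | excitable | ring with nested core |
| gyrate | (anchor) | excitable + limit cycle | wood-grain: broken concentric rings |
| annular | q_a = 3.5 | bistable | single bright rim, chronic interior |
| circular | q_a = 3.5, p_i = 0.03 | bistable | filled expanding disk |
| shrinkage | printed set | bistable | retreating front |

Five of the six conditions (fading through annular) lie on the
activator-production axis `q_a` alone, giving a transition sequence
along rising pro-inflammatory production: fading → arcuate →
polycyclic → gyrate → annular. Depleting `p_i` from the anchor
instead ends in the circular pattern.

The healthy-to-threshold distance `d_HT` decreases along
fading_fast → fading → arcuate → polycyclic → gyrate: the more benign
the pattern class, the more stable the healthy state is against
stimulation.

## What the synthetic data does and does not emulate

The stimulation fixtures emulate idealized in-silico protocols:
uniform resting skin, Gaussian micro-inflammation seeds (unit width
for the expanding experiments; width 4 for the circular fading
experiment, so that interior-first clearing is spatially resolvable),
linear and reticular stimulated regions, and transient well-mixed
pulses. They do not emulate real skin: no cellular chemotaxis, no
acquired immunity (so expanding patterns never arrest), no 3D dermal
structure, no heterogeneity in barrier properties, and no measurement
noise. Passing tests therefore demonstrate internal
consistency of the model-and-classifier pipeline under the stated
study conditions, not clinical validity.

## Problem sizes

Unit and property tests run on 32–64² grids with short horizons; the
classifier battery uses 96–128² synthetic masks. The acceptance script
runs each expanding-pattern preset at 96–128² for 60–200 time units
(the smallest sizes at which each morphology is fully developed;
larger grids and horizons give the same labels), the fading and
shrinkage checks at 96², and the regime transects by census only.

## Known limitations

- The morphology constants were tuned on this package's synthetic
  battery and presets; exotic parameter corners can land in *other*.
  Ambiguity falls back to *other* deliberately rather than forcing
  one of the five clinical classes.
- Pattern identity near regime boundaries depends on the lattice
  coupling (see above); labels at identical parameters but different
  `dx` can differ legitimately.
- The fast/slow fading split has no quantitative criterion in the
  clinical vocabulary; the package reports `d_HT` and disappearance
  time and leaves the threshold to the user.
- `find_steady_states` guarantees only roots inside the invariant box
  plus a margin; for pathological parameter sets with roots at extreme
  concentrations the scan resolution (4000 points) bounds detection.
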