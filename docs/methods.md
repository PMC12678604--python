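# Methods

This note documents the models implemented in `sprintergetics`, the
parameter values and why they were chosen, the numerical schemes, and the
limitations a user should keep in mind.

## Scope and assumptions

The package models a single maximal sprint effort (roughly 5–60 s) on a
flat, windless, straight track. The runner is treated as a point mass at
the centre of mass; wind, bends, drafting and lane effects are not
modelled. Reaction time (gun to movement onset) is subtracted before any
model evaluation, so the model clock starts at first movement; when the
true reaction time is unknown a default of 0.15 s is used, typical of
elite starters.

## Kinematics

Velocity during the acceleration phase follows the mono-exponential rise
`v(t) = v_f (1 − e^(−t/τ))`; acceleration is its analytic derivative.
Fitting assigns each split interval's average velocity to the interval's
time midpoint and minimizes squared residuals by damped (Levenberg–
Marquardt) least squares, starting from τ = 1.5 s and v_f = the highest
interval average. Two caveats follow from the midpoint assignment:

* An interval average of a convex velocity curve is not the midpoint
  value; for a first 10 m interval (≈1.8 s at elite pace) the mismatch
  biases τ upward by a few percent. The bias-free self-consistency test
  therefore synthesizes average velocities *at* the midpoints, while
  round trips through genuine split tables are checked at ~5%.
* Late-race deceleration contaminates the asymptote, so `v_f` is
  corrected upward (never downward) to the highest observed instantaneous
  or interval-average velocity, and for races longer than 200 m the fit
  can be restricted to the first 200 m (`max_distance`).

The full-race profile appends a linear deceleration from the end of the
acceleration phase — taken as the time midpoint of the fastest interval —
to a final velocity derived from the last interval's average velocity.
Distance is the trapezoidal integral on a uniform grid (default
dt = 0.01 s, where the pure-acceleration integral matches its closed form
to <0.01%).

## Energy cost and metabolic power

Accelerated running is mapped to constant-speed slope running via the
equivalent slope ES = a/g and equivalent mass EM = √(ES²+1). The default
cost variant multiplies the gradient-cost polynomial

    C(ES) = 155.4·ES⁵ − 30.4·ES⁴ − 43.3·ES³ + 46.3·ES² + 19.5·ES + 3.6

by EM. The polynomial was calibrated for |ES| ≤ 0.45; sprint starts reach
ES ≈ 1, so beyond `es_linear_limit` (default 0.45, configurable) the
polynomial is continued linearly with matched slope, keeping the cost C¹
and monotone. The published closed-form accelerated-running cost
(`minetti_pavei` variant) is available as an alternative; the two differ
by several percent at sprint-start accelerations, which propagates to
~10% differences in peak power over the first second.

Air resistance adds `0.01 v²` (J kg⁻¹ m⁻¹) to the per-metre cost. After
peak velocity the cost is pinned at the constant-speed flat-running value
3.8 J kg⁻¹ m⁻¹ — decelerating runners hold normal running posture, so the
accelerated-cost mapping no longer applies. Because C(0)·EM(0) = 3.6, the
switch produces a small upward power step at the phase boundary. This
discontinuity is genuine model structure: it is flagged on the series
(`t_discontinuity`) and never smoothed. Basal metabolism is *not* added to
kinematic power; all aerobic bookkeeping is above basal rate.

## Pathway model

Total power is the sum of three independent fixed-shape pulses (amplitudes
in W kg⁻¹, times in s):

| parameter | default | meaning |
|---|---|---|
| MAP | 24.5 (men) / 21.0 (women) | maximal aerobic power, from elite VO₂max ≈ 70/60 mL kg⁻¹ min⁻¹ × 20.9 J mL⁻¹ |
| BMR | 1.2 | basal rate (3.5 mL O₂ kg⁻¹ min⁻¹); subtracted, not modelled |
| k_aer | 23 | aerobic on-kinetics time constant |
| k1, k2 | 2.75, 35 | glycolytic activation / inhibition time constants |
| μ_al, σ_al | −0.4, 1.0 | log-normal alactic pulse: peak at e^μ ≈ 0.67 s |

The glycolytic pulse is peak-normalized: k_norm = 1/[(1 − e^(−t*/k1))
e^(−t*/k2)] at t* = k1 ln(1 + k2/k1), computed analytically and verified
against grid maximization, so `P_la,max` is the literal maximum of the
pulse (at t* ≈ 7.2 s for the defaults).

On the alactic constants: quoted shape pairs for this pulse circulate in
both orders, and the package uses μ_al = −0.4, σ_al = 1. This is the pair
under which the published amplitude–energy pairs for all six reference
performances are mutually consistent (e.g. 137.7 W kg⁻¹ ↔ 362 J kg⁻¹ over
9.43 s), and it places the alactic peak at ≈0.67 s — where ATP/PCr
splitting is fastest, at contraction onset — rather than at 2.7 s. The
transposed pair (μ = 1, σ = 0.4) cannot reproduce those pairs or the
observed early power peak.

With the shapes fixed, the model is linear in (P_al,max, P_la,max); the
"fit" to an observed power series is non-negative linear least squares of
the aerobic-corrected residual on the two unit pulses, with equal weights
on the uniform grid. Adjusted R² uses p = 2. Pathway energies are
trapezoidal integrals on the same grid; the alactic integrand takes its
limit value 0 at t = 0, and the mass missed on (0, dt) is below
P_al,max·dt.

## Duration-dependent capacities

Availability curves convert maximal stores into the energy a maximal race
of duration T can draw:

* alactic: E_al(T) = E_al,max · e^(−(ln T − 1.75)²/(2·1.5²)), never
  exceeding the capacity (equality at T = e^1.75 ≈ 5.75 s); the implied
  average alactic power E_al/T peaks at e^(1.75 − 1.5²) ≈ 0.61 s;
* lactic: zero for T ≤ 3 s (glycolysis needs the ADP/Pi rise of the first
  seconds), then a peak-normalized bi-exponential with 20 s rise and
  1500 s decay, maximal at T = 3 + 20 ln 76 ≈ 89.6 s.

Both are linear in the capacity, so fits to per-race energies use the
closed-form least-squares amplitude Σym/Σm². Effective durations are
finish time minus reaction time. Capacity estimates outside physiological
reference ranges (alactic 310–390 / 230–292 J kg⁻¹ men/women, lactic
940–1250 J kg⁻¹) produce warnings, never clamping.

Lactate equivalence: 1 mmol L⁻¹ accumulated blood lactate ↔ 3.0 (men) /
2.7 (women) mL O₂ per kg body mass ↔ 62.7 / 56.43 J kg⁻¹ (the women's
figure is the product of its two factors). Dividing the fitted male lactic
capacity by 62.7 gives ≈21 mmol L⁻¹, the expected elite ceiling.

## Inverse engine

Reconstruction steps through the target power series from rest. Each step
solves for the next velocity v₁ given the current v₀:

* accelerating branch: acceleration a = (v₁ − v₀)/dt, midpoint velocity
  (v₀ + v₁)/2; the model power at the interval midpoint is matched to the
  midpoint of the target series (Brent root-find on a ∈ (0, 12] m s⁻²).
  Midpoint matching keeps the finite-difference acceleration second-order;
  matching at the nodes instead would bias the decaying acceleration by
  O(dt) and lose ~0.2% of distance at dt = 0.01 s.
* flat (decelerating) branch: the node power (3.8 + 0.01 v₁²)v₁ has no
  acceleration term, so v₁ is the closed-form (Cardano) root of the node
  equation — exact, and immune to error accumulation.

The two branches' power ranges overlap on a narrow band (the 3.6 vs 3.8
J kg⁻¹ m⁻¹ gap times velocity), where pure power matching is ambiguous.
Kinematics-derived series carry the flagged phase boundary, which fixes
the regime exactly; for model-generated series the accelerating branch is
preferred and ties are broken by the target's local trend (non-increasing
power → decelerate). Steps whose target is unreachable within the
acceleration bracket or at rest are clipped to the nearest feasible
velocity and reported. Round trips through all six reference profiles
reproduce distance to <1e-4 % and velocity to <2e-4 m s⁻¹ RMSE.

Capacity optimization minimizes the sum of squared relative distance
errors over the supplied performances (two free parameters, MAP fixed),
with a Nelder–Mead simplex over the log-capacities from three
deterministic starts spread across the physiological range; the objective
uses dt = 0.02 s (the reconstruction error at that grid is orders below
the ~0.5% residual race-distance errors). Race-time simulation brackets by
geometric growth from distance/13 s and bisects the running duration to
0.005 s; the returned time adds the 0.15 s reaction.

## Synthetic split tables

The generator inverts the forward two-phase profile: acceleration per the
exponential model until velocity reaches `peak_fraction` (default 0.995)
of v_f, then a linear deceleration whose final velocity closes the
distance budget exactly; cumulative times at the marks are obtained by
root-finding on the closed-form distance. Specs that no profile can
satisfy (budget infeasible, or final velocity outside (0, v_peak]) are
rejected. Optional Gaussian noise perturbs interval average velocities
with a seeded generator, emulating timing scatter.

What the generator does *not* emulate: instantaneous-velocity measurement
(radar), wind and lane effects, stride-to-stride variability, reaction-time
variation, or timing quantization. Tests passing on these fixtures
therefore validate the pipeline's internal consistency and its behaviour
under idealized velocity noise, not robustness to every artefact of real
championship data.

## Degenerate inputs and tie-breaks

Non-monotone splits, fewer than three intervals, times before the reaction
time, non-positive durations and negative energies are rejected with
`ValueError`. A derived final velocity above the fitted peak velocity is
flagged (warning plus profile flag), not repaired. A zero-power series
reconstructs to rest. `adjust_peak_velocity` never lowers v_f. The
alactic pulse is defined as 0 at t = 0 by its limit.

## Limitations

* Women reuse the male-derived shape constants (μ = 1.75, σ = 1.5, 20 s,
  1500 s); the larger female simulation errors trace mainly to the lactic
  availability curve underestimating women's 400 m energy.
* The availability curves rest on three performances per sex plus
  theoretical anchors; beyond 400 m (durations ≳ 50 s) simulations are
  extrapolation and should be treated as such.
* The gradient-cost polynomial beyond |ES| = 0.45 is a slope-matched
  linear continuation, not a calibration; peak-power values in the first
  second inherit that uncertainty (the two cost variants differ by up to
  ~10% there).
* The three pathways are independent by construction; real metabolism
  couples them (ADP-mediated feedback), which a differential-equation
  model would capture but this package deliberately does not.
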