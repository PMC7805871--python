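# Methods

## Muscle-tendon model

Each virtual muscle is a lumped winding-filament unit with four elements:
a contractile element (CE) generating `Fce = act·fl(Xm)·P0`; a linear damper
`C_ce` in parallel with the CE approximating the force-velocity relation,
with separate lengthening (`Cce_l`) and shortening (`Cce_s`) coefficients; a
massless, frictionless pulley (the thin filaments) whose rotation winds the
titin spring `k_ts`; and a series spring `k_ss` (tendon, aponeurosis,
extracellular matrix) attached at the pulley axle. Force balances about the
pulley hold in rotation (`Fce + Cce·ẋce = kts·Xts`) and translation
(`Fce + Cce·ẋce + kts·Xts = kss·(Xm − Xp)`), and the CE velocity is the
superposition of the two balance solutions, which reduces algebraically to
`ẋce = (kss·(Xm − Xp) − 2·Fce)/Cce` — the titin terms cancel.

### Force-length relation

The published description of `fl` is a second-order polynomial with value 1
at the optimal length; its coefficients are not published. We use the
symmetric parabola `fl(Xm) = max(0, 1 − ((Xm − L0)/(w·L0))²)` with
half-width `w = 0.5` (zero active force at ±50% strain), which spans the
conventional filament-overlap range and is configurable per muscle
(`fl_width`). The optimal length of each virtual muscle is not tabulated
either; we define `L0` as the muscle-tendon length at the neutral ankle
angle, so that quiet stance sits on the force-length plateau. Both choices
are exposed in the configuration file.

### State closure

The printed equations determine the CE velocity but not the update laws for
the pulley position `Xp` and the titin strain `Xts` (those derivations are
in theses that are not available). The closure used here treats both as
dynamic states driven by the same damper:

    ẋp  = (Fss − Fce − Fts)/Cce        (translational balance rate)
    ẋts = (Fss − 2·Fts)/Cce            (= ẋp + winding rate (Fce − Fts)/Cce)
    Xts ← max(Xts, 0)

with `Fss = kss·(Xm − Xp)`, `Fts = kts·Xts`. The titin rate is the sum of
pulley translation (carrying the titin attachment with it) and winding (the
negative of the rotational-balance CE velocity: CE shortening winds titin
on, a force drop lets it unwind — deactivation unwinding therefore emerges
from the same equations with no extra rate constant). This closure

- satisfies all four balance equations at equilibrium, where `kts·Xts = Fce`
  and `Fss = 2·Fce`;
- is a genuine ODE in `(Xp, Xts)` — linear between damping switches, with a
  stable Jacobian (eigenvalues ≈ −3 s⁻¹ and −31 s⁻¹ for the posterior
  muscle while shortening) — so explicit Euler refinement converges at
  first order;
- preserves a decaying memory of active length changes in `Xts`, producing
  force enhancement after stretch and depression after shortening.

An alternative closure that solves the translational balance for `Xp`
quasi-statically at each step is degenerate when combined with the
superposition CE velocity (substituting one into the other forces
`kts·Xts ≡ Fce` identically) and was rejected.

The damping coefficient is selected by the sign of the CE velocity, judged
on the current-step superposition numerator `kss·(Xm − Xp) − 2·Fce` (which
has the same sign as the current `ẋce` and does not depend on the
coefficient being selected); ties select the lengthening coefficient.
Selecting on the previous step's velocity instead introduces a one-step
switching lag that leaves a spurious ~20 N offset after each square-wave
activation edge.

### Integration and its accuracy

State updates are explicit Euler at a fixed 500 Hz, matching the real-time
control rate of the target hardware; the rates are evaluated at the new
length/activation input and the previous internal state. A sub-stepped
oracle (`oracle_advance`) verifies the integrator: it divides each 2 ms
interval into `refinement` sub-steps, interpolating the length input
linearly and holding activation constant over the interval (activation is a
piecewise-constant per-sample command; interpolating it would misrepresent
the input). Halving the step size halves the max force deviation from the
refinement-100 oracle (measured ratio 2.03 over a level-walking stride —
textbook first-order behaviour).

The absolute deviation at 500 Hz is dominated by the stiff series-spring
mode `λ ≈ (kss + 2·kts)/Cce` (≈ 27–31 s⁻¹ for the posterior muscle while
shortening) excited by the square-wave activation edges and the fast
push-off shortening: over one default medium-speed stride it measures
≈ 1.4% of `P0` for the anterior muscle and ≈ 3.1% for the posterior
(`λ·dt/2` times the transient amplitude at `dt = 2 ms`). This is an honest
property of fixed-step Euler with these published constants; it is reported
as-is rather than smoothed away, and the activation-edge fluctuations it
reflects are a known artefact of square-wave muscle activation in this
controller family.

### History dependence

Residual force enhancement/depression is probed with ramp-hold protocols:
activate at a start length, settle 2 s, ramp at constant velocity to a
final length, hold, and measure the output force at a fixed offset (default
1 s) after the ramp ends, against a purely isometric contraction at the
same final length. In this model the effect decays during the hold (slow
eigenvalue ≈ −1.8 to −3 s⁻¹), so the measurement offset is part of the
metric definition. The standard test grid uses ramps of 2/5/10% of `L0`
that all end at `L0`, with a fixed 0.5 s ramp duration (velocity scales
with amplitude): with constant-velocity ramps the larger amplitudes take
longer and their early portion is partially forgotten before the
measurement, compressing the amplitude ordering the protocol is meant to
resolve.

## Ankle layer

The ankle is a hinge; angle `θ` is 0 with the foot perpendicular to the
shank, dorsiflexion positive, plantarflexion negative. Each muscle spans a
triangle with shank attachment length `SAL` and foot moment arm `FMA`; the
included angle is `γ_A = 90° − θ` (anterior) and `γ_P = 90° + θ`
(posterior), so plantarflexion stretches the anterior muscle and slackens
the posterior, and the two lengths always move oppositely. Lengths follow
the law of cosines; the moment arm is the virtual-work arm
`r = dL/dθ = SAL·FMA·sin γ / L` (equal to the perpendicular distance from
the joint to the muscle line, and ≈ FMA near γ = 90°); a constant-arm mode
(`constant_moment_arm`) is available for comparison. The net moment
`M = (Fss_P·r_P − Fss_A·r_A)/100` N·m is plantarflexion-positive; a slack
series spring transmits no force (negative series-spring values are clamped
to zero at the moment computation, leaving the state equations linear). An
optional viscous compensation term `resistance_gain·θ̇` (default 0) stands
in for hardware mechanical resistance, which is otherwise out of scope.

Stage-based activation uses the two tabulated subject presets: profile 1
activates the anterior muscle at 0.93/0.28/0.31 in stages 2/3/4 and the
posterior at 0.44 in stage 6 (profile 2: 0.63/0.48/0.51 and 0.69); stages
never activate both muscles at once. Square waves are the default; an
optional slew-rate limiter (`smoothing_s`) can spread each transition over
a configurable window.

## Synthetic gait

No subject recordings are published, so the generator emulates the
qualitative waveforms only. Cycles are shape-preserving piecewise cubics
(PCHIP) through named control points, tiled to make the interpolant C¹
across the heel-strike wrap; PCHIP does not overshoot, so a control point
placed at an extremum is the extremum. Defaults:

- Level walking, heel strike at 0%: early-stance dip (−3/−5/−6° at 8%),
  dorsiflexion peak (+8/+10/+11° at 48%), plantarflexion peak at 60%
  (−8/−13/−19° for the slow/medium/fast classes, spanning the published
  −8° to −19° range; stride times 1.40/1.15/0.95 s), gradual dorsiflexing
  swing return. The plantarflexion knot sits at the stance/swing boundary,
  where peak plantarflexion occurs at toe-off.
- Stair ascent (step-over-step; one cycle of the instrumented leg spans two
  steps, so 80 steps/min gives a 1.5 s cycle): pull-up dorsiflexion +9° at
  10%, pull-up plantarflexion −5° at 24%, second dorsiflexion +12° at 50%,
  plantarflexion peak −17° at 70% (within the published −15° to −19° range,
  deeper and later than level walking), swing return.
- Transition bout: 2 level strides + 4 stair steps + 2 level strides under
  one configuration; every cycle starts and ends at the heel-strike angle,
  so joins are continuous.

Stage labels are assigned by cycle fraction (stance 60%, stages 4/5/6
splitting stance at 50% and 75%, stages 2/3 halving swing) — the exact
in-stance boundaries are not published and are configuration, not claimed
values. Stride-to-stride variability is seeded Gaussian jitter (SD 0.3° by
default) on the interior control-point angles; noise 0 gives strictly
periodic output. The generator does not emulate measurement noise,
timing jitter of the stage detector, kinematic soft-tissue artefacts, or
between-subject variability, so passing tests demonstrate the controller's
response to idealized kinematics, not performance on hardware data.

## Stride analytics

Strides are segmented at the 3→4 label transition (the heel-strike proxy —
the artifact has no ground contact to detect), resampled to 100 points per
cycle by linear interpolation (monotone, artefact-free around peaks), and
summarized by peak net moment (N·m/kg), peak stance plantarflexion
(degrees) and peak power (W/kg; signed maximum, configurable in principle
to magnitude). Power is `P = (M/mass)·ω` with `ω = −θ̇` in rad/s so that
both factors are plantarflexion-positive: push-off generation is positive,
controlled-dorsiflexion absorption negative, and a fully passive run
dissipates (non-positive work per closed cycle). The SEM of a single stride
is reported as 0 with a flag rather than NaN. Dominant moment peaks are
counted with a height-and-prominence floor of 20% of the bout maximum,
which separates the functional pull-up/push-off peaks from the small
activation-switching ripples.

## Tuning and sensitivity

Fitting maximizes R² (`1 − SSE/SST` about the reference mean) of the
controller's net moment against a reference trace, over a user-chosen free
subset of the ten muscle constants, within finite bounds, using a
derivative-free bounded local search (Powell) — deterministic given the
start point, mirroring single-start local optimization practice;
activation levels are user preference, not fitted, by default. Because no
recorded torque ships with the package, test references are self-generated
with known parameters, making fitting a parameter-recovery exercise
(recovery from ±25% offsets is exact to ≤0.01%). The sensitivity scan
perturbs each of the ten constants and each nonzero stage activation one at
a time over 0.5%–250% of nominal (grid including the ±25% slice and the
1.0 self-comparison, which scores exactly 1); perturbations that violate a
domain (activation scaled above 1) are recorded as missing and the scan
continues.

## Problem sizes

Default test and acceptance workloads are desk-scale: bouts of 2–8 cycles
at 500 Hz (≈1 000–5 000 samples), 8 s isometric settles, a 126-simulation
sensitivity scan and a 3-parameter Powell fit; the full suite runs in well
under a minute on one core.

## Known limitations

- The pulley/titin closure is this package's own (the original derivation
  is unpublished); it is isolated behind `advance_state` so alternatives
  can be swapped in, and the behavioural test suite (equilibria, history
  dependence, convergence) pins what any replacement must satisfy.
- History dependence decays during the hold rather than persisting
  indefinitely; metrics are defined at a fixed post-ramp offset.
- The damper is always engaged, so fast passive stretches produce viscous
  forces that real relaxed muscle would not; swing-phase waveforms must be
  realistically gradual.
- Absolute moment magnitudes (~0.4–0.6 N·m/kg peak with profile 1 on
  synthetic kinematics) sit below typical recorded peaks (~1–1.5 N·m/kg):
  force development from a square-wave activation onset is rate-limited by
  the titin winding mode, and the synthetic waveforms are not tuned to any
  subject. Pattern-level properties (peak counts, timing, terrain
  adaptation) are the reproduction targets, not absolute torque.
- No ground-reaction forces, no metabolic cost, no state detection from
  torque/IMU (stage labels are an input), no biarticular knee coupling,
  no hardware friction model.
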