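# Methods

## Model

Frontal-plane stance is modeled as a linear inverted pendulum (LIPM): a
point mass at constant height `l` pivoting about the stance-foot ground
projection, with mediolateral dynamics `ẍ = ω²x`, `ω = √(g/l)`,
`g = 9.81 m/s²`. In the stance-foot frame the pivot-to-CoM direction is
negative, so during a normal transfer `x₀ < 0` and the approach velocity
`ẋ₀ > 0`. Setting `ẋ(t) = 0` on the passive solution gives the stationary
time `ωt* = artanh(u)` with `u = ẋ₀/(ω|x₀|)`, defined for `0 ≤ u < 1`;
`u ≥ 1` means the pendulum would fall laterally over the pivot and no
minimum distance exists, and `ẋ₀ < 0` means the CoM is already receding,
in which case the projected minimum is the current position. Substituting
`t*` back yields the projected transfer magnitude, algebraically equal to
the orbital-energy closed form `−√(x₀² − (ẋ₀/ω)²)` (the quantity
`ẋ² − ω²x²` is conserved along passive trajectories). The magnitude
splits exactly into `x₀·cosh(ωt*)` (foot-placement-related, coefficient
≥ 1) and `ẋ₀·sinh(ωt*)/ω` (velocity-related, coefficient in seconds).

The inverse-tangent notation sometimes seen for the stationary-time
solution is implemented as the inverse *hyperbolic* tangent: only artanh
satisfies the derivation (`tanh(ωt*) = u`) and has the domain `(−1, 1)`
that matches the validity condition. An RK4 integration of `ẍ = ω²x` is
kept in the test suite as an independent oracle for both the trajectory
and the projected minimum.

`ω` is evaluated from the instantaneous CoM height at the event instant.
In treadmill gait the CoM height varies by ~1% of body height during the
transfer phase, so this differs negligibly from a per-step constant; the
generator holds height exactly constant.

## Measurement pipeline

Filtering is a 4th-order Butterworth low-pass, applied zero-phase
(forward–backward) so event timing is not lag-shifted: 6 Hz for
kinematics, 15 Hz for kinetics, before any event detection or
differentiation. CoM velocity is the central-difference derivative of the
filtered position at the kinematic rate; values at event instants are
linearly interpolated; CoM velocity is linearly interpolated up to the
kinetic timeline for power computation.

Initial contact is an upward crossing of the per-belt vertical GRF
through a 20 N threshold holding for at least 50 ms; foot off is the
mirrored downward crossing; crossing times are interpolated between
samples. The threshold and debounce are conventions (configurable), not
measured constants. Transfer completion is the minimum of
|CoM − stance-foot| over the kinematic samples strictly inside the single
support window, refined by a parabolic fit through the discrete minimum;
a minimum sitting on the window edge flags the step `boundary_minimum`.
Steps are excluded for annotation overlap (handrail, toe drag — not
detectable from the provided channels), belt crossover (leading foot
landing across the belt midline at IC), non-alternating contacts, and
fall-over-pivot projections.

Trailing-limb power is the product of the trailing-belt mediolateral GRF
and the mediolateral CoM velocity, both mapped into the leading-stance
sign convention; work is the trapezoidal integral over the detected
double-support window with interpolated endpoints. The leading-limb
contribution is deliberately not modeled. Work is reported in joules,
not mass-normalized.

Per-participant outcomes use included steps only, no imputation:
asymmetries are non-paretic-side means minus paretic-side means (positive
= greater transfer toward the non-paretic side); contributions divide the
IC asymmetry and the double-support / early-single-support changes by the
final asymmetry (they telescope to 100% identically); prediction MAE is
the per-side mean |CFO projection − final magnitude|; the control
correlation is the per-side Pearson r between the IC projection and its
double-support change, computed per participant, never pooled;
variability is the per-side sample SD (n−1) of the IC projection and the
final magnitude. Group inference (mixed models, ANOVA, multiplicity
corrections) is out of scope by design: the pipeline emits the tidy
per-step and per-participant tables those fits consume.

## Synthetic data generator

The generator emulates hemiparetic treadmill walking with exact ground
truth. Per step it draws a foot placement and an IC velocity from
side-specific normal distributions, places the leading foot, and evolves
the CoM analytically: passive LIPM about the leading pivot, with a
half-sine trailing-limb force per unit mass occupying the later 80% of
double support (push-off peaks late in double support; the force is zero
at both ends of its support, which also keeps the work integrand
insensitive to the few-millisecond uncertainty of threshold-based event
detection). Because the forced oscillator has a closed-form solution and
the work–energy identity `W/m = Δ[½(ẋ² − ω²x²)]` holds exactly along it,
the half-sine amplitude that injects a prescribed work target is a root
of a quadratic; there is no numerical integration anywhere, and the
logged ground truth (event times, states, projections, work) is exact to
floating point.

Key design choices:

- **Event scheduling.** Instead of forcing a fixed step period (which
  would require a velocity discontinuity at IC), each next IC occurs when
  the passive fall-away velocity reaches the next drawn IC velocity, so
  the CoM trajectory is C¹ across steps. `step_period` (0.65 s) enters
  only through the double-support duration (`ds_fraction` = 0.38 of it,
  i.e. ~0.25 s — slow hemiparetic gait). The acceleration is still
  discontinuous at IC (the pivot switches feet); the zero-phase kinematic
  filter turns that corner into a ~2–4 mm error in the IC-instant
  projection, decaying before CFO. This is the pipeline's dominant
  measurement error and the reason double support was given a realistic,
  generous duration.
- **Defaults as study conditions.** Paretic steps: foot placement
  0.12 ± 0.015 m (wider, more variable) and trailing work 1.65 J;
  non-paretic: 0.10 ± 0.010 m and 1.8 J; IC velocity 0.15 ± 0.02 m/s both
  sides; body mass 75 kg, CoM height 0.95 m; 100 Hz kinematics / 1000 Hz
  kinetics. The work targets were solved so the early-single-support
  durations land at the hemiparetic scale (~0.1 s paretic, ~0.25 s
  non-paretic) with the paretic-step work deficit preserved. A
  `compensation_gain` mode replaces fixed targets with a controller that
  steers each step's CFO projection toward a set point — the construction
  used for step-to-step control and variability studies.
- **Feasibility guards.** Draws are redrawn (then deterministically
  adjusted) so every step's projected magnitude stays ≥ 5 cm at IC and
  ≥ ~5 cm after the work input: steps closer to the pivot approach a
  lateral fall, where the projection is ill-conditioned and real walkers
  do not operate. A zero-work (ballistic) scenario, `passive_config`,
  uses a faster approach velocity and shorter double support because a
  passive double support of realistic duration is dynamically impossible
  at the default geometry (the CoM would turn around mid-double-support).
- **Lateral stabilization.** A weak foot-placement centering gain (0.15
  on the stride's foot-midpoint offset) prevents the lab-frame drift that
  otherwise accumulates from left/right asymmetry; all transfer metrics
  are frame-relative and unaffected by it beyond a small (<1 cm) shift of
  the effective placement means.
- **Vertical forces** are complementary linear load-transfer ramps over
  double support summing to body weight — sufficient for threshold event
  detection, not claimed physiological. Swing-foot trajectories are
  smoothstep interpolations with a small clearance bump.
- **Measurement noise.** Kinematic channels carry 1 mm of noise modeled
  as 55% soft-tissue artifact — quasi-periodic at the step frequency with
  amplitude/phase drifting over ~1 s — plus 45% white sensor noise;
  kinetic channels carry 1 N white noise. The artifact share matters:
  white noise at the sampling rate is almost entirely removed by the
  prescribed 6 Hz zero-phase filter and its slow residual shifts the CFO
  projection and the final magnitude together, which would make the
  prediction error an order of magnitude smaller than real marker-based
  systems show. Movement-frequency artifact passes the filter and
  decorrelates across the 0.1–0.3 s prediction horizon, reproducing the
  millimeter-scale MAE of optical motion capture.

What passing tests show — and don't. The generator realizes the analysis
model exactly (passive single support, pivot at the foot CoM, constant
height), so end-to-end agreement demonstrates the correctness of the
measurement chain, not the validity of the LIPM for real bodies. Real
gait adds angular-momentum fluctuations, height changes, moving centers
of pressure and ankle strategies that the model deliberately omits; on
real data the CFO-prediction error therefore bounds model-plus-noise
error, whereas here it reflects noise alone.

## Numerical notes

- Filtering uses `scipy.signal.sosfiltfilt`; the effective magnitude
  response is the squared design response; the design order (4) is what
  is quoted.
- The completion search requires at least 3 kinematic samples inside the
  single-support window, else the step is `incomplete`; the parabolic
  refinement shift is clamped to ±1 sample.
- Double-support work integration requires ≥ 3 kinetic samples; the
  window endpoints are linearly interpolated so the trapezoid covers
  exactly [IC, CFO].
- `v₀ = 0` is treated as a valid projection with `t* = 0` (the state is
  already at its minimum); `u = 1` exactly is classified fall-over-pivot
  (asymptotic approach, no finite minimum).
- Sample-rate checks require uniform spacing to 1 ppm and an integer
  kinetic/kinematic rate ratio.
- Analyses that are means/SDs require ≥ 3 included steps per side, the
  correlation and regression ≥ 5; fewer raises an insufficient-data
  error rather than returning unstable estimates.

## Problem sizes

Unit and acceptance runs use 30-step trials (~17 s of simulated walking)
and 12-participant cohorts; the asymmetry-recovery check repeats the full
cohort pipeline across 50 generator seeds. These sizes put standard
errors well below the prescribed effect sizes (2 cm placement offset,
30% work deficit) while keeping the whole suite in tens of seconds.
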