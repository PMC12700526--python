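# Methods

`moveholdlab` analyses planar robotic-manipulandum experiments that ask
whether the involuntary resting force biases of an impaired arm intrude on
active reaching, or only on holding still. This note documents the models,
the estimators, the synthetic world used to validate them, and the
numerical choices — in enough detail to judge what a passing test does and
does not establish.

## Conventions

Workspace positions are in cm (+x rightward, +y away from the body),
forces in N as exerted by the participant on the robot handle, angles in
degrees in (−180, 180] with 0 at "3 o'clock" and counter-clockwise (CCW)
positive. Handle position and force are sampled at 200 Hz. Left-arm data
are mirrored about the y-axis (`flip_left_to_right`) before cohort
aggregation so that all arms share a common frame; the operation is an
involution (a tagged mirrored trial flips back).

## Resting-bias estimation (passive-hold trials)

A trial's resting bias is the mean handle force over a window 2–5 s after
hold onset. The first 2 s are discarded because passive transport of the
arm can transiently elevate muscle tone (a spasticity-like,
velocity-dependent effect) that dissipates early in the hold; the
synthetic generator models it as an exponential transient with a 0.7 s
time constant, and the estimator's residual from such a transient has the
closed form `a·τ·(e^{−2/τ} − e^{−5/τ})/3`, which the tests verify.

Rejection of unstable trials is automated (trace inspection by a human rater is
the traditional approach): a trial is flagged when the hand drifts > 1 cm
during the hold or the within-window force SD exceeds 3× the sensor-noise
scale. Both analysis modes (with and without rejection) are exposed
because robustness to this choice is part of the analysis contract.

Per-position biases are visit means; forces at the five canonical targets
are taken directly from a measured position within 0.5 cm (robot
repeatability scale) or else by component-wise piecewise-linear
interpolation on a Delaunay triangulation — exact on linear fields, no
overshoot. Targets outside the measured hull fall back to the nearest
measurement and are tagged `extrapolated`.

**Potential ("isocline") maps.** A scalar field φ is fitted on a regular
grid by minimising `Σ‖∇φ + F‖² + λ‖Δφ‖²` (centered differences, one-sided
at edges; Tikhonov weight λ = 1e−3), with the gauge fixed so φ = 0 at the
center target. Forces point downhill; bias vectors cross the level sets
perpendicularly. The residual is reported because a sampled field need not
be conservative: on a pure-curl field the minimal-norm φ is flat and the
residual equals the field RMS, which is a test.

**Measurement-variance decomposition.** The fraction of bias-magnitude
variance attributable to repeated measurement is the within-position sum
of squares over the total sum of squares, across all visits, positions,
conditions and subjects. The construction is one defensible reading of a
"variance attributed to repeated measurements" decomposition; it is exact
on the synthetic generator, where visit-to-visit variability is an
explicit parameter.

## Kinematic events and outcomes (reach trials)

Velocity is estimated by central finite differences with one-sided
endpoints, then a 25 ms moving average. The differentiation scheme is not
part of the analysis contract; the default window suppresses 200 Hz
differentiation noise while moving 3.5 cm/s threshold crossings by at most
one sample on minimum-jerk traces (verified by test). All thresholds are
exposed parameters.

* onset: first sample with speed > 3.5 cm/s;
* end: first later sample within the target (radius 0.5 cm, from the
  10 mm target diameter) at speed < 3.5 cm/s;
* θ_start / θ_end: signed angle (CCW+) between the start→target direction
  and the 150 ms chord starting at onset / at the first crossing within
  2 cm of the target;
* outlier rule: |θ_start| ≥ 90°;
* pulse settling: time from pulse onset until |lateral velocity| < 2 cm/s
  persists ≥ 100 ms, or the movement ends first (censored); maximum
  lateral deviation is measured relative to the straight start→target
  line, signed along the pulse direction (a trajectory-relative mode is a
  switch);
* release stabilization: time from force release until speed < 2 cm/s
  persists ≥ 100 ms with the hand within 2 cm of the target; a 2 s
  recording cap applies, with `exclude` / `impute_2s` / `uncapped`
  handling of capped trials.

Persistence windows are closed intervals: 100 ms at 200 Hz means 21
consecutive samples; a dip that lasts to the end of the considered span
qualifies. Trials whose movement end is undetectable still contribute
their angles (onset-only outcomes), which matters in the always-on
counterfactual where a strong bias can hold the hand off-target beyond
the recorded window.

## Interaction statistics

Resting biases join the outcome table by projection onto each trial's
geometry: lateral components are dot products with the unit vector 90° CCW
of the movement direction; release components are projections on the
displacement direction (opposite the removed force), so that positive
means aligned with the perturbing displacement. The *resistive* component
is its negation; sensitivity regressions for release outcomes use the
resistive component so that negative slopes mean better performance with a
more resistive bias, the sign convention used throughout the holding analyses.

Three estimators probe the bias–outcome association:

* **extreme-instance contrasts** — per subject, the two direction (or
  position × release-direction) instances with the strongest opposing
  projected biases; outcome means compared by paired t-test. Ties are
  broken lexicographically and logged.
* **per-subject sensitivities** — OLS slope over all trials, one-sample
  t-test of slopes against zero. Trial-level regression is the default; a
  direction-mean mode exists for robustness checks.
* **Response Asymmetry Index** — `RAI = (r_A − r_O)/(r_A + r_O)` with
  `r_A`/`r_O` the mean responses of the most-aligned/most-opposed
  instances; computed for maximum deviation and settling/stabilization
  time, for both the holding-release and the moving-pulse contexts, and
  compared between contexts by paired t-test.

Circular means use the resultant vector; the angular SEM is the circular
standard deviation `sqrt(−2 ln R̄)` over `sqrt(n)`. The mean is undefined
(an error) at zero resultant length.

The resting-magnitude ANOVA enters per-subject magnitudes (2 support × 2
proximity cells) into a model with sum-coded within-subject factors
Support and Proximity, a centered continuous FM-UE covariate, all two-way
interactions, and a random intercept per subject (fitted with a linear
mixed model). Effect sizes are classical η² = SS_effect/SS_total from the
fixed-effects Type-II partition (partial η² is also reported); p-values
are mixed-model Wald tests. Classical η² is the default because a shared
denominator makes effect sizes comparable across factors.

Two-sided p-values throughout; no multiple-testing correction by default
(`holm_adjust` is provided for a corrected reading of a test family but is
never applied automatically).

## The synthetic world

The generator exists so every stage can be validated against ground
truth. It emulates the two-experiment protocol: passive-hold mapping
(15–25 positions × 3 visits × 4 blocks: both arms × with/without air-sled
support) and reaching blocks of 96 ten-cm movements over a five-target
array (8 directions, 12 each; 64 unperturbed movements of which 20 carry
the extended-hold release perturbation, one per position × direction pair;
16 CCW + 16 CW pulse trials).

**Bias field.** A convergent attractor: magnitude
`(base_gain + distance_gain·d)` pointing from the hand toward a near-body
convergence point at distance `d`, scaled by `support_scale` (default 0.5)
under air-sled support, and by an impairment scale in [0, 1] that maps to
a nominal FM-UE score via `fm = 66 − 52·impairment`. Defaults
(`base_gain` 1 N, `distance_gain` 0.35 N/cm, convergence point near
(0, 5) cm with a 3 cm per-subject SD) reproduce the observed phenomena:
distal magnitudes near 6.5 N vs proximal 3.5–4 N without support, roughly
halved with support, directions near −90° with several degrees of
between-subject spread. A per-trial bias jitter (SD 0.5 N) models
visit-to-visit physiological variability; without it the repeated-
measurement variance fraction would be unrealistically near zero. The
functional form is the simplest that reproduces these facts and is not
claimed to be any patient's true field.

**Arm and controller.** A planar point mass (2 kg) driven by a PD servo
tracking a minimum-jerk reference (duration 0.65 s → 1.25 s with
impairment), with white motor-force noise at the 1 kHz integration rate.
Impairment lowers stiffness (kp 4 → 1.5 N/cm), lowers the damping ratio
(0.9 → 0.5, giving the overshoot and slow stabilization seen in impaired
responses) and raises motor noise. While holding (after movement end) a
slow integral term (ki = 0.5 N/(cm·s)) compensates sustained loads — the
6 N preload and the resting bias — only partially over the several-second
preload, so participants settle close to, not exactly on, the target;
after the abrupt release the uncompensated bias residual and the
unwinding compensation shape the response. This term is what lets the
release metrics depend on the resting bias at all: with a pure PD hold,
the post-release transient amplitude is `|F_imposed|/kp` regardless of
the bias, contrary to the observed interaction.

**Gating.** The resting bias enters the reach dynamics through a gate:
`hold_only` (0 during movement, `1 − e^{−Δt/0.3 s}` after movement end) is
the hypothesis under test; `always_on` is the counterfactual in which
posture intrudes on movement; `off` is a clean-dynamics control. The
simulator detects "movement over" online with the same predicate as the
end detector (inside the target below 3.5 cm/s after the reference ends),
plus fallbacks (below threshold 1.5 s after the reference, or 3 s
unconditionally) so gating always engages even when a strong always-on
bias holds the hand off-target.

**Perturbations.** The pulse is a raised-cosine ("bell-shaped" made
concrete): 12 N peak, 70 ms support, applied laterally once the hand is
2 cm from the start; its integral is `12·0.07/2 = 0.42 N·s` and the
simulated momentum transfer matches it to under 1%. The release
perturbation ramps a 6 N force linearly over 2 s in one of four diagonal
directions, holds it for U(3, 5) s, then steps to zero; recording
continues 3 s after release, and the analysis-level 2 s cap mirrors the
recording truncation such setups can impose.

**Integration and determinism.** Fixed-step RK4 at 1 kHz (no fastmath),
downsampled to 200 Hz. Every trial draws its noise from a seed sequence
keyed by (cohort seed, subject, experiment, block, trial), so cohorts are
bit-reproducible and independent of how trials are batched — a test
resimulates a cohort trial standalone and compares arrays exactly.

**What the generator does not model.** No muscle/joint-space dynamics, no
EMG, no gravity or 3D support biomechanics, no visual feedback loops, no
learning or fatigue across blocks, no trial-to-trial carryover of the
hold state. A green discrimination test therefore establishes that the
*pipeline* separates gated from ungated worlds of this kind — not that
the linear point-mass model is a faithful patient model. Two known
quantitative gaps: post-release paths are shorter and smoother than real
responses, and the path-to-stabilization sensitivity, though consistently
negative, is heterogeneous across impairment levels and only marginally
significant at n = 16 — a caveat the decision ledger of this
repository's development notes in detail.

## Numerical choices

* Sample-index conventions: events bind to the first sample at or after
  their time; tolerances of 1e−12 guard float comparisons at sample
  boundaries.
* The potential fit solves the stacked sparse least-squares system with
  LSQR; the constant nullspace is resolved by the minimal-norm solution
  and then re-gauged at the center target. Residual is invariant to the
  gauge.
* Zero-variance guards: paired contrasts on identical samples return
  t = 0, p = 1; exactly tied nonzero differences raise (infinite t);
  subjects with constant projected bias are dropped from sensitivity
  estimation with a warning.
* Degenerate selections (all projected components equal — e.g. a zero
  bias map) raise rather than returning an arbitrary pair; the pipeline
  skips such subjects with a warning.

## Scope notes

Clinical scores enter only as per-subject covariate numbers; EMG,
physiology and descending-pathway modelling are out of scope. Converting a public deposit's native layout is a
best-effort concern, not a core API guarantee; the canonical on-disk format is a JSON manifest
plus one `t,x,y,fx,fy` CSV per trial.
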