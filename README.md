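# moveholdlab

Analysis pipeline for planar robotic-manipulandum experiments that separate
the control of **moving** from the control of **holding still** in the
impaired (e.g. post-stroke, hemiparetic) arm — plus a fully parameterised
synthetic cohort generator so that every stage of the analysis can be
validated against ground truth without any data download.

It is written for motor-control and neurorehabilitation researchers working
with planar robot data (hand position and handle force at 200 Hz) from
two-part protocols:

1. **Resting-bias mapping** — the robot passively carries the relaxed hand
   between workspace positions and holds it still while the force sensor
   records the involuntary *resting postural force bias* at each location;
2. **Reaching and holding** — blocks of 10 cm point-to-point reaches over a
   five-target array, a third of them perturbed mid-movement by a 70 ms,
   12 N bell-shaped lateral force pulse, and 20 per block ending in an
   extended hold during which a 6 N force is ramped on, held 3–5 s, and
   abruptly released.

## The analysis

Per trial, the resting bias is the mean handle force over the 2–5 s hold
window (the first 2 s are discarded to let approach-related tone
dissipate), averaged over visits, and interpolated to the five reach
targets. Bias **fields** can be summarised as isocline maps: the scalar
potential φ minimising ‖∇φ + F‖² + λ‖Δφ‖², whose level sets bias vectors
cross perpendicularly.

Kinematic events use velocity-threshold rules (onset/end at 3.5 cm/s,
settling/stabilization at 2 cm/s with a 100 ms persistence requirement),
and the outcomes are initial/endpoint reach angles θ_start and θ_end
(150 ms chords), time and path to target, pulse settling time and maximum
lateral deviation, and release time/path to stabilization and maximum
deviation.

The interaction layer projects each trial's resting bias onto the
movement or perturbation geometry and asks whether it predicts the
outcome, three ways: extreme-instance paired contrasts (the most-CCW vs
most-CW, or most-aligned vs most-opposed, instances per subject),
per-subject sensitivity slopes tested against zero at the group level,
and the Response Asymmetry Index

    RAI = (r_A − r_O) / (r_A + r_O)

contrasting the response when the bias is aligned with the perturbation
(r_A) vs opposed to it (r_O), compared between holding-release and
moving-pulse perturbations. Resting-bias magnitudes also feed a
mixed-model ANOVA against impairment (FM-UE), target proximity and arm
support, reported as η² with mixed-model p-values.

The synthetic generator drives a planar point-mass arm (PD reach servo on
a minimum-jerk reference, slow integral load compensation while holding,
RK4 at 1 kHz) through a *gated* bias field: `hold_only` (the bias switches
on only after movement ends — the hypothesis the analysis is designed to
detect), `always_on` (the counterfactual), or `off`. See
`docs/methods.md` for the model, defaults and their rationale.

## Worked example

```sh
moveholdlab run --seed 1 --subjects 6 --blocks 1 --out mhl_out
```

simulates a six-patient cohort (impairments spanning FM-UE ≈ 20–53),
estimates the resting-bias maps, computes the kinematic outcomes, joins
them, and prints a report like:

```
[rest] bias magnitude (mean +/- SEM, N) by condition:
          paretic / airsled: distant 3.10+/-0.60  near 2.03+/-0.39  direction -86.9+/-2.8 deg
          paretic /    none: distant 6.34+/-1.16  near 4.06+/-0.80  direction -87.5+/-2.6 deg
  measurement variance fraction: 0.016
```

— resting biases point toward the body (≈ −90°), are stronger at distant
positions, and are roughly halved by arm support; only ~2% of their
variance is measurement noise. The interaction section then shows the
dissociation the pipeline is built to detect:

```
                   theta_start: -0.0118+/-0.1422 per N  (t=-0.08, df=5, p=0.937)
  release_time_to_stabilization: -0.0304+/-0.0167 per N  (t=-1.83, df=5, p=0.1274)
         release_max_deviation: -0.1008+/-0.0044 per N  (t=-23.04, df=5, p=2.867e-06)
```

Movement-phase outcomes (θ_start) are insensitive to the resting bias,
while holding-phase responses improve when the bias opposes the
perturbation (negative slopes against the resistive component; strongly
significant for maximum deviation even at n = 6) — the hold-gated world
the cohort was generated from. Simulating with `--gating always_on`
instead makes the θ_start sensitivity significantly positive.

The same stages are available programmatically
(`moveholdlab.pipeline.run_pipeline`, or `analyze_rest` / `analyze_move` /
`analyze_hold` on any `TrialSet`), and as separate CLI subcommands
(`simulate`, `analyze-rest`, `analyze-move`, `run`). Trial sets are stored
as a JSON manifest plus one `t,x,y,fx,fy` CSV per trial.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full pipeline end to end on a seeded synthetic cohort —
simulation, resting-bias estimation, kinematic outcomes, interaction
statistics — verifying that every stage product is produced, and writes
the result JSON to `--out`.
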