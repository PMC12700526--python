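"""End-to-end orchestration: simulate -> rest -> move -> hold -> report.

The stages mirror the experiment structure:

* ``rest``  — aggregate passive-hold trials into per-condition bias maps,
  summarize magnitudes/directions, decompose measurement variance, and run
  the FM-UE x Support x Proximity ANOVA on paretic-arm magnitudes;
* ``move``  — build the per-trial kinematic outcome table for reach trials;
* ``hold``  — join the Experiment-1 bias maps onto the Experiment-2
  outcomes (projected onto each trial's geometry) and run the interaction
  statistics: extreme-instance paired contrasts, per-subject sensitivity
  regressions, and Response Asymmetry Indices for holding vs. moving
  perturbations.

Everything here is plain-function plumbing over the analysis modules; the
command-line interface in :mod:`moveholdlab.cli` is a thin wrapper.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from . import interaction_stats as ist
from . import kinematics as kin
from . import resting_bias as rb
from .io import TrialSet, read_trialset
from .synthetic import (
    CohortConfig,
    SubjectSpec,
    GatingMode,
    simulate_cohort,
    target_array,
    DISTANT_TARGET_IDX,
    NEAR_TARGET_IDX,
)

logger = logging.getLogger(__name__)

MOVEMENT_OUTCOMES = ("theta_start", "theta_end")
PULSE_OUTCOMES = ("settling_time", "max_lateral_dev")
RELEASE_OUTCOMES = ("time_to_stabilization", "path_to_stabilization", "max_deviation")


# ---------------------------------------------------------------------------
# rest stage


def analyze_rest(
    ts: TrialSet,
    qc: bool = True,
    window: tuple = rb.DEFAULT_WINDOW,
    noise_scale: float = rb.DEFAULT_NOISE_SCALE_N,
) -> dict:
    """Bias maps, cohort summary, variance fraction and magnitude ANOVA."""
    rest = [tr for tr in ts if tr.meta.experiment == "rest"]
    if not rest:
        raise ValueError("no passive-hold trials in the trial set")
    grouped: Dict[Tuple[str, str, str], list] = {}
    fm_by_subject = {}
    group_by_subject = {}
    for tr in rest:
        key = (tr.meta.subject_id, tr.meta.arm, tr.meta.support)
        grouped.setdefault(key, []).append(tr)
        fm_by_subject[tr.meta.subject_id] = tr.meta.fm_ue
        group_by_subject[tr.meta.subject_id] = tr.meta.group
    maps = {
        key: rb.aggregate_bias_map(
            trials, window=window, noise_scale=noise_scale, qc=qc
        )
        for key, trials in grouped.items()
    }
    summary = rb.summarize_bias(list(maps.values()))
    try:
        var_fraction = rb.variance_decomposition(list(maps.values()))
    except ValueError:
        var_fraction = float("nan")

    anova_input = magnitude_by_proximity(maps, fm_by_subject, group_by_subject)
    anova = None
    patients = anova_input[anova_input["group"] == "patient"]
    if len(patients["subject_id"].unique()) >= 3 and patients["support"].nunique() == 2:
        try:
            anova = ist.rest_anova(patients)
        except Exception as err:  # pragma: no cover - diagnostic path
            logger.warning("rest ANOVA failed: %s", err)
    return {
        "maps": maps,
        "summary": summary,
        "per_subject": summary.attrs["per_subject"],
        "variance_fraction": var_fraction,
        "anova_input": anova_input,
        "anova": anova,
    }


def magnitude_by_proximity(
    maps: Mapping, fm_by_subject: Mapping, group_by_subject: Mapping
) -> pd.DataFrame:
    """Per subject x support x proximity mean canonical bias magnitude
    (paretic / primary arm only) — the ANOVA input table."""
    rows = []
    for (subject, arm, support), bm in maps.items():
        if arm not in ("paretic", "dominant-proxy"):
            continue
        mag = np.linalg.norm(bm.canonical_forces, axis=1)
        for prox, idx in (("distant", DISTANT_TARGET_IDX), ("near", NEAR_TARGET_IDX)):
            rows.append(
                {
                    "subject_id": subject,
                    "group": group_by_subject.get(subject, "patient"),
                    "support": support,
                    "proximity": prox,
                    "magnitude": float(np.mean(mag[list(idx)])),
                    "fm_ue": fm_by_subject.get(subject),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# move stage


def analyze_move(ts: TrialSet, cap_mode: str = "impute_2s",
                 drop_outliers: bool = True) -> pd.DataFrame:
    """Kinematic outcome table for every reach trial."""
    return kin.outcome_table(
        [tr for tr in ts if tr.meta.experiment == "reach"],
        cap_mode=cap_mode,
        drop_outliers=drop_outliers,
    )


# ---------------------------------------------------------------------------
# hold stage: joining biases onto outcomes


def _canonical_index(x: float, y: float, targets: np.ndarray, tol: float = 1.0) -> int:
    d = np.hypot(targets[:, 0] - x, targets[:, 1] - y)
    j = int(np.argmin(d))
    if d[j] > tol:
        raise ValueError(f"position ({x}, {y}) is not near any canonical target")
    return j


def attach_bias_projections(
    outcomes: pd.DataFrame,
    maps: Mapping,
    targets: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Join projected resting biases onto the per-trial outcome table.

    Adds, per trial: the lateral (CCW-positive) components of the resting
    bias at the start and target positions, the component along the pulse
    direction (aligned positive), and the release-frame components (aligned
    with the perturbing displacement, and its negation, the resistive
    component opposing it).
    """
    targets = target_array() if targets is None else targets
    df = outcomes.copy()
    cols = {
        "bias_start_lat": np.nan,
        "bias_end_lat": np.nan,
        "bias_pulse_aligned": np.nan,
        "bias_release_aligned": np.nan,
        "bias_release_resistive": np.nan,
    }
    for c in cols:
        df[c] = np.nan
    for i, row in df.iterrows():
        key = (row["subject_id"], row["arm"], row["support"])
        bm = maps.get(key)
        if bm is None or bm.canonical_forces is None:
            continue
        j_start = _canonical_index(row["start_x"], row["start_y"], targets)
        j_end = _canonical_index(row["target_x"], row["target_y"], targets)
        f_start = bm.canonical_forces[j_start]
        f_end = bm.canonical_forces[j_end]
        d = row["direction_deg"]
        lat_start = ist.project_bias(f_start, "reach_start", d)
        df.at[i, "bias_start_lat"] = lat_start
        df.at[i, "bias_end_lat"] = ist.project_bias(f_end, "reach_end", d)
        if row["trial_type"] == "reach_pulse":
            sign = 1.0 if row["pulse_sign"] == "CCW" else -1.0
            df.at[i, "bias_pulse_aligned"] = sign * lat_start
        if row["trial_type"] == "reach_hold_release":
            aligned = ist.project_bias(
                f_end, "release", float(row["release_direction_deg"])
            )
            df.at[i, "bias_release_aligned"] = aligned
            df.at[i, "bias_release_resistive"] = -aligned
    return df


def _extreme_contrast(df: pd.DataFrame, key_cols, component_col: str,
                      outcome_col: str, context: str) -> dict:
    """Per-subject extreme-instance selection + group paired t-test."""
    per_subject = []
    for subj, g in df.groupby("subject_id"):
        g = g[np.isfinite(g[component_col]) & np.isfinite(g[outcome_col])]
        if not len(g):
            continue
        comp, outs = {}, {}
        for k, v in g.groupby(key_cols):
            k = k if isinstance(k, tuple) else (k,)
            comp[k] = float(v[component_col].iloc[0])
            outs[k] = v[outcome_col].to_numpy()
        vals = np.array(list(comp.values()))
        if len(comp) < 2 or np.all(vals == vals[0]):
            logger.warning("subject %s: degenerate %s selection skipped", subj, context)
            continue
        pair = ist.select_extremes(comp, outs, context=context)
        per_subject.append(
            {
                "subject_id": subj,
                "component_hi": pair.component_values[0],
                "component_lo": pair.component_values[1],
                "outcome_hi": pair.outcome_means[0],
                "outcome_lo": pair.outcome_means[1],
            }
        )
    tbl = pd.DataFrame(per_subject)
    result = {"context": context, "outcome": outcome_col, "per_subject": tbl}
    if len(tbl) >= 2:
        try:
            md, t, dof, p = ist.paired_contrast(tbl["outcome_hi"], tbl["outcome_lo"])
            result.update(mean_diff=md, t=t, df=dof, p=p)
        except ValueError as err:
            result.update(error=str(err))
    return result


def analyze_hold(outcomes: pd.DataFrame, maps: Mapping) -> dict:
    """Interaction statistics between resting biases and movement/holding.

    Returns extreme-instance contrasts, per-subject sensitivities and the
    RAI comparison, on the paretic (or control-primary) arm.
    """
    df = attach_bias_projections(outcomes, maps)
    df = df[df["arm"].isin(["paretic", "dominant-proxy"])]

    unpert = df[df["trial_type"] == "reach_unperturbed"]
    pulse = df[df["trial_type"] == "reach_pulse"]
    release = df[df["trial_type"] == "reach_hold_release"]

    contrasts = {
        "reach_start": _extreme_contrast(
            unpert, ["direction_deg"], "bias_start_lat", "theta_start", "reach_start"
        ),
        "reach_end": _extreme_contrast(
            unpert, ["direction_deg"], "bias_end_lat", "theta_end", "reach_end"
        ),
    }
    for out in PULSE_OUTCOMES:
        contrasts[f"pulse_{out}"] = _extreme_contrast(
            pulse, ["direction_deg", "pulse_sign"], "bias_pulse_aligned", out, "pulse"
        )
    for out in RELEASE_OUTCOMES:
        contrasts[f"release_{out}"] = _extreme_contrast(
            release,
            ["target_x", "target_y", "release_direction_deg"],
            "bias_release_aligned",
            out,
            "release",
        )

    sensitivities = {}
    if len(unpert):
        sensitivities["theta_start"] = ist.sensitivity(unpert, "theta_start", "bias_start_lat")
        sensitivities["theta_end"] = ist.sensitivity(unpert, "theta_end", "bias_end_lat")
    for out in PULSE_OUTCOMES:
        if len(pulse):
            sensitivities[f"pulse_{out}"] = ist.sensitivity(pulse, out, "bias_pulse_aligned")
    for out in RELEASE_OUTCOMES:
        if len(release):
            sensitivities[f"release_{out}"] = ist.sensitivity(
                release, out, "bias_release_resistive"
            )

    rai = rai_analysis(df)
    return {"table": df, "contrasts": contrasts, "sensitivities": sensitivities,
            "rai": rai}


_RAI_METRICS = {
    # response metric comparable between the two perturbation types:
    # maximum deviation along the perturbation, and settling/stabilization time
    "max_dev": {"pulse": "max_lateral_dev", "hold": "max_deviation"},
    "settling": {"pulse": "settling_time", "hold": "time_to_stabilization"},
}


def rai_analysis(df: pd.DataFrame) -> dict:
    """Per-subject Response Asymmetry Indices for holding vs. pulse
    perturbations, and their paired comparison.

    For each subject and metric, ``r_A``/``r_O`` are the mean responses of
    the most-aligned / most-opposed instances (pulse: movement direction x
    pulse sign; hold: position x release direction)."""
    out = {}
    for metric, cols in _RAI_METRICS.items():
        rows = {}
        for kind, sub, keys, comp in (
            ("pulse", df[df["trial_type"] == "reach_pulse"],
             ["direction_deg", "pulse_sign"], "bias_pulse_aligned"),
            ("hold", df[df["trial_type"] == "reach_hold_release"],
             ["target_x", "target_y", "release_direction_deg"],
             "bias_release_aligned"),
        ):
            col = cols[kind]
            for subj, g in sub.groupby("subject_id"):
                g = g[np.isfinite(g[comp]) & np.isfinite(g[col])]
                if not len(g):
                    continue
                compv, outs = {}, {}
                for k, v in g.groupby(keys):
                    k = k if isinstance(k, tuple) else (k,)
                    compv[k] = float(v[comp].iloc[0])
                    outs[k] = v[col].to_numpy()
                vals = np.array(list(compv.values()))
                if len(compv) < 2 or np.all(vals == vals[0]):
                    continue
                pair = ist.select_extremes(compv, outs, context=kind)
                r_a, r_o = pair.outcome_means  # aligned = positive component
                try:
                    rai = ist.response_asymmetry_index(r_a, r_o).rai
                except ValueError:
                    logger.warning(
                        "subject %s: RAI undefined for %s/%s", subj, kind, metric
                    )
                    continue
                rows.setdefault(subj, {})[kind] = rai
        tbl = pd.DataFrame.from_dict(rows, orient="index").sort_index()
        res = {"per_subject": tbl}
        if {"hold", "pulse"} <= set(tbl.columns):
            both = tbl.dropna(subset=["hold", "pulse"])
            res["mean_hold"] = float(both["hold"].mean()) if len(both) else float("nan")
            res["mean_pulse"] = float(both["pulse"].mean()) if len(both) else float("nan")
            if len(both) >= 2:
                try:
                    md, t, dof, p = ist.paired_contrast(both["hold"], both["pulse"])
                    res.update(mean_diff=md, t=t, df=dof, p=p)
                except ValueError as err:
                    res["error"] = str(err)
        out[metric] = res
    return out


# ---------------------------------------------------------------------------
# run configuration / pipeline


@dataclass
class RunConfig:
    seed: int = 0
    stages: tuple = ("simulate", "rest", "move", "hold", "report")
    out_dir: str = "mhl_out"
    in_dir: Optional[str] = None
    qc_mode: str = "auto"             # auto | none
    cap_mode: str = "impute_2s"
    n_subjects: int = 4
    n_blocks: int = 1
    gating: str = "hold_only"
    arms: tuple = ("paretic",)
    thresholds: dict = field(default_factory=dict)

    def validate(self):
        known = {"simulate", "rest", "move", "hold", "report"}
        if not self.stages or not set(self.stages) <= known:
            raise ValueError(f"stages must be a nonempty subset of {sorted(known)}")
        if self.qc_mode not in {"auto", "none"}:
            raise ValueError("qc_mode must be auto or none")
        known_thr = {"speed_threshold", "settle_threshold", "smooth_window"}
        unknown = set(self.thresholds) - known_thr
        if unknown:
            raise ValueError(f"unknown threshold overrides: {sorted(unknown)}")


def default_cohort_config(cfg: RunConfig) -> CohortConfig:
    rng = np.random.default_rng(cfg.seed)
    subjects = []
    for i in range(cfg.n_subjects):
        imp = float(0.25 + 0.65 * i / max(cfg.n_subjects - 1, 1))
        subjects.append(
            SubjectSpec(
                subject_id=f"SYN{i:03d}",
                group="patient",
                impairment=imp,
                gating=GatingMode(mode=cfg.gating),
                side="left" if rng.random() < 0.7 else "right",
            )
        )
    return CohortConfig(subjects, arms=cfg.arms, n_exp2_blocks=cfg.n_blocks)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the requested stages; write CSV tables and a run log."""
    cfg.validate()
    os.makedirs(cfg.out_dir, exist_ok=True)
    log_lines = [f"seed={cfg.seed}", f"stages={','.join(cfg.stages)}",
                 f"qc_mode={cfg.qc_mode}", f"cap_mode={cfg.cap_mode}"]
    for k, v in sorted(cfg.thresholds.items()):
        log_lines.append(f"threshold_override:{k}={v}")

    bundle = {}
    if "simulate" in cfg.stages:
        ts, truth = simulate_cohort(default_cohort_config(cfg), seed=cfg.seed)
        bundle["trialset"] = ts
        bundle["ground_truth"] = truth
        log_lines.append(f"simulated_trials={len(ts)}")
    elif cfg.in_dir:
        bundle["trialset"] = read_trialset(cfg.in_dir)
        log_lines.append(f"loaded_trials={len(bundle['trialset'])}")
    else:
        raise ValueError("no input: request the simulate stage or set in_dir")
    ts = bundle["trialset"]

    if "rest" in cfg.stages:
        rest = analyze_rest(ts, qc=cfg.qc_mode == "auto")
        bundle["rest"] = rest
        rest["summary"].to_csv(os.path.join(cfg.out_dir, "rest_summary.csv"), index=False)
        rest["per_subject"].to_csv(
            os.path.join(cfg.out_dir, "rest_per_subject.csv"), index=False
        )
        if rest["anova"] is not None:
            rest["anova"].to_csv(os.path.join(cfg.out_dir, "rest_anova.csv"), index=False)
        log_lines.append(f"rest_variance_fraction={rest['variance_fraction']:.4f}")

    if "move" in cfg.stages:
        outcomes = kin.outcome_table(
            [tr for tr in ts if tr.meta.experiment == "reach"],
            cap_mode=cfg.cap_mode,
            smooth_window=cfg.thresholds.get("smooth_window", 0.025),
            speed_threshold=cfg.thresholds.get("speed_threshold", kin.SPEED_THRESHOLD),
            settle_threshold=cfg.thresholds.get("settle_threshold", kin.SETTLE_THRESHOLD),
        )
        bundle["outcomes"] = outcomes
        outcomes.to_csv(os.path.join(cfg.out_dir, "move_outcomes.csv"), index=False)
        log_lines.append(f"move_trials={len(outcomes)}")

    if "hold" in cfg.stages:
        if "rest" not in bundle and "rest" not in cfg.stages:
            raise ValueError("hold stage requires the rest stage's bias maps")
        if "outcomes" not in bundle:
            raise ValueError("hold stage requires the move stage's outcome table")
        hold = analyze_hold(bundle["outcomes"], bundle["rest"]["maps"])
        bundle["hold"] = hold
        hold["table"].to_csv(os.path.join(cfg.out_dir, "hold_table.csv"), index=False)
        sens_rows = [
            {
                "analysis": name,
                "mean_slope": r.mean,
                "sem": r.sem,
                "t": r.t,
                "df": r.df,
                "p": r.p,
            }
            for name, r in hold["sensitivities"].items()
        ]
        pd.DataFrame(sens_rows).to_csv(
            os.path.join(cfg.out_dir, "hold_sensitivities.csv"), index=False
        )
        for name, r in hold["sensitivities"].items():
            log_lines.append(f"sensitivity:{name}: mean={r.mean:.4g} t={r.t:.3f} p={r.p:.4g}")

    if "report" in cfg.stages:
        if not ({"rest", "move", "hold"} & set(cfg.stages)):
            raise ValueError("report stage requires at least one analysis stage product")
        report_path = os.path.join(cfg.out_dir, "report.txt")
        with open(report_path, "w") as fh:
            fh.write(render_report(bundle))
        log_lines.append("report=report.txt")

    with open(os.path.join(cfg.out_dir, "run_log.txt"), "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    bundle["log"] = log_lines
    return bundle


def render_report(bundle: dict) -> str:
    """Plain-text summary of the headline statistics."""
    lines = ["moveholdlab report", "=" * 40]
    rest = bundle.get("rest")
    if rest is not None:
        lines.append("\n[rest] bias magnitude (mean +/- SEM, N) by condition:")
        for _, r in rest["summary"].iterrows():
            lines.append(
                f"  {r['arm']:>15s} / {r['support']:>7s}: "
                f"distant {r['mag_distant_mean']:.2f}+/-{r['mag_distant_sem']:.2f}  "
                f"near {r['mag_near_mean']:.2f}+/-{r['mag_near_sem']:.2f}  "
                f"direction {r['direction_mean_deg']:.1f}+/-{r['direction_sem_deg']:.1f} deg"
            )
        lines.append(
            f"  measurement variance fraction: {rest['variance_fraction']:.3f}"
        )
        if rest["anova"] is not None:
            lines.append("  ANOVA on paretic magnitudes:")
            for _, r in rest["anova"].iterrows():
                lines.append(
                    f"    {r['effect']:>20s}: eta2={r['eta_sq']:.3f} p={r['p']:.2g}"
                )
    hold = bundle.get("hold")
    if hold is not None:
        lines.append("\n[hold] per-subject sensitivities (slope vs projected bias):")
        for name, r in hold["sensitivities"].items():
            lines.append(
                f"  {name:>28s}: {r.mean:+.4f}+/-{r.sem:.4f} per N  "
                f"(t={r.t:.2f}, df={r.df}, p={r.p:.4g})"
            )
        lines.append("\n[hold] Response Asymmetry Index (hold vs pulse):")
        for metric, r in hold["rai"].items():
            if "mean_hold" in r:
                extra = f" (paired t p={r['p']:.4g})" if "p" in r else ""
                lines.append(
                    f"  {metric:>10s}: hold {r['mean_hold']:+.3f} "
                    f"vs pulse {r['mean_pulse']:+.3f}{extra}"
                )
    return "\n".join(lines) + "\n"
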