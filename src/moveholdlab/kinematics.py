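"""Per-trial event detection and outcome metrics for reach trials.

Event rules (all thresholds exposed as parameters):

* movement onset — first time speed exceeds 3.5 cm/s;
* movement end — first later time the hand is within the target (radius
  0.5 cm, from the 10 mm target diameter) moving slower than 3.5 cm/s;
* initial reach angle ``theta_start`` — signed deviation (CCW positive) of
  the chord from onset to onset + 150 ms from the start-to-target direction;
* endpoint angle ``theta_end`` — same, for the chord starting where the
  hand first comes within 2 cm of the target;
* pulse settling — time from pulse onset until |lateral velocity| stays
  below 2 cm/s for at least 100 ms (or the movement ends first: censored);
* release stabilization — time from force release until speed stays below
  2 cm/s for at least 100 ms with the hand within 2 cm of the target;
* outlier rule — initial movement direction >= 90 deg away from the target
  direction.

Persistence windows are evaluated on closed intervals: 100 ms at 200 Hz is
21 consecutive samples (or every remaining sample when the window is cut
off by the end of the considered span).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .io import TrialRecord, estimate_velocity, signed_angle_deg, wrap_angle

SPEED_THRESHOLD = 3.5        # cm/s, onset and end detection
SETTLE_THRESHOLD = 2.0       # cm/s, pulse / release response
PERSISTENCE_S = 0.100        # s, how long the settle criterion must hold
ANGLE_CHORD_S = 0.150        # s, chord length for reach angles
TARGET_RADIUS = 0.5          # cm ("within the target", 10 mm diameter)
ENDPOINT_APPROACH_CM = 2.0   # cm, where the endpoint chord starts
STABILIZE_DIST_CM = 2.0      # cm, release stabilization distance criterion
OUTLIER_ANGLE_DEG = 90.0
RELEASE_RECORD_CAP_S = 2.0   # the recording cap applied to release trials


class EventDetectionError(RuntimeError):
    """A rule-based event could not be found in the trial."""


@dataclass
class ReachOutcomes:
    onset_t: float
    end_t: float
    time_to_target: float
    path_length: float
    theta_start: float
    theta_end: float
    outlier: bool


@dataclass
class PulseOutcomes:
    pulse_onset_t: float
    settling_time: float
    max_lateral_dev: float
    censored: bool


@dataclass
class ReleaseOutcomes:
    release_t: float
    time_to_stabilization: float
    path_to_stabilization: float
    max_deviation: float
    censored: bool


def _movement_direction(tr: TrialRecord) -> np.ndarray:
    span = np.asarray(tr.meta.target_pos, float) - np.asarray(tr.meta.start_pos, float)
    norm = np.linalg.norm(span)
    if norm == 0:
        raise EventDetectionError(f"trial {tr.meta.trial_id!r}: zero-length movement")
    return span / norm


def detect_onset(
    tr: TrialRecord,
    speed_threshold: float = SPEED_THRESHOLD,
    smooth_window: float = 0.025,
) -> float:
    """Movement onset: first sample with speed above ``speed_threshold``."""
    _, _, speed = estimate_velocity(tr, smooth_window)
    above = np.flatnonzero(speed > speed_threshold)
    if above.size == 0:
        raise EventDetectionError(
            f"trial {tr.meta.trial_id!r}: speed never exceeds {speed_threshold} cm/s"
        )
    return float(tr.t[above[0]])


def detect_end(
    tr: TrialRecord,
    onset_t: float,
    speed_threshold: float = SPEED_THRESHOLD,
    target_radius: float = TARGET_RADIUS,
    smooth_window: float = 0.025,
) -> float:
    """Movement end: within the target and slower than the threshold."""
    _, _, speed = estimate_velocity(tr, smooth_window)
    target = np.asarray(tr.meta.target_pos, float)
    dist = np.linalg.norm(tr.position() - target, axis=1)
    ok = (tr.t > onset_t) & (dist <= target_radius) & (speed < speed_threshold)
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        raise EventDetectionError(
            f"trial {tr.meta.trial_id!r}: never inside target below "
            f"{speed_threshold} cm/s"
        )
    return float(tr.t[idx[0]])


def _chord_angle(tr: TrialRecord, t0: float, direction: np.ndarray,
                 chord_s: float = ANGLE_CHORD_S) -> float:
    """Signed angle (deg, CCW+) of the chord [t0, t0 + chord_s] vs direction."""
    i0 = int(np.searchsorted(tr.t, t0 - 1e-12))
    t1 = t0 + chord_s
    if t1 > tr.t[-1] + 1e-12:
        raise EventDetectionError(
            f"trial {tr.meta.trial_id!r}: trial too short for a {chord_s*1e3:.0f} ms chord"
        )
    i1 = int(np.searchsorted(tr.t, t1 - 1e-12))
    chord = tr.position()[i1] - tr.position()[i0]
    if np.linalg.norm(chord) == 0:
        return 0.0
    return signed_angle_deg(direction, chord)


def reach_outcomes(
    tr: TrialRecord,
    speed_threshold: float = SPEED_THRESHOLD,
    target_radius: float = TARGET_RADIUS,
    smooth_window: float = 0.025,
) -> ReachOutcomes:
    """Reach metrics for any trial with a start-to-target movement."""
    direction = _movement_direction(tr)
    onset_t = detect_onset(tr, speed_threshold, smooth_window)
    theta_start = _chord_angle(tr, onset_t, direction)
    outlier = abs(theta_start) >= OUTLIER_ANGLE_DEG

    end_t = detect_end(tr, onset_t, speed_threshold, target_radius, smooth_window)
    pos = tr.position()
    target = np.asarray(tr.meta.target_pos, float)
    dist = np.linalg.norm(pos - target, axis=1)
    near = np.flatnonzero((tr.t >= onset_t) & (dist <= ENDPOINT_APPROACH_CM))
    if near.size == 0:
        raise EventDetectionError(
            f"trial {tr.meta.trial_id!r}: never within {ENDPOINT_APPROACH_CM} cm of target"
        )
    theta_end = _chord_angle(tr, float(tr.t[near[0]]), direction)

    seg = (tr.t >= onset_t) & (tr.t <= end_t)
    steps = np.diff(pos[seg], axis=0)
    path = float(np.sum(np.linalg.norm(steps, axis=1)))
    return ReachOutcomes(
        onset_t=onset_t,
        end_t=end_t,
        time_to_target=end_t - onset_t,
        path_length=path,
        theta_start=theta_start,
        theta_end=theta_end,
        outlier=bool(outlier),
    )


def lateral_signal(tr: TrialRecord, reference_direction_deg: float,
                   smooth_window: float = 0.025):
    """Position/velocity projected 90 deg CCW of ``reference_direction_deg``.

    Positive values are counter-clockwise of the movement direction; the
    position component is measured from the trial's start position (i.e.
    relative to the straight start-to-target line).
    """
    th = math.radians(reference_direction_deg)
    lat = np.array([-math.sin(th), math.cos(th)])
    start = np.asarray(tr.meta.start_pos, float)
    vx, vy, _ = estimate_velocity(tr, smooth_window)
    lat_pos = (tr.position() - start) @ lat
    lat_vel = np.column_stack([vx, vy]) @ lat
    return lat_pos, lat_vel


def _persistence_samples(t: np.ndarray, persistence_s: float) -> int:
    dt = float(np.median(np.diff(t)))
    return int(round(persistence_s / dt)) + 1


def _first_persistent_dip(below: np.ndarray, start_idx: int, stop_idx: int,
                          n_persist: int) -> Optional[int]:
    """First index >= start_idx where ``below`` holds for n_persist samples.

    The window is clipped at ``stop_idx`` (inclusive); a dip that lasts to
    the end of the considered span qualifies.
    """
    i = start_idx
    while i <= stop_idx:
        if below[i]:
            j_end = min(i + n_persist - 1, stop_idx)
            if np.all(below[i : j_end + 1]):
                return i
            i += 1
        else:
            i += 1
    return None


def unperturbed_lateral_profile(trials, n_bins: int = 25):
    """Mean lateral position vs forward progress over unperturbed reaches.

    Returns a callable ``f(progress_cm) -> lateral_cm`` usable as the
    ``baseline`` of :func:`pulse_outcomes` to measure pulse deviations
    relative to each direction's typical (rather than straight) trajectory.
    """
    prog_all, lat_all = [], []
    for tr in trials:
        direction = _movement_direction(tr)
        start = np.asarray(tr.meta.start_pos, float)
        rel = tr.position() - start
        prog_all.append(rel @ direction)
        lat_all.append(rel @ np.array([-direction[1], direction[0]]))
    prog = np.concatenate(prog_all)
    lat = np.concatenate(lat_all)
    edges = np.linspace(0.0, max(prog.max(), 1e-6), n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    means = np.full(n_bins, np.nan)
    for i in range(n_bins):
        m = (prog >= edges[i]) & (prog < edges[i + 1])
        if m.any():
            means[i] = lat[m].mean()
    ok = np.isfinite(means)
    if not ok.any():
        raise ValueError("no unperturbed samples to build a lateral profile")

    def f(progress):
        return np.interp(progress, centers[ok], means[ok])

    return f


def pulse_outcomes(
    tr: TrialRecord,
    settle_threshold: float = SETTLE_THRESHOLD,
    persistence_s: float = PERSISTENCE_S,
    smooth_window: float = 0.025,
    baseline=None,
) -> PulseOutcomes:
    """Settling time and lateral deviation after a mid-movement force pulse.

    Settling is the time from pulse onset until |lateral velocity| first
    stays below ``settle_threshold`` for ``persistence_s`` — or until the
    movement ends, whichever comes first (then censored).  The maximum
    lateral deviation is measured relative to the straight start-to-target
    line, signed along the pulse direction; pass a ``baseline`` from
    :func:`unperturbed_lateral_profile` to measure it relative to the mean
    unperturbed trajectory instead.
    """
    if "pulse_onset" not in tr.events:
        raise EventDetectionError(
            f"trial {tr.meta.trial_id!r}: no pulse_onset event recorded"
        )
    pulse_t = float(tr.events["pulse_onset"])
    direction = _movement_direction(tr)
    dir_deg = math.degrees(math.atan2(direction[1], direction[0]))
    lat_pos, lat_vel = lateral_signal(tr, dir_deg, smooth_window)

    onset_t = detect_onset(tr, smooth_window=smooth_window)
    try:
        end_t = detect_end(tr, onset_t, smooth_window=smooth_window)
    except EventDetectionError:
        end_t = float(tr.t[-1])

    i_pulse = int(np.searchsorted(tr.t, pulse_t - 1e-12))
    i_end = int(np.searchsorted(tr.t, end_t + 1e-12)) - 1
    i_end = max(i_end, i_pulse)
    below = np.abs(lat_vel) < settle_threshold
    n_persist = _persistence_samples(tr.t, persistence_s)
    hit = _first_persistent_dip(below, i_pulse, i_end, n_persist)
    if hit is None:
        settling = end_t - pulse_t
        censored = True
    else:
        settling = float(tr.t[hit]) - pulse_t
        # censored if the qualifying window was cut short by movement end
        censored = hit + n_persist - 1 > i_end
    sign = {"CCW": 1.0, "CW": -1.0}.get(tr.meta.pulse_sign)
    if sign is None:
        raise EventDetectionError(f"trial {tr.meta.trial_id!r}: no pulse sign")
    if baseline is not None:
        start = np.asarray(tr.meta.start_pos, float)
        progress = (tr.position() - start) @ direction
        lat_pos = lat_pos - baseline(progress)
    seg = slice(i_pulse, i_end + 1)
    max_dev = float(np.max(sign * lat_pos[seg]))
    return PulseOutcomes(
        pulse_onset_t=pulse_t,
        settling_time=float(settling),
        max_lateral_dev=max_dev,
        censored=bool(censored),
    )


def release_outcomes(
    tr: TrialRecord,
    cap_mode: str = "impute_2s",
    settle_threshold: float = SETTLE_THRESHOLD,
    persistence_s: float = PERSISTENCE_S,
    stabilize_dist: float = STABILIZE_DIST_CM,
    smooth_window: float = 0.025,
) -> ReleaseOutcomes:
    """Stabilization metrics after the abrupt release of a holding force.

    ``cap_mode`` controls trials that do not stabilize within the 2 s
    recording cap: ``exclude`` (NaN time), ``impute_2s`` (time set to 2.0 s)
    or ``uncapped`` (use the full recorded span).
    """
    if cap_mode not in {"exclude", "impute_2s", "uncapped"}:
        raise ValueError(f"unknown cap_mode {cap_mode!r}")
    if "release_onset" not in tr.events:
        raise EventDetectionError(
            f"trial {tr.meta.trial_id!r}: no release_onset event recorded"
        )
    if tr.meta.release_direction_deg is None:
        raise EventDetectionError(
            f"trial {tr.meta.trial_id!r}: no release direction in metadata"
        )
    release_t = float(tr.events["release_onset"])
    target = np.asarray(tr.meta.target_pos, float)
    # displacement direction: opposite the removed force
    th = math.radians(float(tr.meta.release_direction_deg) + 180.0)
    disp_dir = np.array([math.cos(th), math.sin(th)])

    _, _, speed = estimate_velocity(tr, smooth_window)
    dist = np.linalg.norm(tr.position() - target, axis=1)
    i_rel = int(np.searchsorted(tr.t, release_t - 1e-12))
    if cap_mode == "uncapped":
        window_end_t = float(tr.t[-1])
    else:
        window_end_t = min(release_t + RELEASE_RECORD_CAP_S, float(tr.t[-1]))
    i_stop = int(np.searchsorted(tr.t, window_end_t + 1e-12)) - 1

    n_persist = _persistence_samples(tr.t, persistence_s)
    # the speed criterion must persist; distance is evaluated at the moment
    speed_below = speed < settle_threshold
    hit = None
    i = i_rel
    while i <= i_stop:
        if speed_below[i] and dist[i] < stabilize_dist:
            j_end = min(i + n_persist - 1, i_stop)
            if np.all(speed_below[i : j_end + 1]):
                hit = i
                break
        i += 1

    if hit is not None:
        stab_t = float(tr.t[hit]) - release_t
        censored = False
        i_seg_end = hit
    else:
        censored = True
        i_seg_end = i_stop
        if cap_mode == "impute_2s":
            stab_t = RELEASE_RECORD_CAP_S
        elif cap_mode == "exclude":
            stab_t = float("nan")
        else:
            stab_t = float(tr.t[i_stop]) - release_t

    pos = tr.position()
    steps = np.diff(pos[i_rel : i_seg_end + 1], axis=0)
    path = float(np.sum(np.linalg.norm(steps, axis=1)))
    max_dev = float(np.max((pos[i_rel : i_stop + 1] - target) @ disp_dir))
    return ReleaseOutcomes(
        release_t=release_t,
        time_to_stabilization=stab_t,
        path_to_stabilization=path,
        max_deviation=max_dev,
        censored=bool(censored),
    )


# ---------------------------------------------------------------------------
# cohort-level outcome table


def movement_direction_deg(tr: TrialRecord) -> float:
    d = _movement_direction(tr)
    return float(wrap_angle(math.degrees(math.atan2(d[1], d[0]))))


def outcome_table(
    trials,
    cap_mode: str = "impute_2s",
    smooth_window: float = 0.025,
    drop_outliers: bool = True,
    speed_threshold: float = SPEED_THRESHOLD,
    settle_threshold: float = SETTLE_THRESHOLD,
) -> pd.DataFrame:
    """Per-trial outcome table for all reach trials in ``trials``.

    Trials whose onset/end events cannot be detected are flagged
    (``detect_failed``) and keep NaN outcomes; direction outliers are
    flagged and, with ``drop_outliers``, excluded like in the primary
    analysis mode.
    """
    rows = []
    for tr in trials:
        m = tr.meta
        if m.experiment != "reach":
            continue
        row = {
            "trial_id": m.trial_id,
            "subject_id": m.subject_id,
            "group": m.group,
            "arm": m.arm,
            "support": m.support,
            "block": m.block,
            "trial_type": m.trial_type,
            "direction_deg": movement_direction_deg(tr),
            "start_x": m.start_pos[0],
            "start_y": m.start_pos[1],
            "target_x": m.target_pos[0],
            "target_y": m.target_pos[1],
            "pulse_sign": m.pulse_sign,
            "release_direction_deg": m.release_direction_deg,
            "fm_ue": m.fm_ue,
            "outlier": False,
            "detect_failed": False,
            "end_detect_failed": False,
        }
        # angles only need an onset (plus the 2 cm crossing); end-dependent
        # metrics are filled separately so a trial that never meets the end
        # rule still contributes its directional outcomes
        direction = _movement_direction(tr)
        try:
            onset_t = detect_onset(tr, speed_threshold, smooth_window=smooth_window)
            row["onset_t"] = onset_t
            row["theta_start"] = th = _chord_angle(tr, onset_t, direction)
            row["outlier"] = bool(abs(th) >= OUTLIER_ANGLE_DEG)
        except EventDetectionError:
            row["detect_failed"] = True
            rows.append(row)
            continue
        target = np.asarray(tr.meta.target_pos, float)
        dist = np.linalg.norm(tr.position() - target, axis=1)
        near = np.flatnonzero((tr.t >= onset_t) & (dist <= ENDPOINT_APPROACH_CM))
        if near.size:
            try:
                row["theta_end"] = _chord_angle(tr, float(tr.t[near[0]]), direction)
            except EventDetectionError:
                pass
        try:
            end_t = detect_end(tr, onset_t, speed_threshold, smooth_window=smooth_window)
            seg = (tr.t >= onset_t) & (tr.t <= end_t)
            steps = np.diff(tr.position()[seg], axis=0)
            row.update(
                end_t=end_t,
                time_to_target=end_t - onset_t,
                path_length=float(np.sum(np.linalg.norm(steps, axis=1))),
            )
        except EventDetectionError:
            row["end_detect_failed"] = True
        if m.trial_type == "reach_pulse" and not row["detect_failed"]:
            po = pulse_outcomes(
                tr, settle_threshold=settle_threshold, smooth_window=smooth_window
            )
            row.update(
                pulse_onset_t=po.pulse_onset_t,
                settling_time=po.settling_time,
                max_lateral_dev=po.max_lateral_dev,
                pulse_censored=po.censored,
            )
        if m.trial_type == "reach_hold_release" and not row["detect_failed"]:
            rel = release_outcomes(
                tr,
                cap_mode=cap_mode,
                settle_threshold=settle_threshold,
                smooth_window=smooth_window,
            )
            row.update(
                release_t=rel.release_t,
                time_to_stabilization=rel.time_to_stabilization,
                path_to_stabilization=rel.path_to_stabilization,
                max_deviation=rel.max_deviation,
                release_censored=rel.censored,
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    if drop_outliers and len(df):
        df = df[~df["outlier"].astype(bool)].reset_index(drop=True)
    return df
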