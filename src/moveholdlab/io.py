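"""Canonical data model and file formats for planar-manipulandum trials.

Coordinate conventions used throughout the package:

* workspace positions in cm, ``+x`` rightward, ``+y`` away from the body;
* forces in N, measured as the force the participant exerts on the handle,
  same axes as position;
* angles in degrees in ``(-180, 180]``, 0 = the "3 o'clock" (+x) direction,
  counter-clockwise positive;
* time in seconds, nominal sampling rate 200 Hz.

A :class:`TrialRecord` couples one trial's metadata with its synchronized
time series; a :class:`TrialSet` is an ordered cohort of trials plus
provenance.  On disk a trial set is a JSON manifest plus one ``t,x,y,fx,fy``
CSV per trial, so fixtures stay inspectable and diff-able.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

FORMAT_VERSION = "1.0"
NOMINAL_DT = 1.0 / 200.0

GROUPS = {"patient", "control"}
ARMS = {"paretic", "nonparetic", "dominant-proxy"}
SIDES = {"left", "right"}
SUPPORTS = {"airsled", "none"}
EXPERIMENTS = {"rest", "reach"}
TRIAL_TYPES = {"passive_hold", "reach_unperturbed", "reach_pulse", "reach_hold_release"}
PULSE_SIGNS = {"CW", "CCW", "none"}
RELEASE_DIRECTIONS = {45.0, 135.0, 225.0, 315.0}

EVENT_NAMES = {
    "go",
    "hold_onset",
    "movement_onset",
    "movement_end",
    "pulse_onset",
    "release_onset",
}


class FormatError(ValueError):
    """Raised when an on-disk trial set is malformed."""


class TrialValidationError(ValueError):
    """Raised when a trial's metadata or samples violate the data model."""


def wrap_angle(deg):
    """Wrap an angle (degrees) into ``(-180, 180]``."""
    a = np.asarray(deg, dtype=float)
    wrapped = ((-a + 180.0) % 360.0)
    out = -(wrapped - 180.0)
    return out if out.ndim else float(out)


def signed_angle_deg(v_from, v_to) -> float:
    """Signed angle (degrees, CCW positive) rotating ``v_from`` onto ``v_to``."""
    ax, ay = float(v_from[0]), float(v_from[1])
    bx, by = float(v_to[0]), float(v_to[1])
    cross = ax * by - ay * bx
    dot = ax * bx + ay * by
    return math.degrees(math.atan2(cross, dot))


def unit_vector(angle_deg: float) -> np.ndarray:
    th = math.radians(angle_deg)
    return np.array([math.cos(th), math.sin(th)])


@dataclass(frozen=True)
class TrialMeta:
    subject_id: str
    group: str
    arm: str
    side: str
    support: str
    experiment: str
    trial_type: str
    block: int
    start_pos: tuple
    target_pos: tuple
    pulse_sign: str = "none"
    release_direction_deg: Optional[float] = None
    fm_ue: Optional[float] = None
    flags: frozenset = field(default_factory=frozenset)
    trial_id: str = ""

    def validate(self) -> None:
        def check(value, vocab, name):
            if value not in vocab:
                raise TrialValidationError(
                    f"trial {self.trial_id!r}: unknown {name} token {value!r}"
                )

        check(self.group, GROUPS, "group")
        check(self.arm, ARMS, "arm")
        check(self.side, SIDES, "side")
        check(self.support, SUPPORTS, "support")
        check(self.experiment, EXPERIMENTS, "experiment")
        check(self.trial_type, TRIAL_TYPES, "trial_type")
        check(self.pulse_sign, PULSE_SIGNS, "pulse_sign")
        if (self.pulse_sign != "none") != (self.trial_type == "reach_pulse"):
            raise TrialValidationError(
                f"trial {self.trial_id!r}: pulse_sign must be set iff trial_type is reach_pulse"
            )
        has_release = self.release_direction_deg is not None
        if has_release != (self.trial_type == "reach_hold_release"):
            raise TrialValidationError(
                f"trial {self.trial_id!r}: release_direction_deg must be set iff "
                "trial_type is reach_hold_release"
            )
        if has_release and float(self.release_direction_deg) not in RELEASE_DIRECTIONS:
            raise TrialValidationError(
                f"trial {self.trial_id!r}: release_direction_deg "
                f"{self.release_direction_deg!r} not in {sorted(RELEASE_DIRECTIONS)}"
            )
        if self.group == "patient" and self.fm_ue is None:
            raise TrialValidationError(
                f"trial {self.trial_id!r}: fm_ue required for patients"
            )
        if self.fm_ue is not None and not (0.0 <= float(self.fm_ue) <= 66.0):
            raise TrialValidationError(
                f"trial {self.trial_id!r}: fm_ue {self.fm_ue} outside 0-66"
            )


@dataclass
class TrialRecord:
    """One trial: metadata, 200 Hz samples, and optional named event times."""

    meta: TrialMeta
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fx: np.ndarray
    fy: np.ndarray
    events: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.fx = np.asarray(self.fx, dtype=float)
        self.fy = np.asarray(self.fy, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.t.size

    def position(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def force(self) -> np.ndarray:
        return np.column_stack([self.fx, self.fy])

    def validate(self) -> None:
        self.meta.validate()
        n = self.t.size
        for name in ("x", "y", "fx", "fy"):
            if getattr(self, name).size != n:
                raise TrialValidationError(
                    f"trial {self.meta.trial_id!r}: column {name} length mismatch"
                )
        if n and np.any(np.diff(self.t) <= 0):
            raise TrialValidationError(
                f"trial {self.meta.trial_id!r}: timestamps not strictly increasing"
            )
        if n:
            lo, hi = self.t[0], self.t[-1]
            for name, tv in self.events.items():
                if not (lo <= tv <= hi):
                    raise TrialValidationError(
                        f"trial {self.meta.trial_id!r}: event {name!r}={tv} outside "
                        f"[{lo}, {hi}]"
                    )


@dataclass
class TrialSet:
    trials: list
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def validate(self) -> None:
        for tr in self.trials:
            tr.validate()

    def filter(self, **criteria) -> "TrialSet":
        """Subset by meta fields, e.g. ``ts.filter(arm="paretic", support="none")``."""
        kept = [
            tr
            for tr in self.trials
            if all(getattr(tr.meta, k) == v for k, v in criteria.items())
        ]
        return TrialSet(kept, provenance=self.provenance)


# ---------------------------------------------------------------------------
# serialization

_META_FIELDS = (
    "subject_id",
    "group",
    "arm",
    "side",
    "support",
    "experiment",
    "trial_type",
    "block",
    "start_pos",
    "target_pos",
    "pulse_sign",
    "release_direction_deg",
    "fm_ue",
)


def _meta_to_json(meta: TrialMeta) -> dict:
    d = {k: getattr(meta, k) for k in _META_FIELDS}
    d["start_pos"] = list(map(float, meta.start_pos))
    d["target_pos"] = list(map(float, meta.target_pos))
    d["flags"] = sorted(meta.flags)
    return d


def _meta_from_json(d: Mapping, trial_id: str) -> TrialMeta:
    kwargs = {k: d.get(k) for k in _META_FIELDS}
    kwargs["start_pos"] = tuple(kwargs["start_pos"])
    kwargs["target_pos"] = tuple(kwargs["target_pos"])
    kwargs["flags"] = frozenset(d.get("flags", ()))
    kwargs["trial_id"] = trial_id
    return TrialMeta(**kwargs)


def write_trialset(ts: TrialSet, path: str) -> None:
    """Write a trial set as ``manifest.json`` plus one CSV per trial."""
    os.makedirs(path, exist_ok=True)
    entries = []
    for i, tr in enumerate(ts.trials):
        trial_id = tr.meta.trial_id or f"trial_{i:05d}"
        csv_name = f"{trial_id}.csv"
        arr = np.column_stack([tr.t, tr.x, tr.y, tr.fx, tr.fy])
        np.savetxt(
            os.path.join(path, csv_name),
            arr,
            delimiter=",",
            header="t,x,y,fx,fy",
            comments="",
            fmt="%.17g",
        )
        entries.append(
            {
                "trial_id": trial_id,
                "csv": csv_name,
                "meta": _meta_to_json(tr.meta),
                "events": {k: float(v) for k, v in tr.events.items()},
            }
        )
    manifest = {
        "format_version": FORMAT_VERSION,
        "provenance": ts.provenance,
        "trials": entries,
    }
    with open(os.path.join(path, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)


def read_trialset(path: str) -> TrialSet:
    """Read a trial set written by :func:`write_trialset`.

    Unknown CSV columns are ignored; metadata is validated against the
    trial vocabulary and time stamps are checked for monotonicity.
    """
    manifest_path = os.path.join(path, "manifest.json")
    if not os.path.exists(manifest_path):
        raise FormatError(f"no manifest.json under {path!r}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    if "trials" not in manifest:
        raise FormatError(f"manifest {manifest_path!r} lacks a 'trials' list")
    trials = []
    for entry in manifest["trials"]:
        trial_id = entry.get("trial_id", "?")
        csv_path = os.path.join(path, entry["csv"])
        if not os.path.exists(csv_path):
            raise FormatError(f"trial {trial_id!r}: missing file {csv_path!r}")
        df = pd.read_csv(csv_path)
        missing = {"t", "x", "y", "fx", "fy"} - set(df.columns)
        if missing:
            raise FormatError(f"trial {trial_id!r}: CSV lacks columns {sorted(missing)}")
        meta = _meta_from_json(entry["meta"], trial_id)
        tr = TrialRecord(
            meta=meta,
            t=df["t"].to_numpy(),
            x=df["x"].to_numpy(),
            y=df["y"].to_numpy(),
            fx=df["fx"].to_numpy(),
            fy=df["fy"].to_numpy(),
            events={k: float(v) for k, v in entry.get("events", {}).items()},
        )
        tr.validate()
        trials.append(tr)
    return TrialSet(trials, provenance=manifest.get("provenance", ""))


# ---------------------------------------------------------------------------
# velocity estimation

def estimate_velocity(tr: TrialRecord, smooth_window: float = 0.025):
    """Per-sample velocity ``(vx, vy, speed)`` in cm/s.

    Central finite differences of position over ``t`` (one-sided at the
    endpoints) followed by a moving-average over ``smooth_window`` seconds.
    The default 25 ms window suppresses 200 Hz differentiation noise without
    moving 3.5 cm/s threshold crossings by more than one sample on
    minimum-jerk traces.
    """
    if tr.n_samples < 3:
        raise TrialValidationError(
            f"trial {tr.meta.trial_id!r}: need >=3 samples to estimate velocity"
        )
    vx = np.gradient(tr.x, tr.t)
    vy = np.gradient(tr.y, tr.t)
    if smooth_window and smooth_window > 0:
        dt = float(np.median(np.diff(tr.t)))
        w = max(1, int(round(smooth_window / dt)))
        if w % 2 == 0:
            w += 1
        if w > 1:
            vx = uniform_filter1d(vx, size=w, mode="nearest")
            vy = uniform_filter1d(vy, size=w, mode="nearest")
    speed = np.hypot(vx, vy)
    return vx, vy, speed


# ---------------------------------------------------------------------------
# lateralization

_MIRROR_FLAG = "mirrored_left_to_right"


def _mirror_release_dir(deg: float) -> float:
    # mirror about the y-axis: theta -> 180 - theta (mod 360)
    return float((180.0 - deg) % 360.0)


def flip_trial(tr: TrialRecord) -> TrialRecord:
    """Mirror one left-arm trial about the y-axis (see :func:`flip_left_to_right`)."""
    meta = tr.meta
    if meta.side not in SIDES:
        raise TrialValidationError(f"trial {meta.trial_id!r}: side missing/unknown")
    unflip = _MIRROR_FLAG in meta.flags
    if meta.side == "right" and not unflip:
        return tr
    pulse = {"CW": "CCW", "CCW": "CW"}.get(meta.pulse_sign, meta.pulse_sign)
    rel = meta.release_direction_deg
    if rel is not None:
        rel = _mirror_release_dir(rel)
    if unflip:
        new_side = "left"
        new_flags = meta.flags - {_MIRROR_FLAG}
    else:
        new_side = "right"
        new_flags = meta.flags | {_MIRROR_FLAG}
    new_meta = replace(
        meta,
        side=new_side,
        flags=new_flags,
        pulse_sign=pulse,
        release_direction_deg=rel,
        start_pos=(-meta.start_pos[0], meta.start_pos[1]),
        target_pos=(-meta.target_pos[0], meta.target_pos[1]),
    )
    return TrialRecord(
        meta=new_meta,
        t=tr.t.copy(),
        x=-tr.x,
        y=tr.y.copy(),
        fx=-tr.fx,
        fy=tr.fy.copy(),
        events=dict(tr.events),
    )


def flip_left_to_right(ts: TrialSet) -> TrialSet:
    """Mirror left-arm trials so cohorts aggregate in a common right-arm frame.

    ``x``, ``fx``, targets, pulse signs and release directions are mirrored
    about the y-axis; mirrored trials are relabeled ``side="right"`` and
    tagged, so a second application restores the original (involution).
    """
    return TrialSet([flip_trial(tr) for tr in ts.trials], provenance=ts.provenance)
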