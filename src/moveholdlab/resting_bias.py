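"""Resting postural force-bias estimation from passive-hold trials.

Per trial, the resting bias is the mean handle force over a window of the
hold period (default 2-5 s after hold onset, discarding the first 2 s in
which approach-velocity-dependent tone may still be decaying).  Per-trial
estimates are averaged over the repeated visits to each position, yielding
a :class:`BiasMap` per subject x arm x support condition; forces at the five
canonical targets are obtained directly where a measured position is close
enough, else by piecewise-linear interpolation on a triangulation of the
measured positions.

A scalar potential ("isocline") map can be fitted to any bias map:
the least-squares scalar field whose negative gradient best matches the
interpolated vector field, with a small Laplacian smoothing penalty; bias
vectors cross its level sets perpendicularly, and its residual reports the
non-conservative (curl) part of the field that no potential can capture.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.sparse.linalg import lsqr
from scipy.spatial import QhullError

from .io import TrialRecord
from .synthetic import target_array, DISTANT_TARGET_IDX, NEAR_TARGET_IDX

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = (2.0, 5.0)      # s after hold onset
DIRECT_LOOKUP_TOL_CM = 0.5       # robot positioning repeatability scale
QC_MAX_DRIFT_CM = 1.0            # hand displacement allowed during hold
QC_FORCE_SD_MULT = 3.0           # x noise scale
DEFAULT_NOISE_SCALE_N = 0.3


@dataclass
class BiasMeasurement:
    position: tuple
    visit_forces: list              # retained per-visit (fx, fy) tuples
    mean_force: tuple
    n_rejected: int = 0


@dataclass
class BiasMap:
    subject_id: str
    arm: str
    support: str
    measurements: list
    canonical_positions: np.ndarray = field(default_factory=target_array)
    canonical_forces: Optional[np.ndarray] = None   # (5, 2)
    canonical_source: Optional[list] = None         # direct|interpolated|extrapolated

    def positions(self) -> np.ndarray:
        return np.array([m.position for m in self.measurements], dtype=float)

    def forces(self) -> np.ndarray:
        return np.array([m.mean_force for m in self.measurements], dtype=float)


@dataclass
class PotentialMap:
    grid_x: np.ndarray
    grid_y: np.ndarray
    phi: np.ndarray                 # (ny, nx), N*cm; phi(center target) = 0
    fit_residual: float             # N, RMS of grad(phi) + F over nodes


# ---------------------------------------------------------------------------
# per-trial estimation


def estimate_trial_bias(
    tr: TrialRecord,
    window: tuple = DEFAULT_WINDOW,
    noise_scale: float = DEFAULT_NOISE_SCALE_N,
    qc: bool = True,
    max_drift_cm: float = QC_MAX_DRIFT_CM,
    force_sd_mult: float = QC_FORCE_SD_MULT,
):
    """Mean resting force over the hold window; returns ``(force, rejected)``.

    The automated QC proxy replaces the visual trial rejection of a human
    rater: a trial is flagged when the hand drifts more than ``max_drift_cm``
    during the hold or when the within-window force standard deviation
    exceeds ``force_sd_mult`` times the sensor-noise scale.
    """
    if tr.meta.trial_type != "passive_hold" or "hold_onset" not in tr.events:
        raise ValueError(
            f"trial {tr.meta.trial_id!r}: not a passive-hold trial with a hold onset"
        )
    h = float(tr.events["hold_onset"])
    lo, hi = h + window[0], h + window[1]
    if lo < tr.t[0] - 1e-9 or hi > tr.t[-1] + 1e-9:
        raise ValueError(
            f"trial {tr.meta.trial_id!r}: window [{lo}, {hi}] outside trial span"
        )
    m = (tr.t >= lo - 1e-9) & (tr.t <= hi + 1e-9)
    force = (float(np.mean(tr.fx[m])), float(np.mean(tr.fy[m])))
    rejected = False
    if qc:
        hold = tr.t >= h - 1e-9
        pos = tr.position()[hold]
        drift = float(np.max(np.linalg.norm(pos - pos[0], axis=1)))
        fsd = float(max(np.std(tr.fx[m]), np.std(tr.fy[m])))
        rejected = drift > max_drift_cm or fsd > force_sd_mult * noise_scale
    return force, rejected


# ---------------------------------------------------------------------------
# aggregation and interpolation


def _group_positions(trials, decimals: int = 3):
    groups = {}
    for tr in trials:
        key = tuple(np.round(np.asarray(tr.meta.target_pos, float), decimals))
        groups.setdefault(key, []).append(tr)
    return groups


def aggregate_bias_map(
    trials: Iterable[TrialRecord],
    window: tuple = DEFAULT_WINDOW,
    noise_scale: float = DEFAULT_NOISE_SCALE_N,
    qc: bool = True,
    canonical_positions: Optional[np.ndarray] = None,
    direct_tol: float = DIRECT_LOOKUP_TOL_CM,
) -> BiasMap:
    """Average per-trial biases over visits; fill canonical target forces.

    All trials must share one subject x arm x support condition.  Canonical
    forces come from a directly measured position within ``direct_tol`` cm
    when available, otherwise from interpolation (tagged); targets outside
    the convex hull of measured positions fall back to the nearest
    measurement and are tagged ``extrapolated`` with a logged warning.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("no trials to aggregate")
    keys = {(t.meta.subject_id, t.meta.arm, t.meta.support) for t in trials}
    if len(keys) != 1:
        raise ValueError(f"trials span multiple subject/arm/support keys: {keys}")
    subject_id, arm, support = keys.pop()

    measurements = []
    for pos_key, group in _group_positions(trials).items():
        retained, n_rej = [], 0
        for tr in group:
            force, rejected = estimate_trial_bias(
                tr, window=window, noise_scale=noise_scale, qc=qc
            )
            if rejected:
                n_rej += 1
            else:
                retained.append(force)
        if not retained:
            logger.warning(
                "position %s: all %d visits rejected; skipping", pos_key, n_rej
            )
            continue
        mean = tuple(np.mean(np.array(retained), axis=0))
        measurements.append(
            BiasMeasurement(
                position=pos_key,
                visit_forces=retained,
                mean_force=mean,
                n_rejected=n_rej,
            )
        )

    bm = BiasMap(
        subject_id=subject_id,
        arm=arm,
        support=support,
        measurements=measurements,
        canonical_positions=(
            np.asarray(canonical_positions, float)
            if canonical_positions is not None
            else target_array()
        ),
    )
    _fill_canonical(bm, direct_tol)
    return bm


def _fill_canonical(bm: BiasMap, direct_tol: float) -> None:
    pos = bm.positions()
    forces = bm.forces()
    n_can = len(bm.canonical_positions)
    out = np.zeros((n_can, 2))
    source = []
    interp = None
    for i, q in enumerate(bm.canonical_positions):
        d = np.linalg.norm(pos - q[None, :], axis=1)
        j = int(np.argmin(d))
        if d[j] <= direct_tol:
            out[i] = forces[j]
            source.append("direct")
            continue
        if interp is None:
            interp = _build_interpolators(pos, forces)
        val = np.array([interp[0](q), interp[1](q)], dtype=float).ravel()
        if np.any(np.isnan(val)):
            val = np.array([interp[2](q), interp[3](q)], dtype=float).ravel()
            source.append("extrapolated")
            logger.warning(
                "canonical target %s outside the measured hull for %s/%s/%s; "
                "using nearest measurement",
                tuple(q), bm.subject_id, bm.arm, bm.support,
            )
        else:
            source.append("interpolated")
        out[i] = val
    bm.canonical_forces = out
    bm.canonical_source = source


def _build_interpolators(pos: np.ndarray, forces: np.ndarray):
    if len(pos) < 3:
        raise ValueError("need >=3 measured positions to interpolate")
    try:
        lin_x = LinearNDInterpolator(pos, forces[:, 0])
        lin_y = LinearNDInterpolator(pos, forces[:, 1])
    except QhullError as err:
        raise ValueError(f"measured positions are collinear: {err}") from err
    near_x = NearestNDInterpolator(pos, forces[:, 0])
    near_y = NearestNDInterpolator(pos, forces[:, 1])
    return lin_x, lin_y, near_x, near_y


def interpolate_bias(bm: BiasMap, q) -> np.ndarray:
    """Piecewise-linear interpolation of the bias field at ``q`` (cm).

    Exact at measured positions and on linear fields; outside the convex
    hull falls back to the nearest measurement (a logged warning).
    """
    q = np.asarray(q, dtype=float)
    interp = _build_interpolators(bm.positions(), bm.forces())
    val = np.array([interp[0](q), interp[1](q)], dtype=float).ravel()
    if np.any(np.isnan(val)):
        logger.warning("query %s outside measured hull; nearest-neighbour fallback",
                       tuple(q))
        val = np.array([interp[2](q), interp[3](q)], dtype=float).ravel()
    return val


# ---------------------------------------------------------------------------
# cohort summaries


def _circ_stats(angles_deg):
    from .interaction_stats import circ_mean_sem

    return circ_mean_sem(angles_deg)


def summarize_bias(maps: Sequence[BiasMap]) -> pd.DataFrame:
    """Per-subject and cohort summary of canonical-target bias magnitudes
    and directions.

    Magnitudes are averaged within the distant (center + two far targets)
    and near (two close targets) proximity classes; directions are circular
    means over the five targets.  Cohort rows aggregate subjects with plain
    mean +/- SEM for magnitudes and circular mean +/- SEM for directions.
    """
    if not maps:
        raise ValueError("empty cohort")
    rows = []
    for bm in maps:
        if bm.canonical_forces is None:
            raise ValueError("BiasMap lacks canonical forces")
        f = bm.canonical_forces
        mag = np.linalg.norm(f, axis=1)
        ang = np.degrees(np.arctan2(f[:, 1], f[:, 0]))
        mean_dir, _ = _circ_stats(ang)
        rows.append(
            {
                "subject_id": bm.subject_id,
                "arm": bm.arm,
                "support": bm.support,
                "mag_distant": float(np.mean(mag[list(DISTANT_TARGET_IDX)])),
                "mag_near": float(np.mean(mag[list(NEAR_TARGET_IDX)])),
                "mag_all": float(np.mean(mag)),
                "direction_deg": float(mean_dir),
            }
        )
    per_subject = pd.DataFrame(rows)

    cohort_rows = []
    for (arm, support), g in per_subject.groupby(["arm", "support"]):
        n = len(g)
        row = {"arm": arm, "support": support, "n": n}
        for col in ("mag_distant", "mag_near", "mag_all"):
            row[f"{col}_mean"] = float(g[col].mean())
            row[f"{col}_sem"] = float(g[col].std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        mean_dir, sem_dir = _circ_stats(g["direction_deg"].to_numpy())
        row["direction_mean_deg"] = float(mean_dir)
        row["direction_sem_deg"] = float(sem_dir)
        cohort_rows.append(row)
    cohort = pd.DataFrame(cohort_rows)
    cohort.attrs["per_subject"] = per_subject
    return cohort


# ---------------------------------------------------------------------------
# potential / isocline reconstruction


def fit_potential(
    bm: BiasMap,
    grid_spacing: float = 1.0,
    smoothing: float = 1e-3,
    center: Optional[Sequence[float]] = None,
) -> PotentialMap:
    """Fit a scalar potential whose negative gradient matches the bias field.

    Minimises ``sum ||grad(phi) + F||^2 + smoothing * ||lap(phi)||^2`` over
    a regular grid spanning the measured positions, with ``F`` the
    interpolated bias field (nearest-neighbour outside the hull), gradients
    by centered differences.  The additive constant is fixed so that
    ``phi`` is zero at the center canonical target; forces point "downhill".
    """
    pos = bm.positions()
    xmin, ymin = pos.min(axis=0)
    xmax, ymax = pos.max(axis=0)
    gx = np.arange(xmin, xmax + grid_spacing / 2, grid_spacing)
    gy = np.arange(ymin, ymax + grid_spacing / 2, grid_spacing)
    nx, ny = len(gx), len(gy)
    if nx < 3 or ny < 3:
        raise ValueError(f"degenerate grid {ny}x{nx}; need at least 3x3")
    xx, yy = np.meshgrid(gx, gy)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    interp = _build_interpolators(pos, bm.forces())
    fx = np.asarray(interp[0](pts), dtype=float)
    fy = np.asarray(interp[1](pts), dtype=float)
    out = np.isnan(fx) | np.isnan(fy)
    if out.any():
        fx[out] = np.asarray(interp[2](pts[out]), dtype=float)
        fy[out] = np.asarray(interp[3](pts[out]), dtype=float)

    Dx = _diff_operator(nx, grid_spacing)
    Dy = _diff_operator(ny, grid_spacing)
    Ix = sp.identity(nx, format="csr")
    Iy = sp.identity(ny, format="csr")
    Gx = sp.kron(Iy, Dx, format="csr")          # d/dx with row-major (y, x) layout
    Gy = sp.kron(Dy, Ix, format="csr")
    Lap = Gx.T @ Gx + Gy.T @ Gy
    A = sp.vstack([Gx, Gy, math.sqrt(smoothing) * Lap], format="csr")
    b = np.concatenate([-fx, -fy, np.zeros(nx * ny)])
    phi = lsqr(A, b, atol=1e-12, btol=1e-12, iter_lim=20000)[0]

    res = np.concatenate([Gx @ phi + fx, Gy @ phi + fy])
    residual = float(np.sqrt(np.mean(res**2)))

    phi_grid = phi.reshape(ny, nx)
    if center is None:
        center = bm.canonical_positions[0]
    ic = int(np.argmin(np.abs(gy - center[1])))
    jc = int(np.argmin(np.abs(gx - center[0])))
    phi_grid = phi_grid - phi_grid[ic, jc]
    return PotentialMap(grid_x=gx, grid_y=gy, phi=phi_grid, fit_residual=residual)


def _diff_operator(n: int, h: float) -> sp.csr_matrix:
    """1-D first-derivative operator: centered inside, one-sided at the ends."""
    D = sp.lil_matrix((n, n))
    for i in range(n):
        if i == 0:
            D[i, 0], D[i, 1] = -1.0 / h, 1.0 / h
        elif i == n - 1:
            D[i, n - 2], D[i, n - 1] = -1.0 / h, 1.0 / h
        else:
            D[i, i - 1], D[i, i + 1] = -0.5 / h, 0.5 / h
    return D.tocsr()


# ---------------------------------------------------------------------------
# measurement-variance decomposition


def variance_decomposition(maps: Sequence[BiasMap]) -> float:
    """Fraction of bias-magnitude variance due to repeated measurement.

    One-way decomposition on per-visit bias magnitudes: the within-position
    sum of squares (same location, condition and subject) over the total sum
    of squares across all visits, positions, conditions and subjects.
    """
    groups = []
    for bm in maps:
        for meas in bm.measurements:
            mags = [float(np.hypot(fx, fy)) for fx, fy in meas.visit_forces]
            if len(mags) >= 1:
                groups.append(mags)
    replicated = [g for g in groups if len(g) >= 2]
    if not replicated:
        raise ValueError("no position has >=2 retained visits")
    all_vals = np.concatenate([np.asarray(g) for g in groups])
    grand = all_vals.mean()
    ss_total = float(np.sum((all_vals - grand) ** 2))
    ss_within = float(
        sum(np.sum((np.asarray(g) - np.mean(g)) ** 2) for g in groups)
    )
    if ss_total == 0:
        return 0.0
    return ss_within / ss_total
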