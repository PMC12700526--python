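"""Inference layer: do resting biases intrude on moving, or only on holding?

The tools here project per-position resting bias vectors onto the geometry
of each movement or perturbation, then quantify their association with the
kinematic outcomes three ways:

* **extreme-instance contrasts** — per subject, pick the two direction (or
  position x perturbation-direction) instances with the strongest opposing
  projected biases and compare outcome means with a paired t-test;
* **per-subject sensitivities** — OLS slope of an outcome against the
  projected bias over all trials, tested at the group level with a
  one-sample t-test against zero;
* **Response Asymmetry Index** — ``RAI = (r_A - r_O) / (r_A + r_O)`` for
  nonnegative responses ``r_A`` (bias most aligned with the perturbation)
  and ``r_O`` (most opposed), compared between holding-release and
  moving-pulse perturbations.

Plus the circular mean/SEM used for bias directions and the mixed-model
ANOVA of bias magnitudes against impairment (FM-UE), target proximity and
arm support.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# geometry


def project_bias(bias, context: str, direction_deg: float) -> float:
    """Signed component (N) of a bias vector in a movement/perturbation frame.

    For the lateral contexts (``reach_start``, ``reach_end``, ``pulse``)
    ``direction_deg`` is the movement direction and the projection is onto
    the unit vector 90 degrees CCW of it (CCW positive).  For ``release``
    it is the direction of the imposed force, and the projection is onto
    the displacement direction after release (opposite the removed force);
    positive means the bias is aligned with the perturbing displacement.
    """
    bias = np.asarray(bias, dtype=float)
    if not np.isfinite(direction_deg):
        raise ValueError("direction is undefined")
    th = math.radians(float(direction_deg))
    if context in ("reach_start", "reach_end", "pulse"):
        u = np.array([-math.sin(th), math.cos(th)])
    elif context == "release":
        u = -np.array([math.cos(th), math.sin(th)])
    else:
        raise ValueError(f"unknown context {context!r}")
    return float(bias @ u)


@dataclass
class ExtremePair:
    context: str
    key_positive: object            # most CCW (lateral) / most aligned (release)
    key_negative: object
    component_values: tuple         # (positive side, negative side), N
    outcome_means: tuple
    n_trials: tuple


@dataclass
class SensitivityResult:
    outcome: str
    slopes: pd.Series               # per subject, outcome units per N
    mean: float
    sem: float
    t: float
    df: int
    p: float


@dataclass
class RAIResult:
    r_aligned: float
    r_opposed: float
    rai: float


# ---------------------------------------------------------------------------
# selection and tests


def select_extremes(
    components: Mapping,
    outcomes: Mapping,
    context: str = "reach_start",
) -> ExtremePair:
    """Pick the two instances with the strongest opposing projected biases.

    ``components`` maps a direction key to its signed projected bias;
    ``outcomes`` maps the same keys to the per-trial outcome values of that
    instance.  Returns the argmax/argmin pair (ties broken by lexicographic
    key order, logged); raises if every component is equal.
    """
    keys = sorted(components)
    if len(keys) < 2:
        raise ValueError("need at least two direction keys")
    vals = np.array([components[k] for k in keys], dtype=float)
    if np.all(vals == vals[0]):
        raise ValueError("degenerate selection: all projected components equal")
    hi = int(np.argmax(vals))       # argmax/argmin take the first = smallest key
    lo = int(np.argmin(vals))
    if np.sum(vals == vals[hi]) > 1 or np.sum(vals == vals[lo]) > 1:
        logger.info("extreme-selection tie broken lexicographically")
    k_hi, k_lo = keys[hi], keys[lo]
    out_hi = np.asarray(outcomes[k_hi], dtype=float)
    out_lo = np.asarray(outcomes[k_lo], dtype=float)
    return ExtremePair(
        context=context,
        key_positive=k_hi,
        key_negative=k_lo,
        component_values=(float(vals[hi]), float(vals[lo])),
        outcome_means=(float(np.nanmean(out_hi)), float(np.nanmean(out_lo))),
        n_trials=(int(np.sum(np.isfinite(out_hi))), int(np.sum(np.isfinite(out_lo)))),
    )


def paired_contrast(values_a, values_b):
    """Classical paired t-test; returns ``(mean_diff, t, df, p)``.

    Identical samples give the degenerate but well-defined ``t=0, p=1``;
    exactly tied nonzero differences (infinite t) raise instead.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    d = a - b
    if np.std(d, ddof=1) == 0:
        if np.all(d == 0):
            return 0.0, 0.0, a.size - 1, 1.0
        raise ValueError(
            "zero variance of paired differences (exact nonzero ties; t undefined)"
        )
    t, p = sps.ttest_rel(a, b)
    return float(np.mean(d)), float(t), a.size - 1, float(p)


def holm_adjust(pvalues: Mapping) -> dict:
    """Holm step-down adjusted p-values for a named family of tests.

    Not applied by default anywhere in the pipeline (raw two-sided
    p-values are reported); available as a robustness mode.
    """
    items = sorted(pvalues.items(), key=lambda kv: kv[1])
    m = len(items)
    adjusted, running = {}, 0.0
    for rank, (name, p) in enumerate(items):
        running = max(running, (m - rank) * p)
        adjusted[name] = min(running, 1.0)
    return adjusted


def sensitivity(
    df: pd.DataFrame,
    outcome: str,
    bias_col: str,
    subject_col: str = "subject_id",
    by_direction: Optional[Sequence] = None,
) -> SensitivityResult:
    """Per-subject OLS slope of ``outcome`` against ``bias_col``, and the
    group-level one-sample t-test of the slopes against zero.

    Subjects whose projected bias does not vary (slope undefined) are
    dropped with a warning.  Uses trial-level data (all trials) by
    default; pass key columns in ``by_direction`` to regress on
    per-direction outcome means instead (a robustness mode).
    """
    if by_direction is not None:
        df = (
            df.groupby([subject_col, *by_direction], as_index=False)[
                [bias_col, outcome]
            ].mean()
        )
    slopes = {}
    for subj, g in df.groupby(subject_col):
        x = g[bias_col].to_numpy(dtype=float)
        y = g[outcome].to_numpy(dtype=float)
        m = np.isfinite(x) & np.isfinite(y)
        x, y = x[m], y[m]
        if x.size < 2 or np.all(x == x[0]):
            logger.warning("subject %s: constant bias, dropped from sensitivity", subj)
            continue
        slopes[subj] = float(np.polyfit(x, y, 1)[0])
    if len(slopes) < 2:
        raise ValueError("fewer than two subjects with estimable slopes")
    s = pd.Series(slopes, name=f"slope[{outcome}]").sort_index()
    sd = float(s.std(ddof=1))
    n = len(s)
    if sd == 0:
        t, p = (math.inf if s.mean() != 0 else 0.0), (0.0 if s.mean() != 0 else 1.0)
    else:
        t, p = sps.ttest_1samp(s.to_numpy(), 0.0)
    return SensitivityResult(
        outcome=outcome,
        slopes=s,
        mean=float(s.mean()),
        sem=sd / math.sqrt(n),
        t=float(t),
        df=n - 1,
        p=float(p),
    )


def response_asymmetry_index(r_aligned: float, r_opposed: float) -> RAIResult:
    """``RAI = (r_A - r_O) / (r_A + r_O)`` for nonnegative responses."""
    r_a, r_o = float(r_aligned), float(r_opposed)
    if not (r_a + r_o) > 0:
        raise ValueError("RAI undefined: r_aligned + r_opposed must be > 0")
    return RAIResult(r_a, r_o, (r_a - r_o) / (r_a + r_o))


def circ_mean_sem(angles_deg):
    """Circular mean and SEM (degrees) of a sample of angles.

    Mean from the resultant vector; SEM is the circular standard deviation
    ``sqrt(-2 ln R)`` divided by ``sqrt(n)``.  Raises when the resultant
    length vanishes (e.g. an antipodal pair), where the mean is undefined.
    """
    a = np.radians(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise ValueError("no angles")
    C, S = np.mean(np.cos(a)), np.mean(np.sin(a))
    R = math.hypot(C, S)
    if R < 1e-12:
        raise ValueError("circular mean undefined: zero resultant length")
    mean = math.degrees(math.atan2(S, C))
    csd = math.sqrt(max(-2.0 * math.log(R), 0.0))
    sem = math.degrees(csd) / math.sqrt(a.size)
    from .io import wrap_angle

    return float(wrap_angle(mean)), float(sem)


# ---------------------------------------------------------------------------
# Experiment-1 ANOVA


def rest_anova(df: pd.DataFrame) -> pd.DataFrame:
    """Mixed-model ANOVA of bias magnitudes: FM-UE x Support x Proximity.

    ``df`` needs one row per subject x support x proximity cell with columns
    ``subject_id``, ``support`` (airsled/none), ``proximity`` (distant/near),
    ``magnitude`` and ``fm_ue`` (constant within subject).  Support and
    Proximity are within-subject factors (sum-coded), FM-UE a continuous
    between-subject covariate; the model includes all two-way interactions
    and a random intercept per subject.

    Returns one row per effect with classical eta-squared
    (``SS_effect / SS_total``, from the fixed-effects SS partition),
    partial eta-squared, and the mixed-model Wald p-value.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    required = {"subject_id", "support", "proximity", "magnitude", "fm_ue"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    counts = df.groupby(["subject_id", "support", "proximity"]).size()
    n_cells = df["support"].nunique() * df["proximity"].nunique()
    per_subject = counts.groupby("subject_id").size()
    if (counts != 1).any() or (per_subject != n_cells).any():
        raise ValueError("unbalanced design: every subject needs one row per cell")

    d = df.copy()
    d["fm_c"] = d["fm_ue"] - d["fm_ue"].mean()
    formula = (
        "magnitude ~ fm_c + C(support, Sum) + C(proximity, Sum)"
        " + fm_c:C(support, Sum) + fm_c:C(proximity, Sum)"
        " + C(support, Sum):C(proximity, Sum)"
    )
    terms = {
        "fm_c": "FM-UE",
        "C(support, Sum)": "Support",
        "C(proximity, Sum)": "Proximity",
        "fm_c:C(support, Sum)": "FM-UE x Support",
        "fm_c:C(proximity, Sum)": "FM-UE x Proximity",
        "C(support, Sum):C(proximity, Sum)": "Support x Proximity",
    }

    ss_total = float(np.sum((d["magnitude"] - d["magnitude"].mean()) ** 2))
    if ss_total == 0:
        rows = [
            {"effect": name, "eta_sq": 0.0, "eta_sq_partial": 0.0,
             "p": float("nan"), "sign": 0.0}
            for name in terms.values()
        ]
        return pd.DataFrame(rows)

    ols_fit = smf.ols(formula, data=d).fit()
    table = anova_lm(ols_fit, typ=2)
    ss_resid = float(table.loc["Residual", "sum_sq"])

    mixed = smf.mixedlm(formula, data=d, groups=d["subject_id"]).fit(reml=True)

    rows = []
    for term, name in terms.items():
        ss = float(table.loc[term, "sum_sq"])
        coef_names = [c for c in mixed.fe_params.index if _same_term(c, term)]
        p = min(
            (float(mixed.pvalues[c]) for c in coef_names), default=float("nan")
        )
        sign = float(np.sum([mixed.fe_params[c] for c in coef_names]))
        rows.append(
            {
                "effect": name,
                "eta_sq": ss / ss_total,
                "eta_sq_partial": ss / (ss + ss_resid) if (ss + ss_resid) > 0 else 0.0,
                "p": p,
                "sign": sign,
            }
        )
    return pd.DataFrame(rows)


def _same_term(coef_name: str, term: str) -> bool:
    """Match a patsy coefficient name to its model term."""
    base = coef_name.split("[")[0] if ":" not in coef_name else coef_name
    if ":" in term:
        parts_t = [p.split("[")[0] for p in term.split(":")]
        parts_c = [p.split("[")[0] for p in coef_name.split(":")]
        return parts_c == parts_t
    return ":" not in coef_name and base == term
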