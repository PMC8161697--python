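"""Statistical battery for enface-index cohorts.

Implements the analyses used to compare glaucoma and control eyes:

* linear mixed model with crossed random intercepts (eye, ONH sector) and a
  likelihood-ratio test for the disease fixed effect;
* Welch post-hoc t-tests with Bonferroni correction (family of 14: two
  indices × six sectors + weighted average);
* standardized partial AUC at specificity 90–100% (trapezoid rule, McClish
  linear standardization), stratified-bootstrap CIs, and paired comparisons
  (DeLong on the full AUC, or paired bootstrap on the standardized pAUC);
* repeated-measures correlation (common-slope ANCOVA; df = N − subjects − 1)
  and Pearson correlation with Fisher-z CIs;
* minimum detectable correlation at given power (bias-corrected Fisher-z);
* the early-glaucoma subgroup filter (MD ≥ −4 dB).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq

from .geometry import SECTOR_NAMES, SECTOR_WIDTHS_DEG

DEFAULT_SPEC_RANGE: tuple[float, float] = (0.90, 1.00)
BONFERRONI_FAMILY: int = 14


# ---------------------------------------------------------------------------
# Linear mixed model
# ---------------------------------------------------------------------------

@dataclass
class LmmResult:
    """Disease fixed effect from the mixed model, reported as control − glaucoma.

    ``group_difference_um`` is positive when the index is shallower (smaller)
    in glaucoma. ``lrt_chi2``/``lrt_p`` compare the full model against the
    no-disease-effect model, both fitted by maximum likelihood (df = 1).
    """

    group_difference_um: float
    ci_low: float
    ci_high: float
    lrt_chi2: float
    lrt_df: int
    lrt_p: float
    var_eye: float
    var_sector: float
    var_resid: float
    converged: bool


def fit_lmm(table: pd.DataFrame, measure: str) -> LmmResult:
    """Fit ``measure ~ disease + (1|eye) + (1|sector)`` and its LRT.

    ``table`` is long-format with columns eye_id, group (control/glaucoma),
    sector, and the measure. Both models are fitted by ML (they differ in
    fixed effects). Singular/non-converged fits are returned with
    ``converged=False`` rather than raised.
    """
    import statsmodels.formula.api as smf

    data = table[["eye_id", "group", "sector", measure]].dropna().copy()
    data.columns = ["eye_id", "group", "sector", "y"]
    if data["group"].nunique() != 2:
        raise ValueError("fit_lmm requires both groups present")
    if data.groupby("group")["eye_id"].nunique().min() < 2:
        raise ValueError("fit_lmm requires >=2 eyes per group")
    if data["sector"].nunique() < 2:
        raise ValueError("fit_lmm requires >=2 sectors")
    data["one"] = 1
    vc = {"eye": "0 + C(eye_id)", "sector": "0 + C(sector)"}
    data["disease"] = (data["group"] == "glaucoma").astype(float)

    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            full = smf.mixedlm(
                "y ~ disease", data, groups="one", vc_formula=vc, re_formula="0"
            ).fit(reml=False)
            null = smf.mixedlm(
                "y ~ 1", data, groups="one", vc_formula=vc, re_formula="0"
            ).fit(reml=False)
            converged = bool(full.converged and null.converged)
        except Exception:
            # fall back to the degenerate OLS answer, flagged
            converged = False
            g = data.groupby("group")["y"].mean()
            diff = float(g["control"] - g["glaucoma"])
            return LmmResult(diff, np.nan, np.nan, np.nan, 1, np.nan,
                             np.nan, np.nan, np.nan, False)

    coef = float(full.fe_params["disease"])
    se = float(full.bse_fe["disease"])
    z = sps.norm.ppf(0.975)
    # report as control − glaucoma (positive = shallower in glaucoma)
    diff = -coef
    ci_low, ci_high = diff - z * se, diff + z * se
    chi2 = max(0.0, 2.0 * (full.llf - null.llf))
    p = float(sps.chi2.sf(chi2, 1))
    vcomp = dict(zip(full.model.exog_vc.names, full.vcomp))
    return LmmResult(
        group_difference_um=diff,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        lrt_chi2=float(chi2),
        lrt_df=1,
        lrt_p=p,
        var_eye=float(vcomp.get("eye", np.nan)),
        var_sector=float(vcomp.get("sector", np.nan)),
        var_resid=float(full.scale),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

def welch_t_from_summary(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int
) -> tuple[float, float, float]:
    """Welch two-sample t from summary statistics: (t, df, two-sided p).

    Undefined when both SDs are zero (flagged with NaNs if the means are
    equal; infinite t otherwise).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    if v1 + v2 == 0:
        if m1 == m2:
            return (0.0, float("nan"), float("nan"))
        return (float(np.sign(m1 - m2)) * float("inf"), float("nan"), 0.0)
    t = (m1 - m2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return (float(t), float(df), p)


def _weighted_average_per_eye(table: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Per-eye sector-width-weighted average of a measure (needs all 6 sectors)."""
    widths = dict(zip(SECTOR_NAMES, SECTOR_WIDTHS_DEG))

    def agg(g: pd.DataFrame) -> float:
        if set(g["sector"]) != set(SECTOR_NAMES):
            return np.nan
        w = g["sector"].map(widths)
        return float((g[measure] * w).sum() / 360.0)

    out = (
        table.groupby(["eye_id", "group"])[["sector", measure]]
        .apply(agg, include_groups=False)
        .rename(measure)
        .reset_index()
    )
    return out


def posthoc_ttests(
    table: pd.DataFrame,
    measures: tuple[str, ...] = ("first_gap_um", "last_visible_um"),
    family: int | None = None,
) -> pd.DataFrame:
    """Welch t-tests per sector and per weighted average, Bonferroni-adjusted.

    The family defaults to ``len(measures) × 7`` (six sectors + the weighted
    average for each measure), i.e. 14 for the two enface indices, giving the
    adjusted significance threshold 0.05/14 ≈ 0.0036. Returns one row per
    test with Welch t, Satterthwaite df, raw p, and the significance call.
    """
    if family is None:
        family = len(measures) * (len(SECTOR_NAMES) + 1)
    alpha = 0.05 / family
    rows = []
    for measure in measures:
        per_eye_avg = _weighted_average_per_eye(table, measure)
        units: list[tuple[str, pd.DataFrame]] = [
            (s, table[table["sector"] == s]) for s in SECTOR_NAMES
        ]
        units.append(("AVG", per_eye_avg))
        for sector, sub in units:
            a = sub.loc[sub["group"] == "control", measure].dropna().to_numpy()
            b = sub.loc[sub["group"] == "glaucoma", measure].dropna().to_numpy()
            if a.size < 2 or b.size < 2:
                raise ValueError(f"both groups need >=2 eyes in {sector}")
            t, df, p = welch_t_from_summary(
                a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
            )
            rows.append(
                {
                    "measure": measure,
                    "sector": sector,
                    "mean_control": a.mean(),
                    "mean_glaucoma": b.mean(),
                    "difference": a.mean() - b.mean(),
                    "t": t,
                    "df": df,
                    "p": p,
                    "alpha_adjusted": alpha,
                    "significant": bool(p < alpha) if np.isfinite(p) else False,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ROC / partial AUC
# ---------------------------------------------------------------------------

@dataclass
class PaucResult:
    """Standardized partial AUC over specificity 90–100%.

    ``standardized`` maps the raw trapezoid area on FPR ∈ [0, 0.10] linearly
    so that the chance diagonal gives 0.5 and a perfect curve gives 1
    (McClish). ``ci`` is the stratified-bootstrap percentile interval when
    computed.
    """

    standardized: float
    raw: float
    spec_range: tuple[float, float]
    direction: str
    ci: tuple[float, float] | None = None
    B: int | None = None
    seed: int | None = None
    n_redraws: int = 0


def _oriented(scores: np.ndarray, direction: str) -> np.ndarray:
    if direction == "lower":
        return -scores
    if direction == "higher":
        return scores
    raise ValueError("direction must be 'lower' or 'higher'")


def roc_curve_points(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical ROC points (FPR, TPR), ascending, ties moving diagonally.

    ``scores`` are oriented so higher values indicate disease; ``labels`` are
    boolean (True = disease).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    # collapse tied scores into single ROC steps
    distinct = np.concatenate([np.diff(sorted_scores) != 0, [True]])
    tp = np.cumsum(sorted_labels)[distinct]
    fp = np.cumsum(~sorted_labels)[distinct]
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    return fpr, tpr


def _raw_pauc(fpr: np.ndarray, tpr: np.ndarray, fpr_max: float) -> float:
    """Trapezoid area under the ROC over FPR ∈ [0, fpr_max], boundary interpolated."""
    if fpr_max <= 0:
        return 0.0
    inside = fpr < fpr_max
    xs = np.concatenate([fpr[inside], [fpr_max]])
    # linear interpolation at the boundary (np.interp uses the first hit on ties)
    ys = np.concatenate([tpr[inside], [float(np.interp(fpr_max, fpr, tpr))]])
    return float(np.trapezoid(ys, xs))


def standardized_pauc(
    scores,
    labels,
    spec_range: tuple[float, float] = DEFAULT_SPEC_RANGE,
    direction: str = "lower",
) -> PaucResult:
    """Standardized partial AUC of a score for disease at high specificity.

    ``direction='lower'`` declares that low scores indicate disease (true for
    the depth indices and for RNFL thickness). With specificity restricted to
    ``spec_range`` = (s0, s1), the raw trapezoid area over FPR ∈ [1−s1, 1−s0]
    is standardized as ``0.5·(1 + (raw − A_chance)/(A_max − A_chance))``
    where A_chance is the chance-diagonal area and A_max the rectangle area.
    """
    s0, s1 = spec_range
    if not (0 <= s0 < s1 <= 1):
        raise ValueError("spec_range must satisfy 0 <= s0 < s1 <= 1")
    fpr_lo, fpr_hi = 1.0 - s1, 1.0 - s0
    if fpr_lo != 0.0:
        raise ValueError("only ranges extending to 100% specificity are supported")
    oriented = _oriented(np.asarray(scores, dtype=float), direction)
    fpr, tpr = roc_curve_points(oriented, labels)
    raw = _raw_pauc(fpr, tpr, fpr_hi)
    a_chance = fpr_hi**2 / 2.0
    a_max = fpr_hi
    standardized = 0.5 * (1.0 + (raw - a_chance) / (a_max - a_chance))
    return PaucResult(
        standardized=float(standardized),
        raw=raw,
        spec_range=(s0, s1),
        direction=direction,
    )


def bootstrap_ci(
    scores,
    labels,
    B: int = 2000,
    seed: int | None = None,
    spec_range: tuple[float, float] = DEFAULT_SPEC_RANGE,
    direction: str = "lower",
) -> PaucResult:
    """Stratified-bootstrap 95% percentile CI for the standardized pAUC.

    Resampling is within class, so each replicate retains both classes; a
    degenerate replicate (a class drawn empty, impossible under stratified
    resampling but guarded anyway) is redrawn and counted.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    point = standardized_pauc(scores, labels, spec_range, direction)
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(labels)
    neg = np.flatnonzero(~labels)
    values = np.empty(B)
    n_redraws = 0
    for b in range(B):
        while True:
            take = np.concatenate(
                [rng.choice(pos, size=pos.size), rng.choice(neg, size=neg.size)]
            )
            if labels[take].any() and (~labels[take]).any():
                break
            n_redraws += 1
        values[b] = standardized_pauc(
            scores[take], labels[take], spec_range, direction
        ).standardized
    lo, hi = np.percentile(values, [2.5, 97.5])
    point.ci = (float(lo), float(hi))
    point.B = B
    point.seed = seed
    point.n_redraws = n_redraws
    return point


def delong_auc_variance(
    scores_a, scores_b, labels
) -> tuple[float, float, float]:
    """DeLong full AUCs of two paired measures and the variance of their difference.

    Scores must already be oriented (higher = disease). Returns
    (auc_a, auc_b, var_diff).
    """
    labels = np.asarray(labels, dtype=bool)
    xs = np.vstack([np.asarray(scores_a, float), np.asarray(scores_b, float)])
    pos = xs[:, labels]
    neg = xs[:, ~labels]
    m, n = pos.shape[1], neg.shape[1]
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    aucs = np.empty(2)
    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    for k in range(2):
        diff = pos[k][:, None] - neg[k][None, :]
        psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
        aucs[k] = psi.mean()
        v10[k] = psi.mean(axis=1)
        v01[k] = psi.mean(axis=0)
    s10 = np.cov(v10)
    s01 = np.cov(v01)
    var_diff = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    return float(aucs[0]), float(aucs[1]), float(var_diff)


def compare_paired_auc(
    scores_a,
    scores_b,
    labels,
    method: str = "bootstrap",
    direction: str = "lower",
    spec_range: tuple[float, float] = DEFAULT_SPEC_RANGE,
    B: int = 2000,
    seed: int | None = None,
) -> float:
    """Two-sided p for a difference in discrimination between paired measures.

    ``method='delong'`` applies the DeLong paired test to the *full* AUC
    (classical theory covers the full area); ``method='bootstrap'`` resamples
    subjects within class and tests the standardized-pAUC difference against
    zero. A measure compared with itself returns p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("scores_a, scores_b and labels must have equal length")
    a = _oriented(scores_a, direction)
    b = _oriented(scores_b, direction)
    if method == "delong":
        auc_a, auc_b, var = delong_auc_variance(a, b, labels)
        d = auc_a - auc_b
        if var <= 0:
            return 1.0 if d == 0 else 0.0
        z = d / np.sqrt(var)
        return 2.0 * float(sps.norm.sf(abs(z)))
    if method == "bootstrap":
        if np.array_equal(scores_a, scores_b):
            return 1.0
        rng = np.random.default_rng(seed)
        pos = np.flatnonzero(labels)
        neg = np.flatnonzero(~labels)
        diffs = np.empty(B)
        for i in range(B):
            take = np.concatenate(
                [rng.choice(pos, size=pos.size), rng.choice(neg, size=neg.size)]
            )
            pa = standardized_pauc(scores_a[take], labels[take], spec_range, direction)
            pb = standardized_pauc(scores_b[take], labels[take], spec_range, direction)
            diffs[i] = pa.standardized - pb.standardized
        p_low = (np.sum(diffs < 0) + 0.5 * np.sum(diffs == 0)) / B
        p = 2.0 * min(p_low, 1.0 - p_low)
        return float(min(1.0, max(p, 2.0 / B)))
    raise ValueError("method must be 'delong' or 'bootstrap'")


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

@dataclass
class RmcorrResult:
    """Repeated-measures correlation: common within-subject association.

    ``r`` is the sign-of-slope square root of SS_measure/(SS_measure +
    SS_error) from the common-slope ANCOVA with subject intercepts;
    ``df = N_obs − n_subjects − 1``; CI by Fisher transform with standard
    error 1/sqrt(df − 1). ``valid`` is False when x has no within-subject
    variance.
    """

    r: float
    df: int
    ci_low: float
    ci_high: float
    p: float
    n_obs: int
    n_subjects: int
    valid: bool = True


def rmcorr(subjects, x, y) -> RmcorrResult:
    """Repeated-measures correlation of paired (x, y) within subjects."""
    subjects = np.asarray(subjects)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (subjects.shape == x.shape == y.shape):
        raise ValueError("subjects, x, y must have equal length")
    uniq, inverse, counts = np.unique(subjects, return_inverse=True, return_counts=True)
    if uniq.size < 2:
        raise ValueError("rmcorr requires >=2 subjects")
    if counts.min() < 2:
        raise ValueError("rmcorr requires >=2 observations per subject")
    n_obs = x.size
    n_subj = uniq.size
    df = n_obs - n_subj - 1
    # within-subject demeaning
    x_mean = np.bincount(inverse, weights=x) / counts
    y_mean = np.bincount(inverse, weights=y) / counts
    xd = x - x_mean[inverse]
    yd = y - y_mean[inverse]
    sxx = float(np.dot(xd, xd))
    if sxx == 0:
        return RmcorrResult(np.nan, df, np.nan, np.nan, np.nan, n_obs, n_subj, valid=False)
    sxy = float(np.dot(xd, yd))
    syy = float(np.dot(yd, yd))
    ss_measure = sxy**2 / sxx
    ss_error = syy - ss_measure
    if ss_measure + ss_error == 0:
        return RmcorrResult(np.nan, df, np.nan, np.nan, np.nan, n_obs, n_subj, valid=False)
    r = float(np.sign(sxy) * np.sqrt(ss_measure / (ss_measure + ss_error)))
    if ss_error <= 0:
        p = 0.0
    else:
        f = ss_measure / (ss_error / df)
        p = float(sps.f.sf(f, 1, df))
    if df > 1 and abs(r) < 1:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(df - 1)
        zc = sps.norm.ppf(0.975)
        ci = (float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se)))
    else:
        ci = (float("nan"), float("nan"))
    return RmcorrResult(r, df, ci[0], ci[1], p, n_obs, n_subj)


def pearson_ci(x, y) -> tuple[float, tuple[float, float], float]:
    """Pearson r with Fisher-z 95% CI (se = 1/sqrt(n−3)) and two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("pearson_ci requires n >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        return (float("nan"), (float("nan"), float("nan")), float("nan"))
    res = sps.pearsonr(x, y)
    ci = res.confidence_interval(0.95)
    return (float(res.statistic), (float(ci.low), float(ci.high)), float(res.pvalue))


# ---------------------------------------------------------------------------
# Power
# ---------------------------------------------------------------------------

def _fisher_power_lhs(r: float, n: int) -> float:
    # bias-corrected Fisher transform: atanh(r) + r/(2(n-1))
    return float(np.sqrt(n - 3) * (np.arctanh(r) + r / (2 * (n - 1))))


def power_for_r(r: float, n: int, alpha: float = 0.05) -> float:
    """Power of the two-sided Pearson test at true correlation ``r``."""
    z_alpha = sps.norm.ppf(1 - alpha / 2)
    return float(sps.norm.cdf(_fisher_power_lhs(r, n) - z_alpha))


def min_detectable_r(n: int, power: float = 0.90, alpha: float = 0.05) -> float:
    """Smallest correlation detectable with given power and two-sided alpha.

    Solves ``sqrt(n−3)·(atanh r + r/(2(n−1))) = z_{1−α/2} + z_{power}`` for r
    by bracketed root-finding (bias-corrected Fisher z).
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    if not (0 < power < 1 and 0 < alpha < 1):
        raise ValueError("power and alpha must be in (0, 1)")
    target = float(sps.norm.ppf(1 - alpha / 2) + sps.norm.ppf(power))

    def f(r: float) -> float:
        return _fisher_power_lhs(r, n) - target

    lo, hi = 1e-12, 1 - 1e-12
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("no root in (0, 1) for the requested power")
    return float(brentq(f, lo, hi, xtol=1e-12))


# ---------------------------------------------------------------------------
# Subgroup filter
# ---------------------------------------------------------------------------

def subgroup_filter(table: pd.DataFrame, md_threshold: float = -4.0) -> pd.DataFrame:
    """Early-glaucoma subgroup: keep all controls and glaucoma with MD ≥ threshold.

    'Better than or equal to' −4 dB means the boundary value is retained.
    Raises ``ValueError`` if no glaucoma rows survive.
    """
    if "md_db" not in table.columns:
        raise ValueError("table lacks the md_db column")
    keep = (table["group"] == "control") | (table["md_db"] >= md_threshold)
    out = table[keep].copy()
    if not (out["group"] == "glaucoma").any():
        raise ValueError(
            f"subgroup filter md_db >= {md_threshold} removed every glaucoma eye"
        )
    return out
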