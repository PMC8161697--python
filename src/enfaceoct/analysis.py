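"""Cohort-level analysis driver: the full statistical battery in one call.

Consumes the long-format cohort table (eye × sector rows of the two enface
indices and matched-angle thickness) and produces everything reported for a
case–control comparison: mixed-model disease effects with likelihood-ratio
tests, Bonferroni post-hocs, a diagnostic-performance table (standardized
pAUC with bootstrap CIs per sector and weighted average, for the enface
indices and their thickness counterparts), paired pAUC comparisons,
repeated-measures and per-sector Pearson correlations, and power numbers.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import stats
from .geometry import SECTOR_NAMES
from .stats import _weighted_average_per_eye

#: measure column → (pretty name, thickness counterpart column)
MEASURES: dict[str, tuple[str, str | None]] = {
    "first_gap_um": ("Enface First Gap", "thickness_at_fg_um"),
    "thickness_at_fg_um": ("RNFLT at First Gap Angle", None),
    "last_visible_um": ("Enface Last Visible Bundle", "thickness_at_lv_um"),
    "thickness_at_lv_um": ("RNFLT at Last Visible Angle", None),
}


def _eye_level(table: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Per-eye frame with sector columns plus the weighted average."""
    wide = table.pivot_table(
        index=["eye_id", "group"], columns="sector", values=measure, aggfunc="first"
    ).reset_index()
    avg = _weighted_average_per_eye(table, measure).rename(columns={measure: "AVG"})
    return wide.merge(avg, on=["eye_id", "group"])


def diagnostic_table(
    table: pd.DataFrame,
    B: int = 2000,
    seed: int | None = None,
    spec_range: tuple[float, float] = stats.DEFAULT_SPEC_RANGE,
) -> pd.DataFrame:
    """Standardized pAUC (95% bootstrap CI) per sector/AVG for each measure.

    Layout mirrors a diagnostic-performance table: one row per ONH sector
    (plus AVG), one column group per measure. All indices are scored with
    direction='lower' (smaller depth/thickness indicates glaucoma).
    """
    rng = np.random.default_rng(seed)
    rows = {unit: {"sector": unit} for unit in list(SECTOR_NAMES) + ["AVG"]}
    for measure, (pretty, _) in MEASURES.items():
        eye = _eye_level(table, measure)
        labels = (eye["group"] == "glaucoma").to_numpy()
        for unit in list(SECTOR_NAMES) + ["AVG"]:
            scores = eye[unit].to_numpy(dtype=float)
            ok = np.isfinite(scores)
            res = stats.bootstrap_ci(
                scores[ok],
                labels[ok],
                B=B,
                seed=int(rng.integers(2**31)),
                spec_range=spec_range,
                direction="lower",
            )
            rows[unit][f"{pretty} pAUC"] = round(res.standardized, 4)
            rows[unit][f"{pretty} CI low"] = round(res.ci[0], 4)
            rows[unit][f"{pretty} CI high"] = round(res.ci[1], 4)
    return pd.DataFrame([rows[u] for u in list(SECTOR_NAMES) + ["AVG"]])


def analyze_cohort(
    table: pd.DataFrame,
    B: int = 2000,
    seed: int | None = None,
    spec_range: tuple[float, float] = stats.DEFAULT_SPEC_RANGE,
    md_threshold: float | None = None,
    pauc_comparison_method: str = "bootstrap",
) -> dict:
    """Run the full battery; returns a JSON-serializable results dict.

    ``md_threshold`` (e.g. −4.0 dB) restricts glaucoma eyes to the early
    subgroup before analysis. The paired pAUC comparisons contrast each
    enface index with its thickness counterpart at every sector and AVG.
    """
    if md_threshold is not None:
        table = stats.subgroup_filter(table, md_threshold)
    rng = np.random.default_rng(seed)
    results: dict = {"n_eyes": table.groupby("group")["eye_id"].nunique().to_dict()}

    results["lmm"] = {}
    for measure in MEASURES:
        if measure in table.columns:
            results["lmm"][measure] = dataclasses.asdict(stats.fit_lmm(table, measure))

    posthoc = stats.posthoc_ttests(table)
    results["posthoc"] = posthoc.to_dict(orient="records")

    diag = diagnostic_table(table, B=B, seed=int(rng.integers(2**31)), spec_range=spec_range)
    results["diagnostic_table"] = diag.to_dict(orient="records")

    results["pauc_comparisons"] = []
    for measure, (pretty, counterpart) in MEASURES.items():
        if counterpart is None or counterpart not in table.columns:
            continue
        eye_a = _eye_level(table, measure)
        eye_b = _eye_level(table, counterpart)
        merged = eye_a.merge(eye_b, on=["eye_id", "group"], suffixes=("_a", "_b"))
        labels = (merged["group"] == "glaucoma").to_numpy()
        for unit in list(SECTOR_NAMES) + ["AVG"]:
            a = merged[f"{unit}_a"].to_numpy(dtype=float)
            b = merged[f"{unit}_b"].to_numpy(dtype=float)
            ok = np.isfinite(a) & np.isfinite(b)
            p = stats.compare_paired_auc(
                a[ok], b[ok], labels[ok],
                method=pauc_comparison_method,
                direction="lower",
                spec_range=spec_range,
                B=B,
                seed=int(rng.integers(2**31)),
            )
            results["pauc_comparisons"].append(
                {"measure": pretty, "vs": MEASURES[counterpart][0], "sector": unit, "p": p}
            )

    results["rmcorr"] = {}
    for measure, (pretty, counterpart) in MEASURES.items():
        if counterpart is None:
            continue
        pairs = {"all": table}
        pairs.update({g: sub for g, sub in table.groupby("group")})
        for scope, sub in pairs.items():
            res = stats.rmcorr(sub["eye_id"], sub[measure], sub[counterpart])
            results["rmcorr"][f"{measure}|{scope}"] = dataclasses.asdict(res)

    results["pearson_by_sector"] = {}
    for measure, (pretty, counterpart) in MEASURES.items():
        if counterpart is None:
            continue
        for sector, sub in table.groupby("sector"):
            r, ci, p = stats.pearson_ci(sub[measure], sub[counterpart])
            results["pearson_by_sector"][f"{measure}|{sector}"] = {
                "r": r, "ci_low": ci[0], "ci_high": ci[1], "p": p,
            }

    n_total = int(table["eye_id"].nunique())
    n_group = int(table.groupby("group")["eye_id"].nunique().min())
    results["power"] = {
        "min_detectable_r_all": round(stats.min_detectable_r(n_total), 2) if n_total >= 4 else None,
        "min_detectable_r_group": round(stats.min_detectable_r(n_group), 2) if n_group >= 4 else None,
        "n_all": n_total,
        "n_group": n_group,
    }
    results["config"] = {
        "B": B,
        "seed": seed,
        "spec_range": list(spec_range),
        "md_threshold": md_threshold,
        "pauc_comparison_method": pauc_comparison_method,
        "bonferroni_family": stats.BONFERRONI_FAMILY,
    }
    return results
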