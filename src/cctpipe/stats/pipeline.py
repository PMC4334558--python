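"""The cohort decision flow: reliability, gates, group tests, correlations.

Order of operations mirrors the published analysis: per-side/per-rater ICC;
rater x side ANOVA per group; adoption of the right-side first-rater series
when neither factor matters; normality and homoscedasticity gates choosing
pooled t vs Welch vs Mann-Whitney for the group comparison; a log-transform
branch for the gender x group ANOVA; the RR vs P comparison; the correlation
battery; and the lesion-subsample representativeness checks.  Every result
carries the decision path that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..synth.cohort import COHORT_COLUMNS
from .icc import icc_a1
from .tests import (
    anova_two_way,
    correlation,
    ks_two_sample,
    mann_whitney_u,
    normality_omnibus,
    pooled_t_summary,
    power_two_sample_t,
    variance_homogeneity,
    welch_t_summary,
)
from .types import SummaryStats, TestResult


class SchemaError(ValueError):
    pass


@dataclass(frozen=True)
class AnalysisConfig:
    alpha: float = 0.05
    canonical_rater: str = "r1"
    canonical_side: str = "right"
    power_effect_size: float = 0.5
    subsample_rr: int = 25
    subsample_p: int = 12
    correlates: tuple[str, ...] = ("duration_y", "edss", "onset_age", "age")
    log_transform_if_heteroscedastic: bool = True


def _summary(x: np.ndarray) -> SummaryStats:
    q75, q25 = np.percentile(x, [75, 25])
    return SummaryStats(
        mean=float(np.mean(x)),
        sd=float(np.std(x, ddof=1)),
        n=int(x.size),
        median=float(np.median(x)),
        iqr=float(q75 - q25),
    )


def validate_cohort(cohort: pd.DataFrame) -> None:
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise SchemaError(f"cohort table is missing columns: {missing}")
    bad = [
        c
        for c in COHORT_COLUMNS
        if c.startswith("cct_") and not np.all(np.isfinite(cohort[c].to_numpy(float)))
    ]
    if bad:
        raise SchemaError(f"non-finite CCT values in columns: {bad}")
    groups = set(cohort["group"].unique())
    if groups != {"ms", "control"}:
        raise SchemaError(f"expected groups {{'ms', 'control'}}, got {sorted(groups)}")


def run_full_analysis(cohort: pd.DataFrame, config: AnalysisConfig | None = None) -> dict:
    """Run the complete decision flow on a cohort table.

    Returns a nested dict of :class:`TestResult`/:class:`SummaryStats`
    objects; deterministic given the table and configuration.
    """
    config = config or AnalysisConfig()
    validate_cohort(cohort)
    alpha = config.alpha
    report: dict = {"config": config, "decision_log": []}
    log = report["decision_log"].append

    # --- 1. reliability: ICC per group and side --------------------------
    report["icc"] = {}
    for group in ("control", "ms"):
        sub = cohort[cohort["group"] == group]
        for side in ("right", "left"):
            ratings = sub[[f"cct_r1_{side}", f"cct_r2_{side}"]].to_numpy(float)
            report["icc"][f"{group}_{side}"] = icc_a1(ratings, alpha=alpha)

    # --- 2. rater x side ANOVA per group ---------------------------------
    report["rater_side_anova"] = {}
    rater_or_side_effect = False
    for group in ("control", "ms"):
        sub = cohort[cohort["group"] == group]
        y, raters, sides = [], [], []
        for rater in ("r1", "r2"):
            for side in ("right", "left"):
                vals = sub[f"cct_{rater}_{side}"].to_numpy(float)
                y.append(vals)
                raters.append([rater] * len(vals))
                sides.append([side] * len(vals))
        res = anova_two_way(
            np.concatenate(y),
            np.concatenate(raters),
            np.concatenate(sides),
            names=("rater", "side"),
        )
        report["rater_side_anova"][group] = res
        if any(r.p_value < alpha for r in res.values()):
            rater_or_side_effect = True
    series_col = f"cct_{config.canonical_rater}_{config.canonical_side}"
    if rater_or_side_effect:
        log(
            "rater/side ANOVA found a significant effect; the canonical "
            f"series {series_col} is still used but flagged"
        )
    else:
        log(f"no rater/side effect: analysis proceeds on {series_col}")
    report["canonical_series"] = series_col

    ms = cohort[cohort["group"] == "ms"][series_col].to_numpy(float)
    ctrl = cohort[cohort["group"] == "control"][series_col].to_numpy(float)
    report["summary"] = {"ms": _summary(ms), "control": _summary(ctrl)}

    # --- 3. normality / homoscedasticity gates -> group comparison -------
    norm_ms = normality_omnibus(ms)
    norm_ctrl = normality_omnibus(ctrl)
    homosced = variance_homogeneity(ms, ctrl)
    report["normality"] = {"ms": norm_ms, "control": norm_ctrl}
    report["homoscedasticity"] = homosced
    both_normal = norm_ms.p_value >= alpha and norm_ctrl.p_value >= alpha
    equal_var = homosced.p_value >= alpha

    s_ms, s_ctrl = report["summary"]["ms"], report["summary"]["control"]
    if both_normal and equal_var:
        path = "normality held, homoscedasticity held -> pooled t"
        comp = pooled_t_summary(
            s_ms.mean, s_ms.sd, s_ms.n, s_ctrl.mean, s_ctrl.sd, s_ctrl.n, alpha=alpha
        )
    elif both_normal:
        path = "normality held, homoscedasticity rejected -> Welch/Satterthwaite t"
        comp = welch_t_summary(
            s_ms.mean, s_ms.sd, s_ms.n, s_ctrl.mean, s_ctrl.sd, s_ctrl.n, alpha=alpha
        )
    else:
        path = "normality rejected -> Mann-Whitney"
        comp = mann_whitney_u(ms, ctrl)
    report["group_comparison"] = TestResult(
        name=comp.name,
        statistic=comp.statistic,
        p_value=comp.p_value,
        df=comp.df,
        ci95=comp.ci95,
        estimate=comp.estimate,
        decision_path=path,
        notes=comp.notes,
    )
    log(path)

    report["power"] = power_two_sample_t(
        s_ms.n, s_ctrl.n, config.power_effect_size, alpha=alpha
    )

    # --- 4. gender x group ANOVA (log branch on heteroscedasticity) ------
    cct_all = cohort[series_col].to_numpy(float)
    cells = [
        cohort[(cohort["group"] == g) & (cohort["sex"] == s)][series_col].to_numpy(float)
        for g in ("ms", "control")
        for s in ("M", "F")
    ]
    bf_cells = variance_homogeneity(*cells)
    transformed = False
    y_anova = cct_all
    if (
        bf_cells.p_value < alpha
        and config.log_transform_if_heteroscedastic
        and np.any(cct_all <= 0)
    ):
        log(
            "gender x group cells heteroscedastic but CCT contains "
            "non-positive values; log transform skipped"
        )
    elif bf_cells.p_value < alpha and config.log_transform_if_heteroscedastic:
        y_anova = np.log(cct_all)
        cells_log = [np.log(c) for c in cells]
        bf_after = variance_homogeneity(*cells_log)
        transformed = True
        log(
            "gender x group cells heteroscedastic "
            f"(p={bf_cells.p_value:.3g}); log transform applied "
            f"(after: p={bf_after.p_value:.3g})"
        )
        report["gender_homoscedasticity_after_log"] = bf_after
    report["gender_homoscedasticity"] = bf_cells
    gender_res = anova_two_way(
        y_anova,
        cohort["sex"].to_numpy(str),
        cohort["group"].to_numpy(str),
        names=("gender", "group"),
    )
    for key, r in gender_res.items():
        gender_res[key] = TestResult(
            name=r.name,
            statistic=r.statistic,
            p_value=r.p_value,
            df=r.df,
            decision_path=(
                "log-transformed CCT (heteroscedastic cells)" if transformed else "raw CCT"
            ),
            notes=r.notes,
        )
    report["gender_group_anova"] = gender_res

    # --- 5. RR vs P ------------------------------------------------------
    ms_rows = cohort[cohort["group"] == "ms"]
    rr = ms_rows[ms_rows["subtype"] == "RR"][series_col].to_numpy(float)
    pp = ms_rows[ms_rows["subtype"] == "P"][series_col].to_numpy(float)
    if rr.size and pp.size:
        report["subtype_comparison"] = mann_whitney_u(rr, pp)

    # --- 6. correlations within MS ---------------------------------------
    report["correlations"] = {}
    for var in config.correlates:
        vals = ms_rows[var].to_numpy(float)
        ok = np.isfinite(vals)
        if ok.sum() >= 3 and np.ptp(vals[ok]) > 0:
            report["correlations"][var] = {
                "pearson": correlation(ms[ok], vals[ok], "pearson"),
                "spearman": correlation(ms[ok], vals[ok], "spearman"),
            }

    # --- 7. lesion subsample representativeness --------------------------
    rr_idx = ms_rows.index[ms_rows["subtype"] == "RR"][: config.subsample_rr]
    p_idx = ms_rows.index[ms_rows["subtype"] == "P"][: config.subsample_p]
    sub_idx = rr_idx.append(p_idx)
    if len(sub_idx) >= 3:
        sub_vals = cohort.loc[sub_idx, series_col].to_numpy(float)
        report["subsample"] = {
            "n": int(len(sub_idx)),
            "ks_vs_whole": ks_two_sample(sub_vals, ms),
            "mw_vs_whole": mann_whitney_u(sub_vals, ms),
            "summary": _summary(sub_vals),
        }

    return report


def report_to_jsonable(report: dict) -> dict:
    """Recursively convert a report into plain JSON-serialisable types."""
    def convert(obj):
        if hasattr(obj, "to_dict"):
            return convert(obj.to_dict())
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        if isinstance(obj, AnalysisConfig):
            return convert(vars(obj))
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    return convert(report)
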