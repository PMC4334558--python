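"""Intraclass correlation for inter-rater agreement.

Single-measure, absolute-agreement ICC from a two-way model with subjects as
random rows and raters as fixed columns, with the F-based confidence interval
of McGraw & Wong (1996).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .types import IccResult


class IccError(ValueError):
    pass


def _anova_mean_squares(ratings: np.ndarray) -> tuple[float, float, float, int, int]:
    n, k = ratings.shape
    grand = ratings.mean()
    row_means = ratings.mean(axis=1)
    col_means = ratings.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((ratings - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)
    return msr, msc, mse, n, k


def icc_a1(ratings: np.ndarray, alpha: float = 0.05) -> IccResult:
    """ICC(A,1) with its two-sided ``1 - alpha`` confidence interval.

    ``ratings`` is an ``(n_subjects, k_raters)`` matrix with no missing cells.
    Raises :class:`IccError` when the between-subject variance is zero (the
    coefficient is undefined).
    """
    ratings = np.asarray(ratings, dtype=np.float64)
    if ratings.ndim != 2 or ratings.shape[1] < 2:
        raise IccError("ratings must be (n subjects, k >= 2 raters)")
    if ratings.shape[0] < 2:
        raise IccError("need at least 2 subjects")
    if not np.all(np.isfinite(ratings)):
        raise IccError("ratings contain missing cells")

    msr, msc, mse, n, k = _anova_mean_squares(ratings)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if np.var(ratings.mean(axis=1)) == 0 or denom <= 0:
        raise IccError("zero between-subject variance: ICC undefined")
    icc = (msr - mse) / denom

    if mse == 0 and msc == 0:
        # perfect agreement: degenerate interval
        return IccResult(icc=icc, ci95=(icc, icc), n_subjects=n, n_raters=k)

    # McGraw & Wong F-based interval for ICC(A,1)
    a = (k * icc) / (n * (1.0 - icc)) if icc < 1 else np.inf
    b = 1.0 + (k * icc * (n - 1.0)) / (n * (1.0 - icc)) if icc < 1 else np.inf
    if not np.isfinite(a) or not np.isfinite(b):
        return IccResult(icc=icc, ci95=(icc, icc), n_subjects=n, n_raters=k)
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
    )
    f_lower = stats.f.ppf(1.0 - alpha / 2.0, n - 1.0, v)
    f_upper = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1.0)
    lower = (n * (msr - f_lower * mse)) / (
        f_lower * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = (n * (f_upper * msr - mse)) / (
        k * msc + (k * n - k - n) * mse + n * f_upper * msr
    )
    lower, upper = float(min(lower, icc)), float(max(upper, icc))
    return IccResult(icc=float(icc), ci95=(lower, upper), n_subjects=n, n_raters=k)
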