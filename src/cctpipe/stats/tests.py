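"""The statistical test battery used by the cohort analysis.

Each routine returns a :class:`~cctpipe.stats.types.TestResult`; established
scipy/statsmodels implementations back the standard distributions, while the
decision conventions (U = min(U1, U2), Type-II sums of squares, Satterthwaite
df from summary statistics) are fixed here.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .types import TestResult


def welch_t_summary(
    m1: float,
    s1: float,
    n1: int,
    m2: float,
    s2: float,
    n2: int,
    alpha: float = 0.05,
) -> TestResult:
    """Unequal-variance two-sample t test from summary statistics.

    Degrees of freedom follow the Satterthwaite approximation; the two-sided
    ``1 - alpha`` confidence interval of the mean difference uses the same df.
    """
    if s1 <= 0 or s2 <= 0:
        raise ValueError("standard deviations must be > 0")
    if n1 < 2 or n2 < 2:
        raise ValueError("sample sizes must be >= 2")
    v1, v2 = s1**2 / n1, s2**2 / n2
    se = np.sqrt(v1 + v2)
    diff = m1 - m2
    t = diff / se
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    tc = stats.t.ppf(1.0 - alpha / 2.0, df)
    return TestResult(
        name="welch_t",
        statistic=float(t),
        p_value=float(p),
        df=float(df),
        ci95=(float(diff - tc * se), float(diff + tc * se)),
        estimate=float(diff),
    )


def pooled_t_summary(
    m1: float,
    s1: float,
    n1: int,
    m2: float,
    s2: float,
    n2: int,
    alpha: float = 0.05,
) -> TestResult:
    """Classical equal-variance two-sample t test (df = n1 + n2 - 2)."""
    if s1 <= 0 or s2 <= 0:
        raise ValueError("standard deviations must be > 0")
    if n1 < 2 or n2 < 2:
        raise ValueError("sample sizes must be >= 2")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = m1 - m2
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    tc = stats.t.ppf(1.0 - alpha / 2.0, df)
    return TestResult(
        name="student_t",
        statistic=float(t),
        p_value=float(p),
        df=float(df),
        ci95=(float(diff - tc * se), float(diff + tc * se)),
        estimate=float(diff),
    )


def normality_omnibus(x) -> TestResult:
    """D'Agostino-Pearson K^2 omnibus normality test.

    Requires n >= 20: the moment Z-transforms are unreliable below that.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 20:
        raise ValueError(f"normality omnibus needs n >= 20, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality test undefined")
    k2, p = stats.normaltest(x)
    return TestResult(
        name="dagostino_pearson_k2",
        statistic=float(k2),
        p_value=float(p),
        df=2.0,
    )


def variance_homogeneity(*groups) -> TestResult:
    """Brown-Forsythe test: one-way ANOVA on |x - group median|."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")
    f, p = stats.levene(*arrays, center="median")
    k = len(arrays)
    n = sum(a.size for a in arrays)
    return TestResult(
        name="brown_forsythe",
        statistic=float(f),
        p_value=float(p),
        df=(float(k - 1), float(n - k)),
    )


def anova_two_way(y, factor_a, factor_b, names: tuple[str, str] = ("a", "b")) -> dict:
    """Two-way fixed-effects ANOVA with interaction.

    Balanced designs use the classical closed-form decomposition; unbalanced
    designs fall back to Type-II sums of squares via an OLS fit.  Returns a
    dict with one :class:`TestResult` per effect (A, B, interaction).
    """
    y = np.asarray(y, dtype=np.float64)
    a = np.asarray(factor_a)
    b = np.asarray(factor_b)
    if not (y.shape == a.shape == b.shape):
        raise ValueError("y, factor_a, factor_b must have equal length")
    levels_a, ia = np.unique(a, return_inverse=True)
    levels_b, ib = np.unique(b, return_inverse=True)
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValueError("each factor needs at least 2 levels")
    counts = np.zeros((len(levels_a), len(levels_b)), dtype=int)
    np.add.at(counts, (ia, ib), 1)
    if np.any(counts == 0):
        raise ValueError("every cell needs at least one observation")

    if np.all(counts == counts[0, 0]):
        results = _anova_balanced(y, ia, ib, len(levels_a), len(levels_b), counts[0, 0])
    else:
        results = _anova_type2(y, a, b)
    key_a, key_b = names
    return {
        key_a: results[0],
        key_b: results[1],
        "interaction": results[2],
    }


def _anova_balanced(y, ia, ib, na, nb, r) -> list[TestResult]:
    if r < 2:
        raise ValueError("interaction needs replication (>= 2 per cell)")
    grand = y.mean()
    mean_a = np.array([y[ia == i].mean() for i in range(na)])
    mean_b = np.array([y[ib == j].mean() for j in range(nb)])
    cell = np.zeros((na, nb))
    for i in range(na):
        for j in range(nb):
            cell[i, j] = y[(ia == i) & (ib == j)].mean()
    ss_a = nb * r * float(((mean_a - grand) ** 2).sum())
    ss_b = na * r * float(((mean_b - grand) ** 2).sum())
    ss_ab = r * float(
        ((cell - mean_a[:, None] - mean_b[None, :] + grand) ** 2).sum()
    )
    ss_err = float(((y - cell[ia, ib]) ** 2).sum())
    df_a, df_b = na - 1, nb - 1
    df_ab = df_a * df_b
    df_err = y.size - na * nb
    mse = ss_err / df_err
    out = []
    for name, ss, df in (("A", ss_a, df_a), ("B", ss_b, df_b), ("AxB", ss_ab, df_ab)):
        if mse == 0:
            f = np.inf if ss > 0 else 0.0
            p = 0.0 if ss > 0 else 1.0
        else:
            f = (ss / df) / mse
            p = float(stats.f.sf(f, df, df_err))
        out.append(
            TestResult(
                name=f"anova_{name}",
                statistic=float(f),
                p_value=p,
                df=(float(df), float(df_err)),
                notes={"ss": ss, "balanced": True},
            )
        )
    return out


def _anova_type2(y, a, b) -> list[TestResult]:
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    frame = pd.DataFrame({"y": y, "fa": pd.Categorical(a), "fb": pd.Categorical(b)})
    model = smf.ols("y ~ C(fa) * C(fb)", data=frame).fit()
    table = sm.stats.anova_lm(model, typ=2)
    out = []
    for name, row_key in (("A", "C(fa)"), ("B", "C(fb)"), ("AxB", "C(fa):C(fb)")):
        row = table.loc[row_key]
        out.append(
            TestResult(
                name=f"anova_{name}",
                statistic=float(row["F"]),
                p_value=float(row["PR(>F)"]),
                df=(float(row["df"]), float(table.loc["Residual", "df"])),
                notes={"ss": float(row["sum_sq"]), "balanced": False, "type": "II"},
            )
        )
    return out


def _u_statistics(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n1, n2 = x.size, y.size
    ranks = stats.rankdata(np.concatenate([x, y]))  # midranks on ties
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    return u1, n1 * n2 - u1


def mann_whitney_u(x, y, exact_limit: int = 20) -> TestResult:
    """Mann-Whitney U with midrank ties; U = min(U1, U2).

    Combined samples of at most ``exact_limit`` observations get an exact
    two-sided p by full enumeration of rank assignments (which handles ties
    correctly by construction); larger samples use the tie-corrected normal
    approximation with continuity correction.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    u1, u2 = _u_statistics(x, y)
    u = min(u1, u2)

    if n1 + n2 <= exact_limit:
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        count = 0
        total = 0
        offset = n1 * (n1 + 1) / 2.0
        for idx in combinations(range(n1 + n2), n1):
            r1 = ranks[list(idx)].sum()
            u1_perm = r1 - offset
            if min(u1_perm, n1 * n2 - u1_perm) <= u + 1e-9:
                count += 1
            total += 1
        p = count / total
        method = "exact_enumeration"
    else:
        _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
        n = n1 + n2
        tie_term = (counts**3 - counts).sum() / (n * (n - 1.0))
        sigma2 = n1 * n2 / 12.0 * ((n + 1.0) - tie_term)
        if sigma2 <= 0:
            p = 1.0
        else:
            mu = n1 * n2 / 2.0
            z = (u + 0.5 - mu) / np.sqrt(sigma2)  # continuity-corrected
            p = min(1.0, 2.0 * stats.norm.cdf(z))
        method = "normal_tie_corrected"
    return TestResult(
        name="mann_whitney_u",
        statistic=float(u),
        p_value=float(p),
        notes={"u1": float(u1), "u2": float(u2), "method": method},
    )


def ks_two_sample(x, y) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(x, y, method="asymp")
    return TestResult(
        name="ks_two_sample", statistic=float(res.statistic), p_value=float(res.pvalue)
    )


def correlation(x, y, method: str = "pearson") -> TestResult:
    """Pearson r or Spearman rho with the t-approximation p-value."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(
        name=f"{method}_correlation",
        statistic=float(r),
        p_value=float(p),
        df=float(x.size - 2),
    )


def power_two_sample_t(n1: int, n2: int, effect_size_d: float, alpha: float = 0.05) -> float:
    """Power of the two-sided two-sample t test via the noncentral t.

    Noncentrality is ``d * sqrt(n1 n2 / (n1 + n2))`` on ``n1 + n2 - 2`` df.
    """
    if effect_size_d < 0:
        raise ValueError("effect_size_d must be >= 0")
    df = n1 + n2 - 2
    ncp = effect_size_d * np.sqrt(n1 * n2 / (n1 + n2))
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    power = 1.0 - (stats.nct.cdf(tcrit, df, ncp) - stats.nct.cdf(-tcrit, df, ncp))
    return float(power)
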