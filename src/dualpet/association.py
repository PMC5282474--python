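"""Terminal-biomarker statistics and design-stage planning.

Covers the cross-sectional inference layer: one-way ANOVA with Tukey HSD
post-hoc contrasts across age groups, Lilliefors-style normality screening,
Pearson correlations between imaging endpoints and fluid biomarkers,
age-adjusted multiple regression with standardized coefficients,
standardized-difference timelines against a linearly-aging wild-type
baseline, and two-sample t-test group-size planning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "AnovaTukeyResult",
    "AssociationResult",
    "StandardizedDifferenceSeries",
    "anova_tukey",
    "ks_normality",
    "pearson",
    "fit_regression",
    "pooled_sd",
    "standardized_difference_series",
    "group_size",
]


@dataclass
class AnovaTukeyResult:
    """One-way ANOVA omnibus test plus Tukey HSD pairwise contrasts."""

    f: float
    p: float
    df_between: int
    df_within: int
    pairwise: pd.DataFrame  # group_a, group_b, mean_diff, p_adj


def anova_tukey(values: np.ndarray, groups: np.ndarray) -> AnovaTukeyResult:
    """Compare group means by one-way ANOVA with Tukey HSD post-hoc p-values."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in levels]
    for g, s in zip(levels, samples):
        if len(s) < 2:
            raise ValueError(f"group {g!r} has n < 2")
    f, p = stats.f_oneway(*samples)
    hsd = stats.tukey_hsd(*samples)
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            rows.append(
                {
                    "group_a": levels[i],
                    "group_b": levels[j],
                    "mean_diff": float(samples[i].mean() - samples[j].mean()),
                    "p_adj": float(hsd.pvalue[i, j]),
                }
            )
    return AnovaTukeyResult(
        f=float(f),
        p=float(p),
        df_between=len(levels) - 1,
        df_within=sum(len(s) for s in samples) - len(levels),
        pairwise=pd.DataFrame(rows),
    )


def ks_normality(values: np.ndarray) -> float:
    """Normality screen: Kolmogorov-Smirnov with estimated parameters.

    Because no reference distribution is available, the Lilliefors variant
    is used (normal with the sample's own mean and SD), which keeps the
    test honest about the estimated parameters.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need n >= 3 for the normality test")
    if np.std(values, ddof=1) == 0:
        raise ValueError("degenerate constant sample")
    _, p = lilliefors(values, dist="norm", pvalmethod="table")
    return float(p)


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the samples")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class AssociationResult:
    """Standardized OLS fit: per-predictor beta and p, R^2, overall F."""

    outcome: str
    predictors: tuple[str, ...]
    beta: dict[str, float]
    p_values: dict[str, float]
    r_squared: float
    adj_r_squared: float
    f_statistic: float
    df_model: int
    df_resid: int


def fit_regression(
    data: pd.DataFrame, outcome: str, predictors: list[str]
) -> AssociationResult:
    """OLS on z-scored outcome and predictors (standardized coefficients).

    Standardization uses the sample SD (n-1), so the betas are dimensionless
    and, with a single predictor, beta^2 = R^2.
    """
    import statsmodels.api as sm

    cols = [outcome, *predictors]
    df = data[cols].astype(float).dropna()
    n = len(df)
    if n <= len(predictors) + 1:
        raise ValueError(f"n = {n} too small for {len(predictors)} predictors")
    sds = df.std(ddof=1)
    zero_var = [c for c in cols if sds[c] == 0]
    if zero_var:
        raise ValueError(f"zero-variance columns: {zero_var}")
    z = (df - df.mean()) / sds
    x = sm.add_constant(z[predictors].to_numpy())
    if np.linalg.matrix_rank(x) < x.shape[1]:
        corr = z[predictors].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        pairs = [
            (a, b)
            for a in predictors
            for b in predictors
            if a < b and corr.loc[a, b] > 1 - 1e-10
        ]
        raise ValueError(f"rank-deficient design; collinear predictors: {pairs or predictors}")
    fit = sm.OLS(z[outcome].to_numpy(), x).fit()
    return AssociationResult(
        outcome=outcome,
        predictors=tuple(predictors),
        beta={p: float(fit.params[i + 1]) for i, p in enumerate(predictors)},
        p_values={p: float(fit.pvalues[i + 1]) for i, p in enumerate(predictors)},
        r_squared=float(fit.rsquared),
        adj_r_squared=float(fit.rsquared_adj),
        f_statistic=float(fit.fvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
    )


def pooled_sd(sd1: float, n1: int, sd2: float, n2: int) -> float:
    """Combined standard deviation of two groups (pooled, n-1 weighting)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    return math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))


@dataclass
class StandardizedDifferenceSeries:
    """Unitless TG-vs-WT effect timeline for one measure."""

    measure: str
    table: pd.DataFrame  # age_months, tg_mean, wt_interp, sd_used, d


def standardized_difference_series(
    tg_summary: pd.DataFrame,
    wt_points: tuple[tuple[float, float], tuple[float, float]],
    measure: str = "",
    pool_ages: tuple[float, float] | None = None,
) -> StandardizedDifferenceSeries:
    """Standardized TG-WT differences assuming linear wild-type aging.

    For each TG age ``a``: ``d(a) = (mean_TG(a) - wt_interp(a)) / SD_TG(a)``
    where ``wt_interp`` is the straight line through the two wild-type
    ``(age, mean)`` anchor points (extrapolated when a TG age lies outside
    them). ``pool_ages`` marks two TG ages whose groups share a pooled SD —
    used when one group's own SD is degenerately small.

    ``tg_summary`` needs columns ``age_months, mean, sd, n``.
    """
    (a1, m1), (a2, m2) = wt_points
    if a1 == a2:
        raise ValueError("wild-type anchor ages must differ")
    slope = (m2 - m1) / (a2 - a1)

    tg = tg_summary.sort_values("age_months").reset_index(drop=True)
    sd_used = tg["sd"].astype(float).copy()
    if pool_ages is not None:
        pa, pb = pool_ages
        ia = tg.index[tg["age_months"] == pa]
        ib = tg.index[tg["age_months"] == pb]
        if len(ia) != 1 or len(ib) != 1:
            raise ValueError(f"pool_ages {pool_ages} not found among TG ages")
        pooled = pooled_sd(
            float(tg.loc[ia[0], "sd"]),
            int(tg.loc[ia[0], "n"]),
            float(tg.loc[ib[0], "sd"]),
            int(tg.loc[ib[0], "n"]),
        )
        sd_used.iloc[[ia[0], ib[0]]] = pooled

    rows = []
    for idx, row in tg.iterrows():
        sd = float(sd_used.iloc[idx])
        if sd <= 0:
            raise ValueError(
                f"SD at age {row.age_months} is {sd}; use pool_ages to pool a degenerate group"
            )
        wt_interp = m1 + slope * (float(row.age_months) - a1)
        rows.append(
            {
                "age_months": float(row.age_months),
                "tg_mean": float(row["mean"]),
                "wt_interp": wt_interp,
                "sd_used": sd,
                "d": (float(row["mean"]) - wt_interp) / sd,
            }
        )
    return StandardizedDifferenceSeries(measure=measure, table=pd.DataFrame(rows))


def _ttest_power(n: int, d: float, alpha: float) -> float:
    df = 2 * n - 2
    tcrit = stats.t.isf(alpha / 2.0, df)
    nc = d * math.sqrt(n / 2.0)
    upper = float(stats.nct.sf(tcrit, df, nc))
    lower = float(stats.nct.cdf(-tcrit, df, nc))
    if math.isnan(lower):  # negligible lower-tail mass at large noncentrality
        lower = 0.0
    return upper + lower


def group_size(alpha: float, power: float, effect_size_d: float, n_max: int = 10**6) -> int:
    """Smallest per-group n giving the requested power for a two-sided,
    two-sample t-test at standardized effect size d (noncentral-t exact)."""
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    if effect_size_d <= 0:
        raise ValueError("effect size d must be > 0")
    for n in range(2, n_max + 1):
        if _ttest_power(n, effect_size_d, alpha) >= power:
            return n
    raise ValueError(f"requested power not attainable with n <= {n_max}")
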