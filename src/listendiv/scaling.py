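"""Descriptive scaling statistics: diversity-size correlations with Holm
correction, smooth (GAM) trends, country contrasts (ANOVA / Tukey / Cohen's
d), bootstrapped age trajectories, and per-quantile demographic regressions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.gam.api import BSplines, GLMGam
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationResult",
    "correlate",
    "holm_adjust",
    "correlation_family",
    "SmoothFit",
    "smooth_trend",
    "GroupComparison",
    "group_compare",
    "cohens_d",
    "age_trajectory",
    "population_quantile_groups",
    "quantile_regression_r2",
]


@dataclass(frozen=True)
class CorrelationResult:
    name: str
    method: str
    r: float
    ci_low: float
    ci_high: float
    p: float
    p_adjusted: float | None
    n: int


def _fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    if n <= 3 or abs(r) >= 1.0:
        return (np.nan, np.nan)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zc = stats.norm.ppf(0.5 + level / 2)
    return float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se))


def correlate(
    x,
    y,
    method: str = "pearson",
    ci: str = "fisher",
    n_boot: int = 1000,
    seed: int = 0,
    name: str = "",
) -> CorrelationResult:
    """Two-tailed correlation with a 95% CI (Fisher-z or bootstrap).

    The p-value is unadjusted; use :func:`correlation_family` to apply the
    Holm correction across a family of tests.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    if ci == "fisher":
        lo, hi = _fisher_ci(float(r), x.size)
    elif ci == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, x.size, x.size)
            if method == "pearson":
                reps[b] = stats.pearsonr(x[idx], y[idx])[0]
            else:
                reps[b] = stats.spearmanr(x[idx], y[idx])[0]
        lo, hi = np.percentile(reps, [2.5, 97.5])
    else:
        raise ValueError("ci must be 'fisher' or 'bootstrap'")
    return CorrelationResult(
        name=name,
        method=method,
        r=float(r),
        ci_low=float(lo),
        ci_high=float(hi),
        p=float(p),
        p_adjusted=None,
        n=int(x.size),
    )


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values for a family of tests."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="holm")[1]


def correlation_family(
    pairs: dict[str, tuple], method: str = "pearson", **kwargs
) -> pd.DataFrame:
    """Correlations for a named family of (x, y) pairs, Holm-adjusted
    jointly across the family."""
    results = [correlate(x, y, method=method, name=k, **kwargs) for k, (x, y) in pairs.items()]
    adj = holm_adjust([r.p for r in results])
    rows = []
    for res, pa in zip(results, adj):
        rows.append(
            {
                "name": res.name,
                "method": res.method,
                "r": res.r,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p": res.p,
                "p_adjusted": float(pa),
                "n": res.n,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SmoothFit:
    """A fitted smooth trend with a pointwise 95% band on a grid."""

    grid: np.ndarray
    fitted: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    kind: str  # "spline" or "linear"
    alpha: float | None  # selected penalty weight (spline only)

    def predict(self, x_new) -> np.ndarray:
        return np.interp(np.asarray(x_new, dtype=float), self.grid, self.fitted)


def smooth_trend(
    x, y, df: int = 8, degree: int = 3, n_grid: int = 100
) -> SmoothFit:
    """Penalised cubic-spline trend of ``y`` on ``x``.

    The penalty weight is selected by generalised cross-validation.  With
    too few points for the basis the fit falls back to a straight line with
    a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    grid = np.linspace(x.min(), x.max(), n_grid)

    def _linear(reason: str) -> SmoothFit:
        warnings.warn(f"{reason}; falling back to a linear fit", stacklevel=3)
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        pred = fit.get_prediction(sm.add_constant(grid)).summary_frame(alpha=0.05)
        return SmoothFit(
            grid=grid,
            fitted=pred["mean"].to_numpy(),
            ci_low=pred["mean_ci_lower"].to_numpy(),
            ci_high=pred["mean_ci_upper"].to_numpy(),
            kind="linear",
            alpha=None,
        )

    if x.size < df + 2 or np.unique(x).size <= degree + 1:
        return _linear("too few points for the spline basis")
    bs = BSplines(x[:, None], df=[df], degree=[degree])
    model = GLMGam(y, exog=np.ones((x.size, 1)), smoother=bs, alpha=1.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit()  # initialises the scale used by the GCV search
            alpha = float(model.select_penweight()[0][0])
            res = GLMGam(y, exog=np.ones((x.size, 1)), smoother=bs, alpha=alpha).fit()
    except Exception:  # e.g. an exactly-interpolated (noise-free) response
        return _linear("spline fit degenerate on this response")
    basis = bs.transform(grid[:, None])
    design = np.column_stack([np.ones(n_grid), basis])
    mean = design @ res.params
    cov = res.cov_params()
    se = np.sqrt(np.einsum("ij,jk,ik->i", design, cov, design))
    zc = stats.norm.ppf(0.975)
    return SmoothFit(
        grid=grid,
        fitted=mean,
        ci_low=mean - zc * se,
        ci_high=mean + zc * se,
        kind="spline",
        alpha=alpha,
    )


def cohens_d(a, b) -> float:
    """Pooled-SD Cohen's d between two samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    sp = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if sp == 0:
        return 0.0
    return float((a.mean() - b.mean()) / sp)


@dataclass
class GroupComparison:
    f_stat: float
    df_between: int
    df_within: int
    p: float
    tukey: pd.DataFrame  # pairwise adjusted p-values and mean differences
    effect_sizes: pd.DataFrame  # pairwise Cohen's d


def group_compare(values, groups) -> GroupComparison:
    """One-way ANOVA across groups with Tukey-HSD post-hoc contrasts and
    pooled-SD Cohen's d per pair."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if levels.size < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == g] for g in levels]
    f_stat, p = stats.f_oneway(*samples)
    tk = pairwise_tukeyhsd(values, groups)
    tukey = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    rows = []
    for i in range(levels.size):
        for j in range(i + 1, levels.size):
            rows.append(
                {
                    "group1": levels[i],
                    "group2": levels[j],
                    "cohens_d": cohens_d(samples[i], samples[j]),
                }
            )
    return GroupComparison(
        f_stat=float(f_stat),
        df_between=levels.size - 1,
        df_within=values.size - levels.size,
        p=float(p),
        tukey=tukey,
        effect_sizes=pd.DataFrame(rows),
    )


def age_trajectory(
    ages,
    wid,
    bin_width: int = 5,
    n_users: int = 100,
    n_reps: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, float]:
    """Bootstrapped mean WID across ``bin_width``-year age bins.

    Per bin, each replicate draws ``n_users`` distinct users and averages
    their WID; bins with fewer than ``n_users`` users are dropped with a
    warning.  Returns the per-bin table and the left edge of the argmax bin.
    """
    ages = np.asarray(ages, dtype=float)
    wid = np.asarray(wid, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bins = (np.floor(ages / bin_width) * bin_width).astype(int)
    rows = []
    for b in np.unique(bins):
        vals = wid[bins == b]
        if vals.size < n_users:
            warnings.warn(
                f"age bin [{b}, {b + bin_width}) has {vals.size} < {n_users} users; dropped",
                stacklevel=2,
            )
            continue
        means = np.empty(n_reps)
        for r in range(n_reps):
            means[r] = vals[rng.choice(vals.size, n_users, replace=False)].mean()
        lo, hi = np.percentile(means, [2.5, 97.5])
        rows.append(
            {
                "age_bin": b,
                "mean": means.mean(),
                "ci_low": lo,
                "ci_high": hi,
                "n_users": vals.size,
            }
        )
    if not rows:
        raise ValueError("no age bin holds enough users")
    table = pd.DataFrame(rows)
    peak = float(table.loc[table["mean"].idxmax(), "age_bin"])
    return table, peak


def population_quantile_groups(
    populations, n_groups: int = 3, labels=("small", "medium", "large")
) -> pd.Series:
    """Partition areas into population-size groups of (near-)equal counts.

    Areas are ranked by population; remainder areas go to the lower groups.
    """
    populations = pd.Series(populations)
    if len(labels) != n_groups:
        raise ValueError("labels must match n_groups")
    order = populations.sort_values(kind="stable").index
    n = len(order)
    base, rem = divmod(n, n_groups)
    sizes = [base + (1 if i < rem else 0) for i in range(n_groups)]
    assignments = np.repeat(np.arange(n_groups), sizes)
    out = pd.Series(
        pd.Categorical.from_codes(assignments, categories=list(labels), ordered=True),
        index=order,
    ).reindex(populations.index)
    out.name = "size_group"
    return out


def quantile_regression_r2(
    table: pd.DataFrame,
    outcome_cols,
    covariate_cols,
    group_col: str = "size_group",
) -> pd.DataFrame:
    """Adjusted R-squared of each outcome regressed (OLS) on all demographic
    covariates, separately within each population-size group."""
    rows = []
    for g, sub in table.groupby(group_col, observed=True):
        X = sm.add_constant(sub[list(covariate_cols)].astype(float))
        for out in outcome_cols:
            fit = sm.OLS(sub[out].astype(float), X).fit()
            rows.append(
                {"size_group": g, "outcome": out, "adj_r2": float(fit.rsquared_adj), "n": len(sub)}
            )
    return pd.DataFrame(rows)
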