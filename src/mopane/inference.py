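"""Statistical procedures used by the woodland analyses, with explicit contracts.

Thin, contract-checked wrappers around scipy/statsmodels: paired and Welch
t-tests, Pearson chi-square on contingency tables, two-way ANOVA with
Type II sums of squares, Tukey HSD from summary statistics, Benjamini-
Hochberg step-up adjustment, binary logistic regression, three-parameter
logistic (sigmoid) curve fitting by least squares, and ordinary least
squares.  Every result records the scale transform that was applied to the
response (none, log10 or log_e) so downstream tables stay auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import optimize, stats
from statsmodels.stats.anova import anova_lm

__all__ = [
    "TestResult",
    "FitResult",
    "SeparationError",
    "paired_t",
    "welch_t",
    "chisq_contingency",
    "two_way_anova",
    "tukey_hsd",
    "bh_adjust",
    "logistic_glm_fit",
    "logistic_curve_fit",
    "linear_fit",
]

#: p-values smaller than this are additionally reported as a printed bound.
_P_FLOOR = 2.2e-16

TRANSFORMS = ("none", "log10", "log_e")


class SeparationError(RuntimeError):
    """Raised when a logistic regression is perfectly separated."""


def _apply_transform(x: np.ndarray, transform: str) -> np.ndarray:
    if transform == "none":
        return x
    if transform == "log10":
        return np.log10(x)
    if transform == "log_e":
        return np.log(x)
    raise ValueError(f"unknown transform {transform!r}; use one of {TRANSFORMS}")


def _p_label(p: float) -> str:
    return f"<{_P_FLOOR:g}" if p < _P_FLOOR else format(p, ".4g")


@dataclass(frozen=True)
class TestResult:
    """A test statistic with its degrees of freedom and p-value."""

    statistic: float
    df: float
    p_value: float
    method: str
    transform: str = "none"

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    @property
    def p_label(self) -> str:
        return _p_label(self.p_value)


@dataclass(frozen=True)
class FitResult:
    """Coefficients, standard errors and fit statistics for a model fit."""

    model: str
    params: dict
    se: dict
    n_used: int
    n_excluded: int = 0
    adj_r2: float | None = None
    f_stat: float | None = None
    f_df: tuple | None = None
    p_values: dict = field(default_factory=dict)
    converged: bool = True
    transform: str = "none"

    def __post_init__(self):
        if self.adj_r2 is not None and self.adj_r2 > 1.0 + 1e-12:
            raise ValueError("adjusted R^2 cannot exceed 1")


def paired_t(x: Sequence[float], y: Sequence[float], transform: str = "none") -> TestResult:
    """Classical paired t-test on matched per-plot values.

    The transform is applied to both series before differencing.  Zero
    variance of the differences (including x == y elementwise with any
    nonzero mean shift) has no defined t and raises.
    """
    x = _apply_transform(np.asarray(x, dtype=float), transform)
    y = _apply_transform(np.asarray(y, dtype=float), transform)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("paired_t needs two equal-length 1-d samples with n >= 2")
    d = x - y
    if np.allclose(d, d[0]) and not np.allclose(d, 0.0):
        raise ValueError("differences have zero variance; t is undefined")
    res = stats.ttest_rel(x, y)
    t = float(res.statistic)
    if np.isnan(t):  # identical pairs: zero mean difference, zero variance
        t = 0.0
        p = 1.0
    else:
        p = float(res.pvalue)
    return TestResult(statistic=t, df=len(x) - 1, p_value=p, method="paired t", transform=transform)


def welch_t(x: Sequence[float], y: Sequence[float], transform: str = "none") -> TestResult:
    """Welch's unequal-variance t-test with Welch-Satterthwaite df."""
    x = _apply_transform(np.asarray(x, dtype=float), transform)
    y = _apply_transform(np.asarray(y, dtype=float), transform)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("welch_t needs n >= 2 in each group")
    if np.allclose(x, x[0]) and np.allclose(y, y[0]):
        if np.isclose(x[0], y[0]):
            # identical constant groups: no evidence of difference
            return TestResult(0.0, len(x) + len(y) - 2, 1.0, "Welch t", transform)
        raise ValueError("both groups constant; t is undefined")
    res = stats.ttest_ind(x, y, equal_var=False)
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
    return TestResult(
        statistic=float(res.statistic),
        df=float(df),
        p_value=float(res.pvalue),
        method="Welch t",
        transform=transform,
    )


def chisq_contingency(counts) -> TestResult:
    """Pearson chi-square test of independence on an r x c count table."""
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2:
        raise ValueError("counts must be a 2-d table")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("table has an all-zero row or column")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return TestResult(statistic=float(chi2), df=int(df), p_value=float(p), method="chi-square")


def two_way_anova(
    response: Sequence[float],
    factor_a: Sequence,
    factor_b: Sequence,
    include_interaction: bool = True,
    transform: str = "none",
    ss_type: int = 2,
) -> pd.DataFrame:
    """Two-way ANOVA table with Type II (default) or Type I sums of squares.

    Returns a tidy frame with columns term, sum_sq, df, F, p in model-term
    order.  ``include_interaction=False`` fits main effects only, for
    designs whose residual degrees of freedom cannot support the
    interaction.
    """
    y = _apply_transform(np.asarray(response, dtype=float), transform)
    df = pd.DataFrame({"y": y, "A": list(factor_a), "B": list(factor_b)})
    if df.isna().any().any():
        raise ValueError("two_way_anova requires complete cases")
    formula = "y ~ C(A) + C(B)" + (" + C(A):C(B)" if include_interaction else "")
    fit = smf.ols(formula, data=df).fit()
    if fit.df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    if np.allclose(y, y[0]):
        raise ValueError("response is constant; F undefined")
    table = anova_lm(fit, typ=ss_type)
    out = table.reset_index().rename(
        columns={"index": "term", "PR(>F)": "p", "df": "df", "sum_sq": "sum_sq"}
    )
    out["term"] = (
        out["term"]
        .str.replace("C(A)", "A", regex=False)
        .str.replace("C(B)", "B", regex=False)
        .str.replace("A:B", "A:B", regex=False)
        .str.replace("Residual", "residual", regex=False)
    )
    return out[["term", "sum_sq", "df", "F", "p"]]


def tukey_hsd(
    group_means: Sequence[float],
    mse: float,
    n_per_group: int | Sequence[int],
    df_resid: float | None = None,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons from summary statistics.

    ``mse`` is the ANOVA residual mean square on the analysis scale and
    ``n_per_group`` the per-group sample size(s) (Tukey-Kramer when
    unequal).  ``df_resid`` defaults to the balanced one-way value
    ``k * (n - 1)``.  Adjusted p-values come from the studentized range
    distribution with k groups.
    """
    means = np.asarray(group_means, dtype=float)
    k = len(means)
    if k < 2:
        raise ValueError("need at least two groups")
    if mse < 0:
        raise ValueError("mse must be >= 0")
    ns = np.full(k, n_per_group) if np.isscalar(n_per_group) else np.asarray(n_per_group)
    if df_resid is None:
        if not np.all(ns == ns[0]):
            raise ValueError("df_resid must be given for unequal group sizes")
        df_resid = k * (ns[0] - 1)
    labels = list(labels) if labels is not None else [str(i) for i in range(k)]
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[j] - means[i]
            se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            if se == 0:
                q = 0.0 if diff == 0 else np.inf
            else:
                q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, df_resid))
            rows.append(
                {
                    "group_1": labels[i],
                    "group_2": labels[j],
                    "mean_diff": diff,
                    "q": q,
                    "p_adj": min(p, 1.0),
                }
            )
    return pd.DataFrame(rows)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-d sequence")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def logistic_glm_fit(
    outcome: Sequence[int], predictor: Sequence[float], predictor_name: str = "x"
) -> FitResult:
    """Maximum-likelihood binary logistic regression on one predictor.

    Raises :class:`SeparationError` on complete separation rather than
    returning silently divergent coefficients.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(set(y)) < 2:
        raise ValueError("both outcome classes must be present")
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception as exc:  # PerfectSeparation{Error,Warning}, overflow
            if "separat" in str(exc).lower() or "Separation" in type(exc).__name__:
                raise SeparationError("complete separation: MLE does not exist") from exc
            raise
    if not fit.mle_retvals.get("converged", False) or np.any(~np.isfinite(fit.bse)):
        raise SeparationError("logistic regression failed to converge (separation?)")
    names = ["intercept", predictor_name]
    return FitResult(
        model="logit-linear GLM",
        params=dict(zip(names, map(float, fit.params))),
        se=dict(zip(names, map(float, fit.bse))),
        p_values=dict(zip(names, map(float, fit.pvalues))),
        n_used=len(y),
        converged=bool(fit.mle_retvals.get("converged", True)),
    )


def _logistic3(x, A, k, x0):
    from scipy.special import expit

    return A * expit(k * (x - x0))


def logistic_curve_fit(
    x: Sequence[float],
    y: Sequence[float],
    exclude: Sequence[int] = (),
    start: tuple[float, float, float] | None = None,
) -> FitResult:
    """Least-squares fit of the 3-parameter logistic y = A/(1+exp(-k(x-x0))).

    ``exclude`` is an explicit caller-supplied set of point indices to drop
    (never an automatic outlier rule).  Starting values default to
    A0 = max(y), x0 = median(x) and k0 from the slope between the 25% and
    75% response quantiles.  The fit is scale-agnostic in x; callers record
    which scale (fraction or percent) they supplied.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    exclude = sorted(set(int(i) for i in exclude))
    if any(i < 0 or i >= len(x) for i in exclude):
        raise ValueError("exclude indices out of range")
    mask = np.ones(len(x), dtype=bool)
    mask[exclude] = False
    xs, ys = x[mask], y[mask]
    n = len(xs)
    if n <= 3:
        raise ValueError("need more than 3 points after exclusions")
    if np.allclose(ys, ys[0]):
        raise ValueError("response is flat; logistic parameters are degenerate")

    if start is None:
        A0 = float(np.max(ys))
        x00 = float(np.median(xs))
        q25, q75 = np.quantile(ys, [0.25, 0.75])
        lo = xs[np.argmin(np.abs(ys - q25))]
        hi = xs[np.argmin(np.abs(ys - q75))]
        with np.errstate(divide="ignore", invalid="ignore"):
            k0 = (np.log(3.0) * 2.0) / (hi - lo) if hi != lo else 1.0
        start = (A0, float(k0), x00)
    try:
        popt, pcov = optimize.curve_fit(_logistic3, xs, ys, p0=start, maxfev=20_000)
    except RuntimeError as exc:
        raise RuntimeError(f"logistic curve fit did not converge (start={start})") from exc
    resid = ys - _logistic3(xs, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((ys - ys.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    p = 3
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    se = np.sqrt(np.diag(pcov))
    names = ["A", "k", "x0"]
    return FitResult(
        model="3-parameter logistic curve",
        params=dict(zip(names, map(float, popt))),
        se=dict(zip(names, map(float, se))),
        n_used=n,
        n_excluded=len(exclude),
        adj_r2=float(adj_r2),
    )


def linear_fit(x: Sequence[float], y: Sequence[float], transform: str = "none") -> FitResult:
    """Ordinary least squares y = a + b x with F test and adjusted R²."""
    x = np.asarray(x, dtype=float)
    y = _apply_transform(np.asarray(y, dtype=float), transform)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("linear_fit needs equal-length samples with n >= 3")
    if np.allclose(x, x[0]):
        raise ValueError("x is constant; slope undefined")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    names = ["intercept", "slope"]
    return FitResult(
        model="linear",
        params=dict(zip(names, map(float, fit.params))),
        se=dict(zip(names, map(float, fit.bse))),
        p_values=dict(zip(names, map(float, fit.pvalues))),
        n_used=len(x),
        adj_r2=float(fit.rsquared_adj),
        f_stat=float(fit.fvalue),
        f_df=(int(fit.df_model), int(fit.df_resid)),
        transform=transform,
    )
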