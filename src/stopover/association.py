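"""Demographic and migration statistics: AICc model sets, Welch t-tests,
Scheirer-Ray-Hare, chi-square, Pearson correlations, and alpha-diversity
associations, with explicit multiple-testing families.

Two-sample comparisons use the unequal-variance (Welch) form with
Satterthwaite degrees of freedom throughout.  Model selection over ordinary
least-squares fits uses AICc with the residual variance counted as a
parameter; models within 2 AICc of the best form the supported set.
Adjusted p-values within a declared family use Benjamini-Hochberg.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.anova import anova_lm

from .diff_abundance import bh_adjust


@dataclasses.dataclass
class TestResult:
    name: str
    statistic: float
    df: float
    p: float
    p_adj: float | None = None
    direction: float = 0.0
    extra: dict = dataclasses.field(default_factory=dict)


def fit_model_set(
    data: pd.DataFrame,
    response: str,
    formulas: list[str],
    scale_numeric: bool = True,
) -> pd.DataFrame:
    """OLS fits per formula ranked by AICc.

    AICc = -2 logLik + 2k + 2k(k+1)/(n-k-1) with k counting coefficients plus
    the residual variance.  Numeric explanatory columns are standardized to
    mean 0, sd 1 before fitting; models without enough residual degrees of
    freedom for AICc are dropped with a warning.
    """
    df = data.copy()
    if scale_numeric:
        for col in df.columns:
            if col != response and pd.api.types.is_numeric_dtype(df[col]):
                sd = df[col].std(ddof=1)
                if sd > 0:
                    df[col] = (df[col] - df[col].mean()) / sd
    rows = []
    for formula in formulas:
        fit = smf.ols(formula, data=df).fit()
        n = int(fit.nobs)
        k = len(fit.params) + 1  # + residual variance
        if n - k - 1 <= 0:
            warnings.warn(f"model {formula!r} dropped: AICc undefined at n={n}, k={k}")
            continue
        aicc = -2.0 * fit.llf + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)
        rows.append({"formula": formula, "k": k, "n": n, "aicc": aicc, "llf": fit.llf})
    if not rows:
        raise ValueError("no fittable models")
    out = pd.DataFrame(rows).sort_values("aicc", kind="stable").reset_index(drop=True)
    out["delta_aicc"] = out["aicc"] - out["aicc"].min()
    rel = np.exp(-0.5 * out["delta_aicc"])
    out["weight"] = rel / rel.sum()
    out["in_best_set"] = out["delta_aicc"] < 2.0
    return out


def welch_t(x, y, name: str = "welch_t") -> TestResult:
    """Unequal-variance two-sample t-test with Satterthwaite df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least two observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    diff = x.mean() - y.mean()
    denom2 = vx / nx + vy / ny
    if denom2 == 0:
        if diff == 0:
            return TestResult(name, 0.0, float(nx + ny - 2), 1.0)
        raise ValueError("zero variance in both groups with unequal means")
    t = diff / np.sqrt(denom2)
    df = denom2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(name, float(t), float(df), float(p), direction=float(np.sign(diff)))


def scheirer_ray_hare(data: pd.DataFrame, response: str, factor_a: str, factor_b: str) -> dict:
    """Nonparametric two-way test on ranks.

    The pooled response is midranked; two-way ANOVA sums of squares on the
    ranks give H = SS_term / MS_total per term, referred to chi-square with
    the term's degrees of freedom.  Midranking makes the total mean square
    self-correcting for ties.  With one factor collapsed to a single level
    the statistic reduces to Kruskal-Wallis for the other factor.
    """
    df = data[[response, factor_a, factor_b]].dropna().copy()
    ranks = stats.rankdata(df[response])
    df["_rank"] = ranks
    n = len(df)
    ms_total = float(((ranks - ranks.mean()) ** 2).sum()) / (n - 1)
    out: dict[str, TestResult] = {}
    if ms_total == 0:
        for term in (factor_a, factor_b, f"{factor_a}:{factor_b}"):
            out[term] = TestResult(term, 0.0, 0.0, 1.0)
        return out
    levels_a = df[factor_a].nunique()
    levels_b = df[factor_b].nunique()
    if min(levels_a, levels_b) < 2:
        # degenerate design: one-way Kruskal-Wallis on the varying factor
        factor = factor_a if levels_a >= 2 else factor_b
        grand = ranks.mean()
        ss = sum(
            (df[factor] == lev).sum() * (df.loc[df[factor] == lev, "_rank"].mean() - grand) ** 2
            for lev in df[factor].unique()
        )
        h = ss / ms_total
        dof = df[factor].nunique() - 1
        out[factor] = TestResult(factor, float(h), float(dof), float(stats.chi2.sf(h, dof)))
        return out
    cells = df.groupby([factor_a, factor_b], observed=True).size()
    if (cells == 0).any() or len(cells) < levels_a * levels_b:
        raise ValueError("empty cell in the two-way design")
    fit = smf.ols(f"_rank ~ C({factor_a}) * C({factor_b})", data=df).fit()
    table = anova_lm(fit, typ=2)
    label = {
        f"C({factor_a})": factor_a,
        f"C({factor_b})": factor_b,
        f"C({factor_a}):C({factor_b})": f"{factor_a}:{factor_b}",
    }
    for row_name, term in label.items():
        ss = float(table.loc[row_name, "sum_sq"])
        dof = float(table.loc[row_name, "df"])
        h = ss / ms_total
        out[term] = TestResult(term, h, dof, float(stats.chi2.sf(h, dof)))
    return out


def chi_square_2x2(table, yates: bool = False, name: str = "chi2") -> TestResult:
    """Pearson chi-square on a 2x2 count table (no continuity correction by
    default; toggle ``yates`` for the corrected form)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 nonnegative table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin in the table")
    chi2, p, dof, _ = stats.chi2_contingency(t, correction=yates)
    return TestResult(name, float(chi2), float(dof), float(p))


def pearson_cor(x, y, name: str = "pearson") -> TestResult:
    """Pearson correlation with its t-test on n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or n != len(y):
        raise ValueError("need paired vectors with n >= 3")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return TestResult(name, float(np.sign(r) * np.inf), float(n - 2), 0.0,
                          direction=float(np.sign(r)), extra={"r": r})
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return TestResult(name, float(t), float(n - 2), float(p),
                      direction=float(np.sign(r)), extra={"r": r})


def adjust_family(tests: list[TestResult], method: str = "bh", family: str = "family") -> list[TestResult]:
    """Benjamini-Hochberg adjustment across a declared test family."""
    if not tests:
        raise ValueError("empty family")
    if method.lower() != "bh":
        raise ValueError("only BH adjustment is supported")
    q = bh_adjust([t.p for t in tests])
    out = []
    for t, qi in zip(tests, q):
        out.append(dataclasses.replace(t, p_adj=float(qi), extra={**t.extra, "family": family}))
    return out


def alpha_association(alpha_values, covariate, kind: str = "regression", name: str = "alpha") -> TestResult:
    """Association of (transformed) alpha diversity with one covariate.

    ``regression``: OLS slope with its overall F-test for numeric covariates;
    ``welch``: two-sample Welch t for a binary grouping such as survival.
    """
    a = np.asarray(alpha_values, dtype=float)
    if kind == "welch":
        cov = pd.Series(list(covariate))
        levels = list(pd.unique(cov))
        if len(levels) != 2:
            raise ValueError("welch kind requires a two-level covariate")
        res = welch_t(a[(cov == levels[0]).to_numpy()], a[(cov == levels[1]).to_numpy()], name)
        return res
    if kind != "regression":
        raise ValueError("kind must be 'regression' or 'welch'")
    x = np.asarray(covariate, dtype=float)
    n = len(a)
    xc = x - x.mean()
    sxx = (xc**2).sum()
    if sxx == 0:
        raise ValueError("constant covariate")
    slope = float((xc * a).sum() / sxx)
    resid = a - a.mean() - slope * xc
    dof = n - 2
    ss_res = float((resid**2).sum())
    ss_reg = float(slope**2 * sxx)
    if ss_res == 0:
        f = np.inf if ss_reg > 0 else 0.0
        p = 0.0 if ss_reg > 0 else 1.0
    else:
        f = ss_reg / (ss_res / dof)
        p = float(stats.f.sf(f, 1, dof))
    return TestResult(name, float(f), float(dof), p, direction=float(np.sign(slope)),
                      extra={"slope": slope})
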