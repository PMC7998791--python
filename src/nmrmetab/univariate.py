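"""Univariate screening: Welch tests, fold-changes, correlations.

The case/control screen follows the heteroscedasticity-robust recipe used
for bucket intensity data: Welch's unequal-variance t test per feature
with Bonferroni correction over the active feature count, GM1T2:HC
fold-changes as ratios of group means with first-order Taylor-expansion
(delta-method) standard errors and t-based 95% confidence intervals, and
full pairwise Pearson correlation with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats


class DataError(ValueError):
    pass


@dataclass
class WelchResult:
    feature: str
    mean_control: float
    mean_case: float
    sd_control: float
    sd_case: float
    t: float
    df: float
    p: float
    p_bonf: float | None = None


@dataclass
class FoldChange:
    """Case:control mean ratio with a delta-method CI.

    ``ratio`` is mean(case)/mean(control); ``se`` the first-order
    Taylor-expansion standard error for independent groups; ``ci95`` the
    t-based 95% interval on Welch-Satterthwaite degrees of freedom.
    """

    feature: str
    ratio: float
    se: float
    ci95: tuple[float, float]
    df: float
    basis: str = "CS"
    reference: float | None = None
    significant_vs_reference: bool | None = None
    direction_vs_reference: str | None = None
    significant_vs_unity: bool = False
    direction_vs_unity: str | None = None


@dataclass
class CorrelationMatrix:
    r: pd.DataFrame
    p: pd.DataFrame
    p_adj: pd.DataFrame


def _welch_df(vx: float, nx: int, vy: float, ny: int) -> float:
    """Welch-Satterthwaite degrees of freedom."""
    a, b = vx / nx, vy / ny
    if a + b == 0:
        return float(nx + ny - 2)
    return (a + b) ** 2 / (a**2 / (nx - 1) + b**2 / (ny - 1))


def welch_test(x, y, feature: str = "") -> WelchResult:
    """Welch's unequal-variance two-sided t test (control x vs case y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DataError("need at least 2 values per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return WelchResult(
                feature, x.mean(), y.mean(), 0.0, 0.0, 0.0, float(x.size + y.size - 2), 1.0
            )
        return WelchResult(
            feature, x.mean(), y.mean(), 0.0, 0.0, np.inf, float(x.size + y.size - 2), 0.0
        )
    t, p = stats.ttest_ind(y, x, equal_var=False)
    df = _welch_df(vx, x.size, vy, y.size)
    return WelchResult(
        feature=feature,
        mean_control=float(x.mean()),
        mean_case=float(y.mean()),
        sd_control=float(np.sqrt(vx)),
        sd_case=float(np.sqrt(vy)),
        t=float(t),
        df=float(df),
        p=float(p),
    )


def bonferroni(p: float, m: int) -> float:
    """Bonferroni correction min(1, p*m) over m features."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, p * m)


def fold_change(x, y, feature: str = "", basis: str = "CS") -> FoldChange:
    """Case:control fold-change with Taylor-expansion SE and t-based 95% CI.

    For independent groups, Var(R) ~ R^2 (s_y^2/(n_y ybar^2)
    + s_x^2/(n_x xbar^2)) to first order; the CI uses the t distribution on
    Welch-Satterthwaite degrees of freedom from the two group variances.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DataError("need at least 2 values per group")
    mx, my = x.mean(), y.mean()
    if mx <= 0:
        raise DataError("control mean must be > 0 for a ratio")
    r = my / mx
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    # equivalent to R^2 (s_y^2/(n_y ybar^2) + s_x^2/(n_x xbar^2)), but
    # well-defined when the case mean is zero
    var_r = (vy / y.size + r**2 * vx / x.size) / mx**2
    se = float(np.sqrt(max(var_r, 0.0)))
    df = _welch_df(vx, x.size, vy, y.size)
    if se == 0:
        ci = (r, r)
    else:
        tq = stats.t.ppf(0.975, df)
        ci = (r - tq * se, r + tq * se)
    fc = FoldChange(feature=feature, ratio=float(r), se=se, ci95=ci, df=float(df), basis=basis)
    return compare_to_reference(fc, 1.0, unity=True)


def compare_to_reference(fc: FoldChange, reference: float, unity: bool = False) -> FoldChange:
    """Flag whether ``reference`` lies outside the fold-change 95% CI."""
    lo, hi = fc.ci95
    significant = not (lo <= reference <= hi)
    direction = None
    if significant:
        direction = "greater" if lo > reference else "less"
    if unity:
        return replace(
            fc, significant_vs_unity=significant, direction_vs_unity=direction
        )
    return replace(
        fc,
        reference=reference,
        significant_vs_reference=significant,
        direction_vs_reference=direction,
    )


def screen(matrix, m: int | None = None) -> pd.DataFrame:
    """Welch + Bonferroni + fold-change screen of a FeatureMatrix.

    Returns a tidy table (feature, direction, fold_change, ci_lo, ci_hi,
    p, p_bonf) in the shape of the published statistics tables.  ``m``
    defaults to the active feature count of the matrix being tested.
    """
    if matrix.groups is None:
        raise DataError("matrix carries no group labels")
    groups = np.asarray(matrix.groups)
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise DataError("exactly two groups required")
    control = "HC" if "HC" in labels else labels[0]
    case = [g for g in labels if g != control][0]
    X = matrix.values
    m = X.shape[1] if m is None else m
    rows = []
    for j, name in enumerate(matrix.feature_names):
        x = X[groups == control, j]
        y = X[groups == case, j]
        wr = welch_test(x, y, feature=name)
        wr.p_bonf = bonferroni(wr.p, m)
        try:
            fc = fold_change(x, y, feature=name)
            ratio, (lo, hi) = fc.ratio, fc.ci95
        except DataError:
            ratio, lo, hi = np.nan, np.nan, np.nan
        rows.append(
            {
                "feature": name,
                "direction": "up" if wr.mean_case > wr.mean_control else "down",
                "fold_change": ratio,
                "ci_lo": lo,
                "ci_hi": hi,
                "t": wr.t,
                "df": wr.df,
                "p": wr.p,
                "p_bonf": wr.p_bonf,
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def pearson_correlations(matrix) -> CorrelationMatrix:
    """Pairwise Pearson r with BH-adjusted p over the upper triangle."""
    from statsmodels.stats.multitest import multipletests

    df = matrix.to_frame() if hasattr(matrix, "to_frame") else pd.DataFrame(matrix)
    X = df.to_numpy(dtype=float)
    n, p = X.shape
    if n < 3:
        raise DataError("need at least 3 samples for correlation p-values")
    names = list(df.columns)
    sd = X.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s); correlations undefined",
            stacklevel=2,
        )
    r = np.full((p, p), np.nan)
    pv = np.full((p, p), np.nan)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(pv, 0.0)
    for i in range(p):
        for j in range(i + 1, p):
            if constant[i] or constant[j]:
                continue
            ri, pij = stats.pearsonr(X[:, i], X[:, j])
            r[i, j] = r[j, i] = ri
            pv[i, j] = pv[j, i] = pij
    iu = np.triu_indices(p, k=1)
    flat = pv[iu]
    adj = np.full_like(flat, np.nan)
    ok = ~np.isnan(flat)
    if ok.any():
        adj[ok] = multipletests(flat[ok], method="fdr_bh")[1]
    padj = np.full((p, p), np.nan)
    padj[iu] = adj
    padj.T[iu] = adj
    np.fill_diagonal(padj, 0.0)
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=names, columns=names),
        p=pd.DataFrame(pv, index=names, columns=names),
        p_adj=pd.DataFrame(padj, index=names, columns=names),
    )
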