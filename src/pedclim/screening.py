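"""Pre-analysis assumption screening.

Canonical correlation inference assumes approximately multivariate-normal,
homoscedastic variables without collinear redundancy or gross outliers.
This module provides the four screens applied before fitting:

* iterative variance-inflation-factor (VIF) exclusion of collinear
  variables (drop the largest VIF ≥ threshold, recompute, repeat);
* Shapiro–Wilk and D'Agostino–Pearson K² normality tests;
* Levene's k-sample homoscedasticity test;
* ROUT outlier detection (robust fit + false-discovery-rate test) on the
  constant model, column-wise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScreeningReport",
    "vif_screen",
    "normality_tests",
    "levene",
    "rout_outliers",
    "screen_matrix",
]

#: auxiliary-regression R² above this is treated as exact singularity
SINGULAR_R2 = 1.0 - 1e-10


@dataclass
class ScreeningReport:
    """Outcome of the screening cascade on one variable set."""

    vif: dict[str, float] = field(default_factory=dict)
    excluded_vif: list[str] = field(default_factory=list)
    excluded_singular: list[str] = field(default_factory=list)
    normality: dict[str, tuple[float, float]] = field(default_factory=dict)
    levene_p: dict[str, float] = field(default_factory=dict)
    outliers: dict[str, list[int]] = field(default_factory=dict)
    Q: float = 0.01

    @property
    def excluded(self) -> list[str]:
        return self.excluded_singular + self.excluded_vif


def _vif_values(X: pd.DataFrame) -> dict[str, float]:
    """VIF_j = 1/(1 − R²_j) from regressing column j on the others."""
    out = {}
    Z = X.to_numpy(dtype=float)
    n = Z.shape[0]
    for j, name in enumerate(X.columns):
        y = Z[:, j]
        others = np.delete(Z, j, axis=1)
        design = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        tss = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / tss if tss > 0 else 1.0
        out[name] = np.inf if r2 >= SINGULAR_R2 else 1.0 / (1.0 - r2)
    return out


def vif_screen(
    X: pd.DataFrame, threshold: float = 5.0
) -> tuple[pd.DataFrame, ScreeningReport]:
    """Iteratively exclude collinear columns until every VIF < threshold.

    Constant and exactly-singular columns (auxiliary R² = 1) are flagged
    separately from finite-VIF exclusions.  Removal is one at a time by
    largest VIF, so the order is deterministic and recorded.
    """
    if X.shape[1] < 3:
        raise ValueError("vif_screen needs at least 3 variables")
    if X.isna().any().any():
        raise ValueError("vif_screen requires complete cases")
    report = ScreeningReport()
    kept = X.copy()
    for name in list(kept.columns):  # constant columns can never be kept
        if kept[name].nunique() <= 1:
            report.excluded_singular.append(name)
            kept = kept.drop(columns=name)
    while kept.shape[1] >= 2:
        vifs = _vif_values(kept)
        # near-ties drop the later column: a redundant pair (an exact
        # linear combination, or a variable that is another plus noise)
        # gives both members statistically indistinguishable VIFs, and
        # sets are conventionally ordered primary variables first,
        # derived ones appended
        worst = max(reversed(list(vifs)), key=lambda k: vifs[k])
        top = vifs[worst]
        if np.isfinite(top):
            for name in reversed(list(vifs)):
                if vifs[name] >= 0.85 * top:
                    worst = name
                    break
        if not np.isfinite(vifs[worst]):
            report.excluded_singular.append(worst)
            kept = kept.drop(columns=worst)
            continue
        if vifs[worst] >= threshold:
            report.excluded_vif.append(worst)
            kept = kept.drop(columns=worst)
            continue
        report.vif = vifs
        break
    else:
        report.vif = {c: 1.0 for c in kept.columns}
    return kept, report


def normality_tests(x: np.ndarray) -> tuple[float, float]:
    """(Shapiro–Wilk p, D'Agostino–Pearson K² p) for one sample.

    K² is the omnibus statistic combining the skewness and kurtosis
    z-scores; it needs n ≥ 8, Shapiro–Wilk n ≥ 3.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise ValueError("normality_tests needs n >= 8")
    if np.ptp(x) == 0:
        raise ValueError("constant sample has no defined normality test")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns for n > 5000
        sw = stats.shapiro(x).pvalue
    dp = stats.normaltest(x).pvalue
    return float(sw), float(dp)


def levene(groups: list[np.ndarray], center: str = "mean") -> float:
    """Levene's k-sample variance-homogeneity test p-value.

    One-way ANOVA on |x − center(group)|; ``center`` is "mean" (classical
    Levene) or "median" (Brown–Forsythe).
    """
    if len(groups) < 2:
        raise ValueError("levene needs at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    devs = [np.abs(np.asarray(g, float) - getattr(np, center)(g)) for g in groups]
    if all(np.ptp(d) == 0 for d in devs):
        warnings.warn("degenerate dispersion in every group; p = 1", stacklevel=2)
        return 1.0
    return float(stats.levene(*groups, center=center).pvalue)


def rout_outliers(x: np.ndarray, Q: float = 0.01) -> list[int]:
    """ROUT outlier detection on the constant model.

    Fits a robust location by iteratively reweighted least squares with
    Lorentzian weights 1/(1 + (r/RSDR)²), estimates the robust standard
    deviation of the residuals (RSDR) as the 68.27th percentile of the
    absolute residuals times the small-n correction n/(n − 1), then tests
    points from the most extreme inward: the i-th most extreme point is an
    outlier when its two-tailed t probability (df = n − 1) falls below
    Q·i/n, stopping at the first non-significant point.  ``Q`` is the
    maximum desired false discovery rate.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("rout_outliers needs n >= 10")
    if np.ptp(x) == 0:
        return []

    center = float(np.median(x))
    for _ in range(50):
        resid = x - center
        rsdr = np.percentile(np.abs(resid), 68.27) * n / (n - 1)
        if rsdr == 0:
            break
        w = 1.0 / (1.0 + (resid / rsdr) ** 2)
        new_center = float(np.sum(w * x) / np.sum(w))
        if abs(new_center - center) <= 1e-12 * max(1.0, abs(center)):
            center = new_center
            break
        center = new_center

    resid = x - center
    rsdr = np.percentile(np.abs(resid), 68.27) * n / (n - 1)
    if rsdr == 0:
        return []
    t = np.abs(resid) / rsdr
    order = np.argsort(-t)  # most extreme first
    pvals = 2.0 * stats.t.sf(t[order], df=n - 1)
    flagged: list[int] = []
    for rank, idx in enumerate(order, start=1):
        if pvals[rank - 1] < Q * rank / n:
            flagged.append(int(idx))
        else:
            break
    return sorted(flagged)


def screen_matrix(
    X: pd.DataFrame,
    vif_threshold: float = 5.0,
    rout_q: float = 0.01,
    levene_groups: pd.Series | None = None,
) -> tuple[pd.DataFrame, ScreeningReport]:
    """Full screening cascade on one variable set.

    Order mirrors the analysis workflow: normality and outlier checks are
    recorded per variable (they never gate the pipeline — inference is by
    permutation downstream), then collinear variables are excluded by VIF.
    """
    kept, report = vif_screen(X, threshold=vif_threshold)
    report.Q = rout_q
    for name in X.columns:
        col = X[name].to_numpy(dtype=float)
        if np.ptp(col) > 0 and col.size >= 10:
            report.normality[name] = normality_tests(col)
            report.outliers[name] = rout_outliers(col, Q=rout_q)
        if levene_groups is not None:
            grp = [col[levene_groups.to_numpy() == g]
                   for g in pd.unique(levene_groups)]
            grp = [g for g in grp if len(g) >= 2]
            if len(grp) >= 2:
                report.levene_p[name] = levene(grp)
    return kept, report
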