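"""Regularized canonical correlation analysis (RCCA).

Given two standardized variable blocks X (n × p) and Y (n × q), canonical
correlation analysis finds linear combinations ("canonical variates")
u_i = X a_i, v_i = Y b_i maximising corr(u_i, v_i) subject to
orthogonality with the earlier pairs.  Regularization adds ridge terms
λ1 I, λ2 I to the within-set covariance matrices, stabilising the solution
when blocks are collinear or n is small relative to p + q.

The solver whitens both blocks with the symmetric inverse square root of
the regularized covariances and takes the SVD of the whitened cross-
covariance; the singular values are the canonical correlations.  Derived
quantities (eigenvalues r²/(1−r²), structure loadings, redundancy,
MANOVA-style significance criteria with their F approximations, and a
permutation test) follow the standard canonical-analysis conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CcaResult",
    "SignificanceTable",
    "standardize",
    "pearson_matrix",
    "fit_rcca",
    "variance_shares",
    "redundancy",
    "multivariate_tests",
    "permutation_test",
    "canonical_scores",
    "MEANINGFUL_R",
]

#: canonical correlations at or above this are flagged "meaningful"
#: (≈10% shared variance)
MEANINGFUL_R = 0.30

_EIG_FLOOR = 1e-12


@dataclass
class CcaResult:
    """Fitted canonical system for one (λ1, λ2) pair.

    Coefficients are for standardized inputs, hence already standardized
    coefficients; loadings are Pearson correlations between each original
    variable and the canonical variate scores.
    """

    r: np.ndarray
    coef_X: np.ndarray
    coef_Y: np.ndarray
    loadings_X: np.ndarray
    loadings_Y: np.ndarray
    lambda1: float
    lambda2: float
    n: int

    @property
    def r2(self) -> np.ndarray:
        return self.r**2

    @property
    def eigenvalues(self) -> np.ndarray:
        return self.r2 / (1.0 - self.r2)

    @property
    def std_coef_X(self) -> np.ndarray:
        return self.coef_X

    @property
    def std_coef_Y(self) -> np.ndarray:
        return self.coef_Y

    @property
    def variance_share(self) -> np.ndarray:
        return variance_shares(self.eigenvalues)

    @property
    def meaningful(self) -> np.ndarray:
        return self.r >= MEANINGFUL_R

    @property
    def redundancy_X(self) -> np.ndarray:
        return np.mean(self.loadings_X**2, axis=0) * self.r2

    @property
    def redundancy_Y(self) -> np.ndarray:
        return np.mean(self.loadings_Y**2, axis=0) * self.r2


@dataclass
class SignificanceTable:
    """Multivariate criteria with F approximations and the per-root
    dimension-reduction sequence of Wilks tests."""

    pillai: float
    hotelling: float
    wilks: float
    roy: float
    approx_F: dict[str, float]
    df_hyp: dict[str, float]
    df_err: dict[str, float]
    p: dict[str, float]
    roots_table: list[dict] = field(default_factory=list)


def standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column z-scores with n−1 standard deviations; errors on constants."""
    X = np.asarray(X, dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(sds == 0)
    if bad.size:
        raise ValueError(f"constant column(s) at position {bad.tolist()}")
    return (X - means) / sds, means, sds


def pearson_matrix(
    X: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(Rxx, Ryy, Rxy): within- and between-set Pearson correlations."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0] or X.shape[0] < 3:
        raise ValueError("X and Y need the same n >= 3 rows")
    Zx, *_ = standardize(X)
    Zy, *_ = standardize(Y)
    n = X.shape[0]
    Rxx = Zx.T @ Zx / (n - 1)
    Ryy = Zy.T @ Zy / (n - 1)
    Rxy = Zx.T @ Zy / (n - 1)
    np.fill_diagonal(Rxx, 1.0)
    np.fill_diagonal(Ryy, 1.0)
    return Rxx, Ryy, Rxy


def _inv_sqrt(M: np.ndarray) -> np.ndarray:
    """Symmetric inverse square root with an eigenvalue floor."""
    vals, vecs = np.linalg.eigh(M)
    vals = np.maximum(vals, _EIG_FLOOR)
    return (vecs / np.sqrt(vals)) @ vecs.T


def fit_rcca(
    Zx: np.ndarray, Zy: np.ndarray, lambda1: float = 0.0, lambda2: float = 0.0
) -> CcaResult:
    """Fit the regularized canonical system on standardized blocks.

    Returns s = min(p, q) variate pairs, correlations descending.  Signs
    are fixed deterministically: the X variable with the largest |loading|
    on each variate loads positively, and the paired Y variate is flipped
    with it so every canonical correlation stays non-negative.
    """
    Zx = np.asarray(Zx, dtype=float)
    Zy = np.asarray(Zy, dtype=float)
    if not (np.isfinite(Zx).all() and np.isfinite(Zy).all()):
        raise ValueError("non-finite values in input")
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("regularization parameters must be >= 0")
    n, p = Zx.shape
    q = Zy.shape[1]
    s = min(p, q)
    Cxx = Zx.T @ Zx / (n - 1) + lambda1 * np.eye(p)
    Cyy = Zy.T @ Zy / (n - 1) + lambda2 * np.eye(q)
    Cxy = Zx.T @ Zy / (n - 1)
    Wx = _inv_sqrt(Cxx)
    Wy = _inv_sqrt(Cyy)
    U, sv, Vt = np.linalg.svd(Wx @ Cxy @ Wy)
    r = np.clip(sv[:s], 0.0, 1.0)
    A = Wx @ U[:, :s]  # unit variance under the regularized metric
    B = Wy @ Vt[:s].T

    scores_x = Zx @ A
    scores_y = Zy @ B
    loadings_X = _corr_cols(Zx, scores_x)
    loadings_Y = _corr_cols(Zy, scores_y)
    for i in range(s):
        j = int(np.argmax(np.abs(loadings_X[:, i])))
        if loadings_X[j, i] < 0:
            A[:, i] *= -1
            B[:, i] *= -1
            loadings_X[:, i] *= -1
            loadings_Y[:, i] *= -1
    return CcaResult(
        r=r, coef_X=A, coef_Y=B,
        loadings_X=loadings_X, loadings_Y=loadings_Y,
        lambda1=float(lambda1), lambda2=float(lambda2), n=n,
    )


def _corr_cols(Z: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Pearson correlations between columns of Z and columns of S."""
    Zc = Z - Z.mean(axis=0)
    Sc = S - S.mean(axis=0)
    denom = np.outer(
        np.sqrt(np.sum(Zc**2, axis=0)), np.sqrt(np.sum(Sc**2, axis=0))
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, Zc.T @ Sc / denom, 0.0)


def variance_shares(eigenvalues: np.ndarray) -> np.ndarray:
    """Percent of total canonical eigenvalue mass per dimension."""
    ev = np.asarray(eigenvalues, dtype=float)
    if np.any(ev < 0):
        raise ValueError("eigenvalues must be >= 0")
    total = ev.sum()
    if total == 0:
        raise ValueError("all eigenvalues are zero")
    return 100.0 * ev / total


def redundancy(result: CcaResult) -> dict[str, np.ndarray | float]:
    """Stewart–Love redundancy per variate and in total, for both sets.

    Rd_i for a set = (mean squared loading of that set's variables on
    variate i) × r_i²: the share of the set's variance explained by the
    opposite set through variate i.
    """
    rx = result.redundancy_X
    ry = result.redundancy_Y
    return {
        "X": rx, "Y": ry,
        "X_total": float(rx.sum()), "Y_total": float(ry.sum()),
    }


def _rao_wilks_F(lam: float, p: int, q: int, n: int, k: int = 1):
    """Rao's F approximation for Wilks Λ on roots k..s.

    Effective dimensions p' = p−k+1, q' = q−k+1; the multiplier subtracts
    the k−1 already-partialled dimensions (the SPSS/STATA dimension-
    reduction convention).
    """
    pp, qq = p - k + 1, q - k + 1
    df1 = pp * qq
    denom = pp**2 + qq**2 - 5
    t = np.sqrt((pp**2 * qq**2 - 4) / denom) if denom > 0 else 1.0
    M = n - 1 - (k - 1) - (pp + qq + 1) / 2.0
    df2 = M * t - (df1 - 2) / 2.0
    lam_t = lam ** (1.0 / t)
    F = (1.0 - lam_t) / lam_t * df2 / df1
    return F, float(df1), float(df2)


def multivariate_tests(
    r: np.ndarray, n: int, p: int, q: int
) -> SignificanceTable:
    """Pillai, Hotelling–Lawley, Wilks and Roy criteria from canonical
    correlations, with their standard F approximations, plus the per-root
    Wilks sequence testing roots k..s for k = 1..s."""
    r = np.asarray(r, dtype=float)
    if n <= p + q + 1:
        raise ValueError("need n > p + q + 1")
    r2 = r**2
    s = min(p, q)
    m = (abs(p - q) - 1) / 2.0
    nn = (n - p - q - 2) / 2.0

    V = float(r2.sum())
    T = float((r2 / (1.0 - r2)).sum())
    lam = float(np.prod(1.0 - r2))
    theta = float(r2[0])

    F_p = (2 * nn + s + 1) / (2 * m + s + 1) * V / (s - V)
    df_p = (s * (2 * m + s + 1), s * (2 * nn + s + 1))
    df_h = (s * (2 * m + s + 1), 2 * (s * nn + 1))
    F_h = df_h[1] * T / (s * df_h[0])
    F_w, df1_w, df2_w = _rao_wilks_F(lam, p, q, n)

    approx_F = {"pillai": float(F_p), "hotelling": float(F_h), "wilks": float(F_w)}
    df_hyp = {"pillai": float(df_p[0]), "hotelling": float(df_h[0]), "wilks": df1_w}
    df_err = {"pillai": float(df_p[1]), "hotelling": float(df_h[1]), "wilks": df2_w}
    pvals = {
        name: float(stats.f.sf(approx_F[name], df_hyp[name], df_err[name]))
        for name in approx_F
    }

    roots = []
    for k in range(1, s + 1):
        lam_k = float(np.prod(1.0 - r2[k - 1:]))
        F_k, d1, d2 = _rao_wilks_F(lam_k, p, q, n, k=k)
        roots.append({
            "roots": f"{k} to {s}", "wilks": lam_k, "F": float(F_k),
            "df_hyp": d1, "df_err": d2, "p": float(stats.f.sf(F_k, d1, d2)),
        })
    return SignificanceTable(
        pillai=V, hotelling=T, wilks=lam, roy=theta,
        approx_F=approx_F, df_hyp=df_hyp, df_err=df_err, p=pvals,
        roots_table=roots,
    )


def permutation_test(
    Zx: np.ndarray,
    Zy: np.ndarray,
    lambda1: float = 0.0,
    lambda2: float = 0.0,
    B: int = 499,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Permutation p-values per canonical root.

    Rows of Zy are permuted B times; p_k = (1 + #{r_k^(b) ≥ r_k^obs}) /
    (B + 1).  Distribution-free, hence robust to the non-normality and
    heteroscedasticity the screening stage records.
    """
    if B < 99:
        raise ValueError("need B >= 99 permutations")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = fit_rcca(Zx, Zy, lambda1, lambda2).r
    exceed = np.zeros_like(obs)
    n = Zx.shape[0]
    for _ in range(B):
        perm = rng.permutation(n)
        r_b = fit_rcca(Zx, Zy[perm], lambda1, lambda2).r
        exceed += r_b >= obs
    return (1.0 + exceed) / (B + 1.0)


def canonical_scores(
    result: CcaResult, Zx_new: np.ndarray, Zy_new: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Project (already standardized) data onto the fitted variates."""
    Zx_new = np.asarray(Zx_new, dtype=float)
    Zy_new = np.asarray(Zy_new, dtype=float)
    if Zx_new.shape[1] != result.coef_X.shape[0]:
        raise ValueError("X column count differs from training")
    if Zy_new.shape[1] != result.coef_Y.shape[0]:
        raise ValueError("Y column count differs from training")
    return Zx_new @ result.coef_X, Zy_new @ result.coef_Y
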