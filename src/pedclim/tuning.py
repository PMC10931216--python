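"""Cross-validated choice of the RCCA regularization parameters.

The (λ1, λ2) pair is picked on a grid by k-fold cross-validation: for each
cell, the model is fitted on k−1 folds and scored by the Pearson
correlation between the held-out first-variate score pair; the cell with
the highest mean score wins (ties towards smaller λ1, then smaller λ2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rcca import canonical_scores, fit_rcca

__all__ = ["TuningResult", "tune_rcc", "select_dimensions", "default_grid"]


@dataclass
class TuningResult:
    grid1: np.ndarray
    grid2: np.ndarray
    score: np.ndarray  # shape (len(grid1), len(grid2))
    best_lambda1: float
    best_lambda2: float
    best_score: float
    k: int
    seed: int


def default_grid(size: int = 10, lo: float = 0.001, hi: float = 1.0) -> np.ndarray:
    """Log-spaced candidate λ values in the open interval (lo, hi)."""
    return np.geomspace(lo, hi, size)


def _folds(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Seeded shuffle split into k near-equal folds, remainder spread
    one-per-fold from the first."""
    perm = rng.permutation(n)
    base, extra = divmod(n, k)
    folds, start = [], 0
    for i in range(k):
        size = base + (1 if i < extra else 0)
        folds.append(perm[start:start + size])
        start += size
    return folds


def tune_rcc(
    Zx: np.ndarray,
    Zy: np.ndarray,
    grid1: np.ndarray,
    grid2: np.ndarray,
    k: int = 10,
    seed: int = 0,
) -> TuningResult:
    """Grid search (λ1, λ2) by k-fold CV of the first-pair score correlation."""
    Zx = np.asarray(Zx, dtype=float)
    Zy = np.asarray(Zy, dtype=float)
    grid1 = np.atleast_1d(np.asarray(grid1, dtype=float))
    grid2 = np.atleast_1d(np.asarray(grid2, dtype=float))
    n = Zx.shape[0]
    if n < 2 * k:
        raise ValueError(f"need n >= 2k rows, got n={n}, k={k}")
    rng = np.random.default_rng(seed)
    folds = _folds(n, k, rng)
    if any(len(f) < 2 for f in folds):
        raise ValueError("a fold has fewer than 2 rows; reduce k")

    score = np.empty((grid1.size, grid2.size))
    for i, l1 in enumerate(grid1):
        for j, l2 in enumerate(grid2):
            vals = []
            for hold in folds:
                train = np.setdiff1d(np.arange(n), hold, assume_unique=False)
                fit = fit_rcca(Zx[train], Zy[train], l1, l2)
                sx, sy = canonical_scores(fit, Zx[hold], Zy[hold])
                vals.append(_safe_corr(sx[:, 0], sy[:, 0]))
            score[i, j] = np.mean(vals)

    best_flat = np.argmax(score)  # ties: argmax takes the first in C order,
    bi, bj = np.unravel_index(best_flat, score.shape)  # i.e. smaller λ1 then λ2
    return TuningResult(
        grid1=grid1, grid2=grid2, score=score,
        best_lambda1=float(grid1[bi]), best_lambda2=float(grid2[bj]),
        best_score=float(score[bi, bj]), k=k, seed=seed,
    )


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def select_dimensions(r: np.ndarray) -> int:
    """Number of dimensions before the largest gap in the correlations.

    d = index (1-based) preceding the largest consecutive drop
    r_i − r_{i+1}.  With a single root, or no gap at all (equal
    correlations), every dimension is kept.
    """
    r = np.asarray(r, dtype=float)
    if r.size == 1:
        return 1
    drops = r[:-1] - r[1:]
    if np.all(drops == 0):
        import warnings

        warnings.warn("no gap among canonical correlations", stacklevel=2)
        return int(r.size)
    return int(np.argmax(drops)) + 1
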