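#!/usr/bin/env python
"""Choose the ridge parameters by 10-fold cross-validation.

Scores a log-spaced lambda grid in (0.001, 1) by the held-out
first-variate score correlation and writes the grid with its optimum to
results/tuning.json.
"""

import json

import numpy as np
import pandas as pd

from pedclim.rcca import standardize
from pedclim.tuning import default_grid, tune_rcc

SEED = 7

if __name__ == "__main__":
    keep = json.load(open("results/screening.json"))
    div = pd.read_csv("results/diversity.csv")
    clim = pd.read_csv("results/birth_climate.csv").dropna()
    both = div.merge(clim, on="id")
    Zx, *_ = standardize(both[keep["genetic"]["kept"]].to_numpy())
    Zy, *_ = standardize(both[keep["climate"]["kept"]].to_numpy())

    grid = default_grid(10)
    res = tune_rcc(Zx, Zy, grid, grid, k=10, seed=SEED)
    with open("results/tuning.json", "w") as fh:
        json.dump({"grid": grid.tolist(), "score": res.score.tolist(),
                   "best_lambda1": res.best_lambda1,
                   "best_lambda2": res.best_lambda2,
                   "best_score": res.best_score, "k": res.k,
                   "seed": res.seed}, fh, indent=1)
    print(f"10-fold CV over a {grid.size}x{grid.size} grid in (0.001, 1)")
    print(f"optimum lambda1 = {res.best_lambda1:.4g}, "
          f"lambda2 = {res.best_lambda2:.4g}, CV score = {res.best_score:.3f}")
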