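#!/usr/bin/env python
"""Screen both variable sets before canonical analysis.

Runs iterative VIF exclusion (threshold 5), records Shapiro-Wilk and
D'Agostino-Pearson normality p-values and ROUT outlier flags (Q = 1%)
per variable, and writes the kept-variable lists to
results/screening.json.
"""

import json

import pandas as pd

from pedclim.pipeline import DIVERSITY_VARS
from pedclim.screening import screen_matrix

if __name__ == "__main__":
    div = pd.read_csv("results/diversity.csv")
    clim = pd.read_csv("results/birth_climate.csv").dropna()
    div = div[div["id"].isin(clim["id"])]

    X_kept, rep_x = screen_matrix(div[DIVERSITY_VARS])
    Y_kept, rep_y = screen_matrix(clim.drop(columns="id"))

    out = {
        "genetic": {"kept": list(X_kept.columns), "excluded": rep_x.excluded,
                    "vif": rep_x.vif},
        "climate": {"kept": list(Y_kept.columns), "excluded": rep_y.excluded,
                    "vif": rep_y.vif},
        "outlier_counts": {
            **{v: len(ix) for v, ix in rep_x.outliers.items()},
            **{v: len(ix) for v, ix in rep_y.outliers.items()},
        },
    }
    with open("results/screening.json", "w") as fh:
        json.dump(out, fh, indent=1)
    print(f"genetic set: excluded {rep_x.excluded}, kept {list(X_kept.columns)}")
    print(f"climate set: excluded {rep_y.excluded}, kept {list(Y_kept.columns)}")
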