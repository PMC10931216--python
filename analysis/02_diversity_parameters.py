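#!/usr/bin/env python
"""Compute every per-individual genetic diversity parameter.

Reads results/data/pedigree.csv and writes results/diversity.csv with
inbreeding F, average relatedness, mean coancestry, non-random mating
degree, GCI, the three pedigree-depth measures, the per-generation
inbreeding rate and offspring counts.
"""

from pathlib import Path

from pedclim.diversity import diversity_table
from pedclim.pedigree import load_pedigree

if __name__ == "__main__":
    ped = load_pedigree("results/data/pedigree.csv")
    df = diversity_table(ped)
    out = Path("results/diversity.csv")
    df.to_csv(out, index=False)
    print(f"{len(df)} individuals -> {out}")
    print(df[["F", "AR", "GCI", "max_gen", "equiv_gen", "delta_F"]]
          .describe().loc[["mean", "std", "max"]].round(4).to_string())
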