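#!/usr/bin/env python
"""Generate the synthetic study dataset.

Writes a multi-generation pedigree (births 1950-2019 over three places)
and the matching per-place daily weather series to results/data/.  The
weather table carries two deliberately redundant columns (average
temperature, maximum barometric pressure) so the screening stage has
planted exclusions to find.
"""

from pathlib import Path

from pedclim.simulate import SyntheticConfig, end_to_end_fixture

OUT = Path("results/data")
SEED = 7

if __name__ == "__main__":
    cfg = SyntheticConfig(seed=SEED)
    paths = end_to_end_fixture(OUT, cfg)
    print(f"pedigree -> {paths['pedigree']}")
    print(f"weather  -> {paths['weather']}")
    print(f"planted redundant climate columns: {paths['planted_redundant']}")
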