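#!/usr/bin/env python
"""Define the study set and attach each individual's birth-day climate.

Prunes the register (unregistered birthplace, foreign-born, no climate
coverage, inaccurate location), scrubs wind sentinels, joins each kept
individual to the weather record of its birth place and date, and writes
results/birth_climate.csv plus the prune report.
"""

import json
from pathlib import Path

from pedclim.climate import assign_birth_climate, load_weather, sentinel_scrub
from pedclim.pedigree import load_pedigree, prune_study_set

if __name__ == "__main__":
    ped = load_pedigree("results/data/pedigree.csv")
    store, scrubbed = sentinel_scrub(load_weather("results/data/weather.csv"))
    study, report = prune_study_set(
        ped, climate_coverage=store.coverage(), home_country="ES"
    )
    tab, missing = assign_birth_climate(ped, store, study_ids=study)
    tab.to_csv("results/birth_climate.csv", index=False)
    with open("results/prune_report.json", "w") as fh:
        json.dump({"n_initial": report.n_initial,
                   "per_category": report.per_category,
                   "n_final": report.n_final,
                   "no_birth_day_record": len(missing)}, fh, indent=1)
    print(f"register {report.n_initial} -> study set {report.n_final} "
          f"(discarded {report.per_category})")
    print(f"{len(tab)} birth-climate vectors -> results/birth_climate.csv")
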