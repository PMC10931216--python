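"""Daily weather store and birth-climate assignment.

Weather observations are daily station summaries keyed by (place, date):
altitude (m), rainfall (mm/day), minimum / average / maximum temperature
(°C), wind direction (tenths of degree, 0–360 scale / 10, with a sentinel
for variable wind), average wind speed and gust speed (m/s), sunlight hours
(h/day) and minimum / maximum barometric pressure (hPa).

Each study individual is assigned the climate vector of its birth place on
its birth date; individuals without an eligible record land on the missing
list, which feeds the ``no_climate_registry`` pruning category.
"""

from __future__ import annotations

import io
import logging
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .pedigree import Pedigree

logger = logging.getLogger(__name__)

#: canonical file/store column order for the 11 observed variables
WEATHER_VARS = [
    "altitude", "rain", "tmin", "tavg", "tmax",
    "wdir", "wspd", "gust", "sun", "pmin", "pmax",
]

#: station-export sentinel conventions: 99 encodes "variable" wind
DEFAULT_SENTINELS = {"wdir": [99.0], "wspd": [99.0]}


class WeatherStore:
    """Daily records indexed by (place, date)."""

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame
        self._index = {
            (r.place, r.date): n for n, r in enumerate(frame.itertuples(index=False))
        }
        self._by_place: dict[str, list[date]] = {}
        for place, d in self._index:
            self._by_place.setdefault(place, []).append(d)
        for dates in self._by_place.values():
            dates.sort()

    def __len__(self) -> int:
        return len(self._index)

    def __contains__(self, key: tuple[str, date]) -> bool:
        return key in self._index

    def get(self, place: str, day: date) -> dict | None:
        n = self._index.get((place, day))
        if n is None:
            return None
        rec = self.frame.iloc[n].to_dict()
        return {k: rec.get(k, np.nan) for k in WEATHER_VARS}

    def dates_for(self, place: str) -> list[date]:
        return self._by_place.get(place, [])

    def coverage(self) -> dict[str, tuple[date, date]]:
        """Per place, the (first, last) covered date — the pruning input."""
        return {pl: (ds[0], ds[-1]) for pl, ds in self._by_place.items() if ds}


def load_weather(source) -> WeatherStore:
    """Read a delimited weather table with columns place,date + variables.

    Duplicate (place, date) keys keep the last row, with a warning.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, newline="") as fh:
            text = fh.read()
    delim = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(io.StringIO(text), sep=delim)
    if not {"place", "date"}.issubset(df.columns):
        raise ValueError("weather table needs columns place,date")
    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601").dt.date
    except ValueError as exc:
        raise ValueError(f"unparseable date in weather table: {exc}") from exc
    for col in df.columns:
        if col in ("place", "date"):
            continue
        df[col] = pd.to_numeric(df[col], errors="raise")
    n_dup = df.duplicated(subset=["place", "date"]).sum()
    if n_dup:
        logger.warning("%d duplicate (place, date) keys; keeping last", n_dup)
        df = df.drop_duplicates(subset=["place", "date"], keep="last")
    return WeatherStore(df.reset_index(drop=True))


def sentinel_scrub(
    store: WeatherStore,
    rules: dict[str, list[float]] | None = None,
) -> tuple[WeatherStore, dict[str, int]]:
    """Replace sentinel-coded cells (e.g. wind direction 99 = variable) with
    missing values.  Returns the scrubbed store and per-variable counts."""
    if rules is None:
        rules = DEFAULT_SENTINELS
    frame = store.frame.copy()
    counts: dict[str, int] = {}
    for var, sentinels in rules.items():
        if var not in frame.columns:
            continue
        mask = frame[var].isin(sentinels)
        counts[var] = int(mask.sum())
        frame.loc[mask, var] = np.nan
    return WeatherStore(frame), counts


def assign_birth_climate(
    p: Pedigree,
    store: WeatherStore,
    study_ids: list[str] | None = None,
    policy: str = "exact",
) -> tuple[pd.DataFrame, list[str]]:
    """Join each study individual to the weather of its birth day and place.

    Policies: ``exact`` (record on the birth date), ``nearest:k`` (closest
    record within ±k days, earlier date winning ties) or ``monthly`` (mean
    of the birth month's records).  Individuals with no eligible record are
    returned on the missing list.
    """
    ids = list(study_ids) if study_ids is not None else p.ids
    kind, k = _parse_policy(policy)
    rows, missing = [], []
    for i in ids:
        ind = p[i]
        vec = None
        if ind.birth_place is not None and ind.birth_date is not None:
            if kind == "exact":
                vec = store.get(ind.birth_place, ind.birth_date)
            elif kind == "nearest":
                vec = _nearest(store, ind.birth_place, ind.birth_date, k)
            else:  # monthly
                vec = _monthly(store, ind.birth_place, ind.birth_date)
        if vec is None:
            missing.append(i)
        else:
            rows.append({"id": i, **vec})
    cols = ["id"] + WEATHER_VARS
    return pd.DataFrame(rows, columns=cols), missing


def _parse_policy(policy: str) -> tuple[str, int]:
    if policy == "exact":
        return "exact", 0
    if policy == "monthly":
        return "monthly", 0
    if policy.startswith("nearest:"):
        return "nearest", int(policy.split(":", 1)[1])
    raise ValueError(f"unknown join policy {policy!r}")


def _nearest(store: WeatherStore, place: str, day: date, k: int) -> dict | None:
    # candidates ordered by |offset| then by date (earlier wins ties)
    best = None
    for off in range(0, k + 1):
        for cand in (day - timedelta(days=off), day + timedelta(days=off)):
            if (place, cand) in store:
                best = store.get(place, cand)
                break
        if best is not None:
            break
    return best


def _monthly(store: WeatherStore, place: str, day: date) -> dict | None:
    days = [d for d in store.dates_for(place)
            if d.year == day.year and d.month == day.month]
    if not days:
        return None
    recs = pd.DataFrame([store.get(place, d) for d in days])
    return recs.mean(skipna=True).to_dict()
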