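"""Synthetic pedigrees, weather series and planted-correlation blocks.

Every stage of the analysis is testable without any download: this module
generates (a) multi-generation pedigrees with controllable assortative
mating, birth years spread over a configured range and birth places drawn
from a configured set; (b) per-place daily weather with realistic first
and second moments plus an annual seasonal cycle; and (c) paired Gaussian
blocks whose population first canonical correlation is planted exactly.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .pedigree import Individual, Pedigree, write_pedigree

__all__ = [
    "PlaceConfig",
    "SyntheticConfig",
    "simulate_pedigree",
    "simulate_weather",
    "simulate_linked_blocks",
    "end_to_end_fixture",
]


@dataclass(frozen=True)
class PlaceConfig:
    """Weather parameter set for one birth place (province-level station).

    Temperature means and the rainfall mean default to Mediterranean-
    climate daily values (°C, mm/day); the seasonal amplitude is the
    half-range of the annual temperature sinusoid.
    """

    name: str
    altitude: float = 400.0
    t_min_mean: float = 8.13
    t_max_mean: float = 18.92
    seasonal_amp: float = 7.0
    temp_noise_sd: float = 2.5
    rain_mean: float = 1.64
    rain_wet_prob: float = 0.25
    wind_mean: float = 3.5
    gust_extra_mean: float = 6.0
    sun_mean: float = 6.68
    pressure_mean: float = 1000.0
    pressure_sd: float = 8.0


@dataclass
class SyntheticConfig:
    n_founders: int = 60
    n_generations: int = 8
    n_pairs_per_generation: int = 110
    offspring_mean: float = 2.2
    assortative_prob: float = 0.1
    #: probability a parent goes unrecorded in the register (real studbooks
    #: are incomplete, which separates the three pedigree-depth measures)
    parent_unknown_prob: float = 0.08
    year_range: tuple[int, int] = (1950, 2019)
    places: list[PlaceConfig] = field(
        default_factory=lambda: [
            PlaceConfig("cordoba", altitude=120.0),
            PlaceConfig("granada", altitude=680.0, t_min_mean=6.0, t_max_mean=17.5),
            PlaceConfig("cadiz", altitude=10.0, t_min_mean=11.0, t_max_mean=21.0,
                        wind_mean=5.0, pressure_mean=1012.0),
        ]
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.assortative_prob <= 1.0:
            raise ValueError("assortative_prob must lie in [0, 1]")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must be ordered")
        if not self.places:
            raise ValueError("need at least one place")


def simulate_pedigree(config: SyntheticConfig) -> tuple[Pedigree, dict]:
    """Breed a pedigree generation by generation.

    Founders form generation 0.  Each later generation samples mating
    pairs from the previous one; with probability ``assortative_prob`` the
    pair is drawn relatives-first (half sibs or closer, when any exist).
    Birth years advance linearly through ``year_range`` with within-
    generation jitter; places are sampled uniformly.  The truth record
    stores each individual's generation and its parents' mating type.
    """
    rng = np.random.default_rng(config.seed)
    lo_year, hi_year = config.year_range
    span = hi_year - lo_year
    places = [pl.name for pl in config.places]

    individuals: list[Individual] = []
    truth: dict[str, dict] = {}
    parents_of: dict[str, tuple[str | None, str | None]] = {}

    def add(id_, sire, dam, sex, gen, mating):
        # registration gaps: the animal exists but a parent may be missing
        # from its register row
        if sire is not None and rng.random() < config.parent_unknown_prob:
            sire = None
        if dam is not None and rng.random() < config.parent_unknown_prob:
            dam = None
        year = lo_year + int(round(span * gen / max(config.n_generations, 1)))
        year = min(max(year + int(rng.integers(-1, 2)), lo_year), hi_year)
        bd = date(year, 1, 1) + timedelta(days=int(rng.integers(0, 365)))
        individuals.append(
            Individual(
                id=id_, sire_id=sire, dam_id=dam, sex=sex, birth_date=bd,
                birth_place=str(rng.choice(places)), country="ES",
            )
        )
        truth[id_] = {"generation": gen, "mating": mating}
        parents_of[id_] = (sire, dam)

    counter = 0

    def next_id():
        nonlocal counter
        counter += 1
        return f"H{counter:05d}"

    males: list[str] = []
    females: list[str] = []
    for _ in range(config.n_founders):
        sex = "male" if rng.random() < 0.5 else "female"
        id_ = next_id()
        add(id_, None, None, sex, 0, "founder")
        (males if sex == "male" else females).append(id_)

    for gen in range(1, config.n_generations + 1):
        if not males or not females:
            raise RuntimeError(
                "population went extinct (no eligible pairs); "
                "increase n_founders"
            )
        new_m, new_f = [], []
        for _ in range(config.n_pairs_per_generation):
            sire, dam, mating = _draw_pair(
                males, females, parents_of, config.assortative_prob, rng
            )
            litter = max(1, int(rng.poisson(config.offspring_mean)))
            for _ in range(litter):
                sex = "male" if rng.random() < 0.5 else "female"
                id_ = next_id()
                add(id_, sire, dam, sex, gen, mating)
                (new_m if sex == "male" else new_f).append(id_)
        males, females = new_m, new_f

    return Pedigree(individuals), truth


def _draw_pair(males, females, parents_of, assort_p, rng):
    """Sample a (sire, dam); relatives-first with probability assort_p."""
    sire = males[int(rng.integers(len(males)))]
    if rng.random() < assort_p:
        sp = set(p for p in parents_of[sire] if p is not None)
        if sp:
            related = [f for f in females
                       if sp & set(p for p in parents_of[f] if p is not None)]
            if related:
                return sire, related[int(rng.integers(len(related)))], "related"
    return sire, females[int(rng.integers(len(females)))], "random"


def simulate_weather(config: SyntheticConfig) -> pd.DataFrame:
    """Daily weather for every place over the configured year range.

    Temperatures follow a seasonal sinusoid plus Gaussian noise with
    t_min < t_max enforced by construction; rainfall is zero-inflated
    gamma; wind direction is von Mises on the tenths-of-degree scale
    (0–36); gust speed is average wind speed plus a positive excess;
    sunlight lies in [0, day length]; pressures vary around the place
    mean with p_min ≤ p_max.
    """
    rng = np.random.default_rng(config.seed + 1)
    start = date(config.year_range[0], 1, 1)
    end = date(config.year_range[1], 12, 31)
    days = pd.date_range(start, end, freq="D")
    doy = days.dayofyear.to_numpy()
    n = len(days)

    frames = []
    for pl in config.places:
        # independent day-to-day noise on tmin and tmax keeps their
        # correlation near real station values (~0.8) instead of ~1
        season = pl.seasonal_amp * np.sin(2 * np.pi * (doy - 110) / 365.25)
        tmin = pl.t_min_mean + season + rng.normal(0, pl.temp_noise_sd, n)
        tmax = pl.t_max_mean + season + rng.normal(0, pl.temp_noise_sd, n)
        tmax = np.maximum(tmax, tmin + 0.3)

        wet = rng.random(n) < pl.rain_wet_prob
        rain = np.where(
            wet, rng.gamma(0.9, pl.rain_mean / pl.rain_wet_prob / 0.9, n), 0.0
        )

        wdir_rad = rng.vonmises(np.pi * 0.8, 0.8, n)  # prevailing westerlies
        wdir = (np.degrees(wdir_rad) % 360.0) / 10.0

        wspd = rng.gamma(2.0, pl.wind_mean / 2.0, n)
        gust = wspd + rng.gamma(2.0, pl.gust_extra_mean / 2.0, n)

        daylength = 12.0 + 3.0 * np.sin(2 * np.pi * (doy - 80) / 365.25)
        sun = np.clip(
            pl.sun_mean / 12.0 * daylength + rng.normal(0, 2.0, n), 0.0, daylength
        )

        pmid = pl.pressure_mean + rng.normal(0, pl.pressure_sd, n)
        phalf = np.abs(rng.normal(0, 2.0, n)) + 0.5
        frames.append(pd.DataFrame({
            "place": pl.name,
            "date": days.date,
            "altitude": pl.altitude,
            "rain": np.round(rain, 2),
            "tmin": np.round(tmin, 2),
            "tmax": np.round(tmax, 2),
            "wdir": np.round(wdir, 2),
            "wspd": np.round(wspd, 2),
            "gust": np.round(gust, 2),
            "sun": np.round(sun, 2),
            "pmin": np.round(pmid - phalf, 2),
            "pmax": np.round(pmid + phalf, 2),
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_linked_blocks(
    n: int, p: int, q: int, rho: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Paired Gaussian blocks with an exactly planted canonical structure.

    A latent standard normal u drives both blocks through unit direction
    vectors a, b:  X = √ρ·u·aᵀ + E_x with Cov(E_x) = I − ρ aaᵀ (and
    likewise for Y), so the population covariances are Σxx = Σyy = I,
    Σxy = ρ abᵀ — the first canonical correlation is ρ exactly and every
    other one is 0.  The noise variance is solved analytically rather
    than by post-hoc rotation.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    if n <= p + q:
        raise ValueError("need n > p + q")
    rng = np.random.default_rng(seed)
    a = rng.normal(size=p)
    a /= np.linalg.norm(a)
    b = rng.normal(size=q)
    b /= np.linalg.norm(b)
    u = rng.normal(size=n)

    def block(w, dim):
        E0 = rng.normal(size=(n, dim))
        # (I − ρ wwᵀ)^{1/2} = I − (1 − √(1−ρ)) wwᵀ for unit w
        E = E0 - (1.0 - np.sqrt(1.0 - rho)) * np.outer(E0 @ w, w)
        return np.sqrt(rho) * np.outer(u, w) + E

    X = block(a, p)
    Y = block(b, q)
    return X, Y, {"a": a, "b": b, "rho": rho}


def end_to_end_fixture(
    out_dir, config: SyntheticConfig | None = None
) -> dict:
    """Write a complete small study dataset for full-pipeline runs.

    Produces ``pedigree.csv``, ``weather.csv`` and ``truth.json`` in
    ``out_dir``.  The weather table carries two deliberately redundant
    columns — average temperature (≈ mean of min/max) and maximum
    barometric pressure (≈ minimum + small positive offset) — so the
    collinearity screen has planted exclusions to find.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config is None:
        config = SyntheticConfig()
    ped, truth = simulate_pedigree(config)
    weather = simulate_weather(config)
    rng = np.random.default_rng(config.seed + 2)
    weather.insert(
        weather.columns.get_loc("tmax") + 1,
        "tavg",
        np.round((weather["tmin"] + weather["tmax"]) / 2.0
                 + rng.normal(0, 0.05, len(weather)), 2),
    )

    ped_path = out / "pedigree.csv"
    weather_path = out / "weather.csv"
    write_pedigree(ped, ped_path)
    weather.to_csv(weather_path, index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(
            {
                "n_individuals": len(ped),
                "planted_redundant": ["tavg", "pmax"],
                "generations": truth,
            },
            fh,
            indent=1,
        )
    return {
        "pedigree": ped_path,
        "weather": weather_path,
        "truth": out / "truth.json",
        "planted_redundant": ["tavg", "pmax"],
    }
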