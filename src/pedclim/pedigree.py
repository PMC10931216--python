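"""Pedigree container: loading, validation, ordering, pruning, navigation.

A pedigree is a directed acyclic graph of individuals linked to their sire
and dam.  Founders are individuals with both parents unknown.  Studbook
exports differ in how they encode an unknown parent (empty cell, ``0``, a
registry-specific token); all are normalised to ``None`` internally.
"""

from __future__ import annotations

import csv
import io
import logging
import warnings
from dataclasses import dataclass, field
from datetime import date

import pandas as pd

logger = logging.getLogger(__name__)

#: tokens always interpreted as "parent unknown"
DEFAULT_UNKNOWN_TOKENS = ("", "0", "NA", "na", "nan", "None")

SEXES = ("male", "female", "unknown")


class PedigreeError(ValueError):
    """Invalid pedigree structure or malformed input."""


@dataclass(frozen=True)
class Individual:
    """One pedigree entry.  ``sire_id``/``dam_id`` are ``None`` when unknown."""

    id: str
    sire_id: str | None = None
    dam_id: str | None = None
    sex: str = "unknown"
    birth_date: date | None = None
    birth_place: str | None = None
    country: str | None = None
    inaccurate_location: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise PedigreeError("individual id must be non-empty")
        if self.sire_id == self.id or self.dam_id == self.id:
            raise PedigreeError(f"individual {self.id!r} is its own parent")

    @property
    def is_founder(self) -> bool:
        return self.sire_id is None and self.dam_id is None

    @property
    def known_parents(self) -> tuple[str, ...]:
        return tuple(p for p in (self.sire_id, self.dam_id) if p is not None)


@dataclass
class PruneReport:
    """Counts of individuals removed from the study set, per category."""

    n_initial: int
    per_category: dict[str, int] = field(default_factory=dict)

    @property
    def n_discarded(self) -> int:
        return sum(self.per_category.values())

    @property
    def n_final(self) -> int:
        return self.n_initial - self.n_discarded


class Pedigree:
    """Id-indexed, topologically orderable collection of individuals."""

    def __init__(self, individuals: list[Individual]):
        self._by_id: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self._by_id:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            self._by_id[ind.id] = ind
        self._materialize_missing_parents()
        self._order = self._toposort()

    def _materialize_missing_parents(self) -> None:
        missing: list[str] = []
        for ind in list(self._by_id.values()):
            for pid in ind.known_parents:
                if pid not in self._by_id and pid not in missing:
                    missing.append(pid)
        for pid in missing:
            logger.warning("parent %r has no pedigree row; created as founder", pid)
            self._by_id[pid] = Individual(id=pid)

    def _toposort(self) -> list[str]:
        # Kahn's algorithm, ties broken by input order so the result is
        # deterministic and founders keep their file order.
        in_deg = {i: len(ind.known_parents) for i, ind in self._by_id.items()}
        children: dict[str, list[str]] = {i: [] for i in self._by_id}
        for ind in self._by_id.values():
            for pid in ind.known_parents:
                children[pid].append(ind.id)
        order = [i for i, d in in_deg.items() if d == 0]
        head = 0
        while head < len(order):
            for c in children[order[head]]:
                in_deg[c] -= 1
                if in_deg[c] == 0:
                    order.append(c)
            head += 1
        if len(order) != len(self._by_id):
            on_cycle = sorted(i for i, d in in_deg.items() if d > 0)
            raise PedigreeError(f"ancestry cycle involving individual {on_cycle[0]!r}")
        # stable: keep relative input order among unconstrained individuals
        rank = {i: n for n, i in enumerate(self._by_id)}
        depth: dict[str, int] = {}
        for i in order:
            ps = self._by_id[i].known_parents
            depth[i] = 1 + max((depth[p] for p in ps), default=-1)
        return sorted(self._by_id, key=lambda i: (depth[i], rank[i]))

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._by_id)

    def __contains__(self, id: str) -> bool:
        return id in self._by_id

    def __getitem__(self, id: str) -> Individual:
        return self._by_id[id]

    def __iter__(self):
        return iter(self._order)

    @property
    def ids(self) -> list[str]:
        """All ids in topological order (parents before offspring)."""
        return list(self._order)

    @property
    def founder_set(self) -> set[str]:
        return {i for i, ind in self._by_id.items() if ind.is_founder}

    def individuals(self) -> list[Individual]:
        return [self._by_id[i] for i in self._order]


def _parse_date(token: str, row: int) -> date | None:
    """ISO-8601 dates; month precision allowed and mapped to day 15."""
    token = token.strip()
    if not token or token in DEFAULT_UNKNOWN_TOKENS:
        return None
    parts = token.split("-")
    try:
        if len(parts) == 2:  # YYYY-MM, common in 1950s records
            d = date(int(parts[0]), int(parts[1]), 15)
            logger.info("row %d: month-precision date %r mapped to %s", row, token, d)
            return d
        if len(parts) == 3:
            return date(int(parts[0]), int(parts[1]), int(parts[2]))
    except ValueError as exc:
        raise PedigreeError(f"row {row}: malformed date {token!r}: {exc}") from exc
    raise PedigreeError(f"row {row}: malformed date {token!r}")


def _norm_parent(token, unknown_tokens: tuple[str, ...]) -> str | None:
    if token is None:
        return None
    token = str(token).strip()
    return None if token in unknown_tokens else token


def load_pedigree(
    source,
    unknown_tokens: tuple[str, ...] = DEFAULT_UNKNOWN_TOKENS,
    birth_year_range: tuple[int, int] | None = None,
) -> Pedigree:
    """Read a delimited pedigree table (comma or tab, autodetected).

    Required columns ``id,sire,dam``; optional ``sex,birth_date,birth_place,
    country,inaccurate_location``.  Parents referenced but absent as rows are
    created as founders with a warning.

    Parameters
    ----------
    source
        Path or file-like object.
    unknown_tokens
        Strings treated as "parent unknown".
    birth_year_range
        If given, a known birth date outside ``[lo, hi]`` raises.
    """
    df = _read_table(source)
    required = {"id", "sire", "dam"}
    if not required.issubset(df.columns):
        raise PedigreeError(f"pedigree table needs columns {sorted(required)}")

    individuals: list[Individual] = []
    for row_no, rec in enumerate(df.to_dict("records"), start=2):
        bd = _parse_date(str(rec.get("birth_date", "") or ""), row_no)
        if bd is not None and birth_year_range is not None:
            lo, hi = birth_year_range
            if not lo <= bd.year <= hi:
                raise PedigreeError(
                    f"row {row_no}: birth year {bd.year} outside [{lo}, {hi}]"
                )
        sex = str(rec.get("sex", "") or "unknown").strip() or "unknown"
        if sex not in SEXES:
            raise PedigreeError(f"row {row_no}: unknown sex {sex!r}")
        place = str(rec.get("birth_place", "") or "").strip() or None
        country = str(rec.get("country", "") or "").strip() or None
        inacc = str(rec.get("inaccurate_location", "") or "").strip() in ("1", "true", "True")
        individuals.append(
            Individual(
                id=str(rec["id"]).strip(),
                sire_id=_norm_parent(rec.get("sire"), unknown_tokens),
                dam_id=_norm_parent(rec.get("dam"), unknown_tokens),
                sex=sex,
                birth_date=bd,
                birth_place=place,
                country=country,
                inaccurate_location=inacc,
            )
        )
    return Pedigree(individuals)


def _read_table(source) -> pd.DataFrame:
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, newline="") as fh:
            text = fh.read()
    delim = "\t" if "\t" in text.splitlines()[0] else ","
    return pd.read_csv(io.StringIO(text), sep=delim, dtype=str, keep_default_na=False)


def write_pedigree(p: Pedigree, path) -> None:
    """Canonical dialect: comma, minimal quoting, LF endings, fixed columns."""
    cols = ["id", "sire", "dam", "sex", "birth_date", "birth_place", "country",
            "inaccurate_location"]
    with open(path, "w", newline="\n") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(cols)
        for ind in p.individuals():
            w.writerow([
                ind.id,
                ind.sire_id or "",
                ind.dam_id or "",
                "" if ind.sex == "unknown" else ind.sex,
                ind.birth_date.isoformat() if ind.birth_date else "",
                ind.birth_place or "",
                ind.country or "",
                "1" if ind.inaccurate_location else "",
            ])


def topological_order(p: Pedigree) -> list[str]:
    """Ids ordered parents-before-offspring, ties by input order."""
    return p.ids


def prune_study_set(
    p: Pedigree,
    climate_coverage: dict[str, tuple[date, date]] | None = None,
    home_country: str | None = None,
) -> tuple[list[str], PruneReport]:
    """Select the study set, mirroring the four studbook pruning categories.

    Categories are applied in order, each individual counted once:

    1. ``birthplace_unregistered`` — no birth place on record;
    2. ``foreign_born`` — country differs from ``home_country``;
    3. ``no_climate_registry`` — no weather coverage for the birth place and
       date (``climate_coverage`` maps place -> (first, last) covered date);
    4. ``location_inaccuracy`` — flagged imprecise birth location.

    Pruning defines the *analysis* set only; genetic parameters are still
    computed on the full historical pedigree, pruned ancestors included.
    """
    cats = {
        "birthplace_unregistered": 0,
        "foreign_born": 0,
        "no_climate_registry": 0,
        "location_inaccuracy": 0,
    }
    kept: list[str] = []
    for ind in p.individuals():
        if ind.birth_place is None:
            cats["birthplace_unregistered"] += 1
            continue
        if home_country is not None and ind.country is not None and ind.country != home_country:
            cats["foreign_born"] += 1
            continue
        if climate_coverage is not None:
            span = climate_coverage.get(ind.birth_place)
            covered = (
                span is not None
                and ind.birth_date is not None
                and span[0] <= ind.birth_date <= span[1]
            )
            if not covered:
                cats["no_climate_registry"] += 1
                continue
        if ind.inaccurate_location:
            cats["location_inaccuracy"] += 1
            continue
        kept.append(ind.id)
    if not kept:
        warnings.warn("pruning left an empty study set", stacklevel=2)
    return kept, PruneReport(n_initial=len(p), per_category=cats)


def offspring_counts(p: Pedigree) -> dict[str, int]:
    """Number of pedigree rows naming each individual as sire or dam."""
    counts = {i: 0 for i in p.ids}
    for ind in p.individuals():
        for pid in ind.known_parents:
            counts[pid] += 1
    return counts
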