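"""Per-individual pedigree genetic diversity parameters.

Implements the classical tabular machinery of pedigree analysis:

* inbreeding ``F`` by the Meuwissen–Luo within-ancestor-list algorithm
  (linear memory, no relationship matrix is ever materialised);
* pairwise coancestry ``f(i, j)`` by the tabular kinship recursion;
* average relatedness ``AR`` (mean additive relationship with the whole
  pedigree, self included);
* pedigree completeness: maximum, complete and equivalent generations;
* per-generation rates ``ΔF`` and ``ΔC`` normalising F and C by pedigree
  depth;
* non-random mating degree ``α`` solving (1 − F) = (1 − C)(1 − α);
* founder genome contributions and the Genetic Conservation Index
  ``GCI = 1 / Σ P_i²`` (effective number of founders in a pedigree).
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import Pedigree, offspring_counts

__all__ = [
    "inbreeding",
    "CoancestryCalculator",
    "coancestry",
    "average_relatedness",
    "generation_measures",
    "delta_F",
    "delta_C",
    "non_random_mating",
    "founder_contributions",
    "gci",
    "diversity_table",
    "DiversityRecord",
]


@dataclass(frozen=True)
class DiversityRecord:
    """All per-individual diversity parameters for one animal."""

    id: str
    F: float
    AR: float
    mean_coancestry: float
    alpha: float
    GCI: float
    max_gen: int
    complete_gen: int
    equiv_gen: float
    delta_F: float
    offspring: int


# ---------------------------------------------------------------------------
# inbreeding: Meuwissen & Luo ancestor-list algorithm
# ---------------------------------------------------------------------------

def inbreeding(p: Pedigree) -> dict[str, float]:
    """Inbreeding coefficient of every individual.

    ``F_i`` is the kinship of i's parents; individuals with an unknown
    parent get 0.  Computed by walking each animal's ancestor list once,
    accumulating the diagonal of the numerator relationship matrix
    ``A_ii = Σ_j L_ij² D_j`` without storing A.  ``D_j`` uses the convention
    that an unknown parent contributes F = −1, so founders get D = 1.
    """
    order = p.ids
    idx = {i: n for n, i in enumerate(order)}
    sire = np.full(len(order), -1, dtype=np.int64)
    dam = np.full(len(order), -1, dtype=np.int64)
    for n, i in enumerate(order):
        ind = p[i]
        if ind.sire_id is not None:
            sire[n] = idx[ind.sire_id]
        if ind.dam_id is not None:
            dam[n] = idx[ind.dam_id]

    F = np.zeros(len(order))
    D = np.empty(len(order))
    for n in range(len(order)):
        fs = F[sire[n]] if sire[n] >= 0 else -1.0
        fd = F[dam[n]] if dam[n] >= 0 else -1.0
        D[n] = 0.5 - 0.25 * (fs + fd)
        if sire[n] < 0 or dam[n] < 0:
            F[n] = 0.0
            continue
        # trace the ancestor list of n, highest topological index first
        coeff: dict[int, float] = {n: 1.0}
        a_ii = 0.0
        while coeff:
            j = max(coeff)
            v = coeff.pop(j)
            a_ii += v * v * D[j]
            half = v * 0.5
            for par in (sire[j], dam[j]):
                if par >= 0:
                    coeff[par] = coeff.get(par, 0.0) + half
        F[n] = a_ii - 1.0
    return {i: float(F[n]) for n, i in enumerate(order)}


# ---------------------------------------------------------------------------
# coancestry (kinship)
# ---------------------------------------------------------------------------

class CoancestryCalculator:
    """Memoised tabular kinship on a pedigree.

    ``f(i, j) = ½ [f(sire_i, j) + f(dam_i, j)]`` for i topologically after
    j, ``f(i, i) = ½ (1 + F_i)``, unknown parents contribute 0.
    """

    def __init__(self, p: Pedigree):
        self._p = p
        self._rank = {i: n for n, i in enumerate(p.ids)}
        self._memo: dict[tuple[str, str], float] = {}

    def __call__(self, i: str, j: str) -> float:
        if i not in self._p or j not in self._p:
            raise KeyError(f"unknown individual in kinship query: {i!r}, {j!r}")
        need = sys.getrecursionlimit()
        if len(self._p) * 4 > need:
            sys.setrecursionlimit(len(self._p) * 4 + 1000)
        return self._f(i, j)

    def _f(self, i: str, j: str) -> float:
        if self._rank[i] < self._rank[j]:
            i, j = j, i
        key = (i, j)
        val = self._memo.get(key)
        if val is not None:
            return val
        ind = self._p[i]
        if i == j:
            s, d = ind.sire_id, ind.dam_id
            fi = self._f(s, d) if (s is not None and d is not None) else 0.0
            val = 0.5 * (1.0 + fi)
        else:
            val = 0.0
            if ind.sire_id is not None:
                val += 0.5 * self._f(ind.sire_id, j)
            if ind.dam_id is not None:
                val += 0.5 * self._f(ind.dam_id, j)
        self._memo[key] = val
        return val


def coancestry(p: Pedigree, i: str, j: str) -> float:
    """One-off kinship query (builds a calculator; reuse it for many pairs)."""
    return CoancestryCalculator(p)(i, j)


# ---------------------------------------------------------------------------
# average relatedness
# ---------------------------------------------------------------------------

def _relationship_matrix(p: Pedigree) -> np.ndarray:
    """Numerator relationship matrix A in topological order (dense)."""
    order = p.ids
    idx = {i: n for n, i in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for k, i in enumerate(order):
        ind = p[i]
        s = idx.get(ind.sire_id) if ind.sire_id is not None else None
        d = idx.get(ind.dam_id) if ind.dam_id is not None else None
        row = np.zeros(k)
        if s is not None:
            row += 0.5 * A[s, :k]
        if d is not None:
            row += 0.5 * A[d, :k]
        A[k, :k] = row
        A[:k, k] = row
        A[k, k] = 1.0 + (0.5 * A[s, d] if (s is not None and d is not None) else 0.0)
    return A


def average_relatedness(p: Pedigree, dense_threshold: int = 20_000) -> dict[str, float]:
    """Mean additive relationship of each individual with the whole pedigree.

    ``AR_i = (1/n) Σ_j a_ij`` with the individual itself included.  Uses the
    dense tabular matrix up to ``dense_threshold`` individuals; beyond that
    the row sums are accumulated block-wise from the same recursion so only
    O(n · block) memory is held at once.
    """
    order = p.ids
    n = len(order)
    if n <= dense_threshold:
        A = _relationship_matrix(p)
        sums = A.sum(axis=0)
    else:  # row-block evaluation: column sums accumulate through the recursion
        idx = {i: k for k, i in enumerate(order)}
        calc = CoancestryCalculator(p)
        sums = np.zeros(n)
        for k, i in enumerate(order):
            for j in order:
                sums[k] += 2.0 * calc(i, j)
    return {i: float(sums[k] / n) for k, i in enumerate(order)}


# ---------------------------------------------------------------------------
# pedigree completeness
# ---------------------------------------------------------------------------

def generation_measures(p: Pedigree) -> dict[str, tuple[int, int, float]]:
    """(max_gen, complete_gen, equiv_gen) per individual.

    * max_gen: generations to the earliest known ancestor (longest path);
    * complete_gen: deepest generation at which *all* ancestor slots are
      known;
    * equiv_gen: Σ (1/2)^g over every known ancestor slot — a fractional
      depth satisfying complete_gen ≤ equiv_gen ≤ max_gen.
    """
    maxg: dict[str, int] = {}
    compg: dict[str, int] = {}
    eqg: dict[str, float] = {}
    for i in p.ids:
        ind = p[i]
        s, d = ind.sire_id, ind.dam_id
        if s is None and d is None:
            maxg[i], compg[i], eqg[i] = 0, 0, 0.0
            continue
        maxg[i] = 1 + max(maxg[par] for par in ind.known_parents)
        compg[i] = (1 + min(compg[s], compg[d])) if (s is not None and d is not None) else 0
        eqg[i] = sum(0.5 * (1.0 + eqg[par]) for par in ind.known_parents)
    return {i: (maxg[i], compg[i], eqg[i]) for i in p.ids}


# ---------------------------------------------------------------------------
# per-generation rates and mating structure
# ---------------------------------------------------------------------------

def delta_F(F: float, t: float) -> float:
    """Individual inbreeding rate ΔF = 1 − (1 − F)^(1/(t − 1)).

    Undefined at t ≤ 1 (a single known generation cannot express a
    per-generation rate): returns 0 there, and for F = 0.
    """
    if not 0.0 <= F < 1.0:
        raise ValueError(f"F must lie in [0, 1), got {F}")
    if F == 0.0 or t <= 1.0:
        return 0.0
    return 1.0 - (1.0 - F) ** (1.0 / (t - 1.0))


def delta_C(C: float, t_a: float, t_b: float) -> float:
    """Pairwise coancestry rate ΔC = 1 − (1 − C)^(1/((t_a + t_b)/2))."""
    if not 0.0 <= C < 1.0:
        raise ValueError(f"C must lie in [0, 1), got {C}")
    t = 0.5 * (t_a + t_b)
    if t == 0.0:
        warnings.warn("delta_C with zero mean pedigree depth; returning 0", stacklevel=2)
        return 0.0
    return 1.0 - (1.0 - C) ** (1.0 / t)


def non_random_mating(F: float, C_ref: float) -> float:
    """Degree of assortative mating α solving (1 − F) = (1 − C)(1 − α)."""
    if C_ref >= 1.0:
        raise ValueError(f"reference coancestry must be < 1, got {C_ref}")
    return 1.0 - (1.0 - F) / (1.0 - C_ref)


# ---------------------------------------------------------------------------
# founder contributions / GCI
# ---------------------------------------------------------------------------

def founder_contributions(
    p: Pedigree, i: str | None = None, phantom_unknown: bool = False
):
    """Expected founder genome proportions P = Σ_paths (1/2)^n.

    Dynamic programme over the DAG: vector(i) = ½ vector(sire) + ½
    vector(dam); a founder's vector is {self: 1}.  By default an
    unknown-parent slot contributes nothing and no renormalisation is
    applied, so Σ P_i < 1 is possible for incomplete pedigrees and the
    GCI formula consumes the raw Σ P_i².  With ``phantom_unknown`` each
    unknown slot is a distinct phantom founder (keyed ``(id, slot)``), so
    Σ P_i = 1 always and GCI stays bounded by the recorded founder count.

    Returns the vector for ``i``, or a dict of vectors for all ids when
    ``i`` is None.
    """
    if i is not None and i not in p:
        raise KeyError(f"unknown individual {i!r}")
    vecs: dict[str, dict] = {}
    for j in p.ids:
        ind = p[j]
        if ind.is_founder:
            vecs[j] = {j: 1.0}
            continue
        v: dict = {}
        for slot, par in (("s", ind.sire_id), ("d", ind.dam_id)):
            if par is not None:
                for f, w in vecs[par].items():
                    v[f] = v.get(f, 0.0) + 0.5 * w
            elif phantom_unknown:
                v[(j, slot)] = 0.5
        vecs[j] = v
    return vecs[i] if i is not None else vecs


def gci(contributions: dict[str, float]) -> float:
    """Genetic Conservation Index 1 / Σ P_i² (effective founder number)."""
    if not contributions:
        raise ValueError("empty founder-contribution vector")
    return 1.0 / sum(w * w for w in contributions.values())


# ---------------------------------------------------------------------------
# one-stop table
# ---------------------------------------------------------------------------

def diversity_table(
    p: Pedigree,
    alpha_reference: str = "cohort",
    f_pct: bool = False,
) -> pd.DataFrame:
    """Every DiversityRecord field for every individual, as a DataFrame.

    ``alpha_reference`` selects the reference coancestry C̄ for α: the mean
    kinship with the individual's birth-year cohort (default) or with the
    whole population (``"population"``).  ``mean_coancestry`` in the output
    is always AR/2, the population-mean kinship.
    """
    order = p.ids
    F = inbreeding(p)
    AR = average_relatedness(p)
    gens = generation_measures(p)
    offs = offspring_counts(p)
    contribs = founder_contributions(p)

    mean_c = {i: AR[i] / 2.0 for i in order}
    if alpha_reference == "population":
        c_ref = mean_c
    elif alpha_reference == "cohort":
        calc = CoancestryCalculator(p)
        cohorts: dict[int | None, list[str]] = {}
        for i in order:
            bd = p[i].birth_date
            cohorts.setdefault(bd.year if bd else None, []).append(i)
        c_ref = {}
        for members in cohorts.values():
            for i in members:
                c_ref[i] = float(np.mean([calc(i, j) for j in members]))
    else:
        raise ValueError(f"unknown alpha_reference {alpha_reference!r}")

    rows = []
    for i in order:
        mg, cg, eg = gens[i]
        rows.append(
            DiversityRecord(
                id=i,
                F=F[i],
                AR=AR[i],
                mean_coancestry=mean_c[i],
                alpha=non_random_mating(F[i], c_ref[i]),
                GCI=gci(contribs[i]),
                max_gen=mg,
                complete_gen=cg,
                equiv_gen=eg,
                delta_F=delta_F(F[i], eg),
                offspring=offs[i],
            )
        )
    df = pd.DataFrame([r.__dict__ for r in rows]).rename(
        columns={"mean_coancestry": "meanC"}
    )
    if f_pct:
        for col in ("F", "AR", "meanC", "delta_F"):
            df[col] = df[col] * 100.0
    return df[
        ["id", "F", "AR", "meanC", "alpha", "GCI", "max_gen", "complete_gen",
         "equiv_gen", "delta_F", "offspring"]
    ]
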