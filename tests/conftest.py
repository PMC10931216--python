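import io

import numpy as np
import pytest

from pedclim.pedigree import Individual, Pedigree, load_pedigree

PED5_CSV = "id,sire,dam\n1,,\n2,,\n3,1,2\n4,1,2\n5,3,4\n"


@pytest.fixture
def ped5() -> Pedigree:
    """Two founders, two full sibs, one full-sib-mating offspring."""
    return load_pedigree(io.StringIO(PED5_CSV))


def random_pedigree(seed: int, n: int, p_known: float = 0.75) -> Pedigree:
    """A random valid pedigree: individual k draws each parent from the
    earlier individuals with probability ``p_known``."""
    rng = np.random.default_rng(seed)
    inds = []
    for k in range(n):
        sire = dam = None
        if k >= 2:
            if rng.random() < p_known:
                sire = f"I{rng.integers(k)}"
            if rng.random() < p_known:
                dam = f"I{rng.integers(k)}"
            if sire is not None and sire == dam:
                dam = None
        inds.append(Individual(id=f"I{k}", sire_id=sire, dam_id=dam))
    return Pedigree(inds)


def wright_inbreeding(p: Pedigree) -> dict[str, float]:
    """Exhaustive path-counting oracle for inbreeding coefficients.

    F_i sums, over every common ancestor A of i's parents and every pair
    of ascending paths (sire→A, dam→A) sharing no individual except A,
    (1/2)^(n1+n2+1) (1 + F_A).  Exponential in pedigree depth; only for
    small test pedigrees.
    """
    paths_memo: dict[str, list[list[str]]] = {}

    def up_paths(x: str) -> list[list[str]]:
        if x in paths_memo:
            return paths_memo[x]
        out = [[x]]
        for par in p[x].known_parents:
            out.extend([x] + rest for rest in up_paths(par))
        paths_memo[x] = out
        return out

    F: dict[str, float] = {}
    for i in p.ids:  # topological order: ancestors first
        ind = p[i]
        if ind.sire_id is None or ind.dam_id is None:
            F[i] = 0.0
            continue
        total = 0.0
        for p1 in up_paths(ind.sire_id):
            set1 = set(p1)
            for p2 in up_paths(ind.dam_id):
                if p1[-1] != p2[-1]:
                    continue
                anc = p1[-1]
                if set1 & set(p2) != {anc}:
                    continue
                total += 0.5 ** (len(p1) + len(p2) - 1) * (1.0 + F[anc])
        F[i] = total
    return F


def classical_cca_correlations(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Brute-force classical CCA oracle: direct solution of the
    generalized eigenproblem on the sample correlation matrices."""
    from pedclim.rcca import pearson_matrix

    Rxx, Ryy, Rxy = pearson_matrix(X, Y)
    M = np.linalg.solve(Rxx, Rxy) @ np.linalg.solve(Ryy, Rxy.T)
    eig = np.sort(np.linalg.eigvals(M).real)[::-1]
    s = min(X.shape[1], Y.shape[1])
    return np.sqrt(np.clip(eig[:s], 0.0, 1.0))
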