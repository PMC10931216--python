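import io

import numpy as np
import pytest

from pedclim.diversity import (
    CoancestryCalculator,
    average_relatedness,
    coancestry,
    delta_C,
    delta_F,
    diversity_table,
    founder_contributions,
    gci,
    generation_measures,
    inbreeding,
    non_random_mating,
)
from pedclim.pedigree import Individual, Pedigree, load_pedigree

from conftest import random_pedigree, wright_inbreeding


class TestInbreeding:
    def test_full_sib_mating_quarter(self, ped5):
        assert inbreeding(ped5)["5"] == pytest.approx(0.25, abs=1e-15)

    def test_founders_zero(self, ped5):
        F = inbreeding(ped5)
        assert F["1"] == 0.0 and F["2"] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_path_counting_oracle(self, seed):
        p = random_pedigree(seed=seed, n=50)
        F = inbreeding(p)
        oracle = wright_inbreeding(p)
        for i in p.ids:
            assert F[i] == pytest.approx(oracle[i], abs=1e-12)

    def test_equals_parental_kinship(self):
        p = random_pedigree(seed=99, n=80)
        F = inbreeding(p)
        calc = CoancestryCalculator(p)
        for i in p.ids:
            ind = p[i]
            if ind.sire_id is not None and ind.dam_id is not None:
                assert F[i] == pytest.approx(
                    calc(ind.sire_id, ind.dam_id), abs=1e-12
                )


class TestCoancestry:
    def test_unrelated_founders_zero(self, ped5):
        assert coancestry(ped5, "1", "2") == 0.0

    def test_full_sibs_quarter(self, ped5):
        assert coancestry(ped5, "3", "4") == pytest.approx(0.25)

    def test_grandchild_recursion(self, ped5):
        # f(5,1) = ½(f(3,1) + f(4,1)) with both halves 0.25
        assert coancestry(ped5, "5", "1") == pytest.approx(0.25)

    def test_symmetry_and_self_identity(self):
        p = random_pedigree(seed=3, n=60)
        calc = CoancestryCalculator(p)
        F = inbreeding(p)
        rng = np.random.default_rng(0)
        ids = p.ids
        for _ in range(50):
            i, j = rng.choice(ids, 2)
            assert calc(i, j) == pytest.approx(calc(j, i), abs=1e-15)
        for i in ids:
            assert 2.0 * calc(i, i) - 1.0 == pytest.approx(F[i], abs=1e-12)

    def test_unknown_id_errors(self, ped5):
        with pytest.raises(KeyError):
            coancestry(ped5, "1", "nope")


class TestAverageRelatedness:
    def test_two_unrelated_founders(self):
        p = Pedigree([Individual(id="a"), Individual(id="b")])
        AR = average_relatedness(p)
        assert AR == {"a": 0.5, "b": 0.5}

    def test_single_individual(self):
        p = Pedigree([Individual(id="a")])
        assert average_relatedness(p)["a"] == 1.0

    def test_ped5_value(self, ped5):
        assert average_relatedness(ped5)["5"] == pytest.approx(0.75)

    def test_block_path_agrees_with_dense(self):
        p = random_pedigree(seed=11, n=40)
        dense = average_relatedness(p)
        blocked = average_relatedness(p, dense_threshold=10)
        for i in p.ids:
            assert blocked[i] == pytest.approx(dense[i], abs=1e-12)


class TestGenerations:
    def test_complete_two_generation_pedigree(self, ped5):
        assert generation_measures(ped5)["5"] == (2, 2, 2.0)

    def test_parents_only(self):
        p = load_pedigree(io.StringIO("id,sire,dam\na,,\nb,,\nc,a,b\n"))
        assert generation_measures(p)["c"] == (1, 1, 1.0)

    def test_single_known_parent(self):
        p = load_pedigree(io.StringIO("id,sire,dam\na,,\nc,a,\n"))
        assert generation_measures(p)["c"] == (1, 0, 0.5)

    def test_ordering_invariant_and_complete_depth(self):
        # complete_gen <= equiv_gen <= max_gen everywhere; a fully known
        # pedigree to depth g has equiv_gen exactly g
        p = random_pedigree(seed=5, n=120)
        for mg, cg, eg in generation_measures(p).values():
            assert cg <= eg + 1e-12 and eg <= mg + 1e-12
        rows = [Individual(id="f1"), Individual(id="f2"), Individual(id="f3"),
                Individual(id="f4")]
        rows += [Individual(id="m1", sire_id="f1", dam_id="f2"),
                 Individual(id="m2", sire_id="f3", dam_id="f4"),
                 Individual(id="kid", sire_id="m1", dam_id="m2")]
        assert generation_measures(Pedigree(rows))["kid"] == (2, 2, 2.0)


class TestRatesAndAlpha:
    @pytest.mark.parametrize("F,t,expected", [
        (0.0, 7.0, 0.0),
        (0.25, 2.0, 0.25),
        (0.19, 5.0, 1.0 - 0.81 ** 0.25),
        (0.1, 1.0, 0.0),  # undefined depth -> 0 by convention
    ])
    def test_delta_F(self, F, t, expected):
        assert delta_F(F, t) == pytest.approx(expected, abs=1e-12)

    def test_delta_F_rejects_F_at_one(self):
        with pytest.raises(ValueError):
            delta_F(1.0, 5.0)

    @pytest.mark.parametrize("C,ta,tb,expected", [
        (0.0, 3.0, 5.0, 0.0),
        (0.25, 1.0, 1.0, 0.25),
        (0.1, 2.0, 4.0, 1.0 - 0.9 ** (1.0 / 3.0)),
    ])
    def test_delta_C(self, C, ta, tb, expected):
        assert delta_C(C, ta, tb) == pytest.approx(expected, abs=1e-12)

    def test_delta_C_zero_depth_warns(self):
        with pytest.warns(UserWarning):
            assert delta_C(0.1, 0.0, 0.0) == 0.0

    @pytest.mark.parametrize("F,C,expected", [
        (0.15, 0.15, 0.0),        # F = C: random mating
        (0.1, 0.2, -0.125),
        (0.2, 0.0, 0.2),
    ])
    def test_alpha(self, F, C, expected):
        assert non_random_mating(F, C) == pytest.approx(expected, abs=1e-12)


class TestFounderContributionsAndGci:
    def test_founder_self_vector(self, ped5):
        assert founder_contributions(ped5, "1") == {"1": 1.0}
        assert gci({"1": 1.0}) == 1.0

    def test_ped5_equal_halves(self, ped5):
        v = founder_contributions(ped5, "5")
        assert v == {"1": 0.5, "2": 0.5}
        assert gci(v) == pytest.approx(2.0)

    def test_three_founder_asymmetric(self):
        rows = [Individual(id="A"), Individual(id="B"), Individual(id="C"),
                Individual(id="bc", sire_id="B", dam_id="C"),
                Individual(id="kid", sire_id="A", dam_id="bc")]
        v = founder_contributions(Pedigree(rows), "kid")
        assert v == {"A": 0.5, "B": 0.25, "C": 0.25}
        assert gci(v) == pytest.approx(1.0 / 0.375)

    def test_equal_contributions_give_exact_k(self):
        for k in (2, 4, 8):
            assert gci({f"f{i}": 1.0 / k for i in range(k)}) == pytest.approx(k)

    def test_incomplete_pedigree_mass_below_one(self):
        rows = [Individual(id="A"), Individual(id="kid", sire_id="A")]
        v = founder_contributions(Pedigree(rows), "kid")
        assert v == {"A": 0.5}  # unknown dam slot dropped, no renormalisation
        assert gci(v) == pytest.approx(4.0)

    def test_phantom_founders_restore_unit_mass(self):
        rows = [Individual(id="A"), Individual(id="kid", sire_id="A")]
        v = founder_contributions(Pedigree(rows), "kid", phantom_unknown=True)
        assert sum(v.values()) == pytest.approx(1.0)
        assert gci(v) == pytest.approx(2.0)  # founder A + one phantom dam

    def test_empty_vector_errors(self):
        with pytest.raises(ValueError):
            gci({})


def test_depth_truncation_never_increases_parameters():
    """Cutting the pedigree at depth g can only lose inbreeding paths,
    founder spread and known generations."""
    p = random_pedigree(seed=21, n=80)
    gens = generation_measures(p)
    F = inbreeding(p)
    contribs = founder_contributions(p)
    # truncate: everyone within 1 generation of the founders becomes a
    # founder, cutting one ancestral layer from every pedigree
    depth = {i: gens[i][0] for i in p.ids}
    trunc = Pedigree([
        Individual(id=i) if depth[i] <= 1 else p[i] for i in p.ids
    ])
    F_t = inbreeding(trunc)
    gens_t = generation_measures(trunc)
    for i in p.ids:
        assert F_t[i] <= F[i] + 1e-12
        assert gens_t[i][2] <= gens[i][2] + 1e-12
    # GCI is monotone only when ancestral paths never reconverge: deeper
    # knowledge then splits founder mass, which can only lower 1/ΣP².
    rows = [Individual(id=f"g{i}") for i in range(4)]
    rows += [Individual(id="s", sire_id="g0", dam_id="g1"),
             Individual(id="d", sire_id="g2", dam_id="g3"),
             Individual(id="kid", sire_id="s", dam_id="d")]
    full = Pedigree(rows)
    cut = Pedigree([Individual(id="s"), Individual(id="d"),
                    Individual(id="kid", sire_id="s", dam_id="d")])
    assert gci(founder_contributions(cut, "kid")) <= gci(
        founder_contributions(full, "kid"))


def test_diversity_table_fields_and_cohort_alpha(ped5):
    df = diversity_table(ped5)
    assert list(df.columns) == ["id", "F", "AR", "meanC", "alpha", "GCI",
                                "max_gen", "complete_gen", "equiv_gen",
                                "delta_F", "offspring"]
    row5 = df.set_index("id").loc["5"]
    assert row5["F"] == pytest.approx(0.25)
    assert row5["AR"] == pytest.approx(0.75)
    assert row5["meanC"] == pytest.approx(0.375)
    assert row5["GCI"] == pytest.approx(2.0)
    pop = diversity_table(ped5, alpha_reference="population")
    # alpha solves (1-F) = (1-meanC)(1-alpha) against the population mean
    a5 = pop.set_index("id").loc["5", "alpha"]
    assert a5 == pytest.approx(1.0 - 0.75 / (1.0 - 0.375))
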