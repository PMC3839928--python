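"""Finite-population statistics: closed forms vs enumeration oracles."""

import itertools
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from translen.lengthstats import (LengthTable, null_oracle, one_subset_test,
                                  set_moments, split_test, subset_report,
                                  two_subset_test)


def exact_moments(vals):
    n = len(vals)
    mean = Fraction(sum(vals), n)
    var = sum((Fraction(v) - mean) ** 2 for v in vals) / n
    return mean, var


def exact_one_subset_null(vals, M):
    """Exhaustive Fraction-arithmetic null of mean(subset) - mean(set)."""
    n = len(vals)
    mean_all = Fraction(sum(vals), n)
    stats = [Fraction(sum(c), M) - mean_all
             for c in itertools.combinations(vals, M)]
    m = sum(stats, Fraction(0)) / len(stats)
    v = sum((s - m) ** 2 for s in stats) / len(stats)
    return m, v, stats

def exact_split_null(vals, L):
    n = len(vals)
    total = sum(vals)
    stats = []
    for c in itertools.combinations(range(n), L):
        part = sum(vals[i] for i in c)
        stats.append(Fraction(part, L) - Fraction(total - part, n - L))
    m = sum(stats, Fraction(0)) / len(stats)
    v = sum((s - m) ** 2 for s in stats) / len(stats)
    return m, v, stats


class TestSetMoments:
    @pytest.mark.parametrize("vals, mean, var", [
        ((5, 5, 5), 5.0, 0.0),
        ((1, 3), 2.0, 1.0),
        ((1, 2, 3, 4), 2.5, 1.25),
    ])
    def test_population_convention(self, vals, mean, var):
        m, v = set_moments(vals)
        assert m == pytest.approx(mean) and v == pytest.approx(var)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            set_moments([])


class TestOneSubset:
    def test_toy_closed_form_and_enumeration(self, six_length_table):
        """Lengths 1..6, subset {1,2}: delta = -2, null variance
        sigma^2 (N-M)/(M(N-1)) = (35/12)(4/10) = 7/6, Cantelli p = 7/31;
        exhaustive enumeration of all 15 subsets confirms the variance and
        the exact tail 1/15 <= 7/31."""
        res = one_subset_test(six_length_table, "short")
        assert res.delta_observed == pytest.approx(-2.0)
        assert res.null_variance == pytest.approx(7.0 / 6.0)
        assert res.cantelli_p == pytest.approx(7.0 / 31.0)
        assert res.direction == "shorter"

        m, v, stats = exact_one_subset_null(list(range(1, 7)), 2)
        assert m == 0
        assert v == Fraction(7, 6)
        tail = Fraction(sum(1 for s in stats if s <= -2), len(stats))
        assert tail == Fraction(1, 15)
        assert tail <= Fraction(7, 31)

    def test_zero_delta_gives_p_one(self):
        ids = list("abcd")
        t = LengthTable(entity_ids=ids, lengths=np.array([2.0, 4.0, 2.0, 4.0]),
                        annotation_sets={"half": {"a", "b"}})
        res = one_subset_test(t, "half")
        assert res.delta_observed == 0.0
        assert res.cantelli_p == 1.0

    def test_degenerate_subsets_rejected(self, six_length_table):
        with pytest.raises(ValueError):
            one_subset_test(six_length_table, set())
        with pytest.raises(ValueError):
            one_subset_test(six_length_table, set(six_length_table.entity_ids))

    def test_variance_identity_exact_on_integer_toys(self):
        """Closed-form null variance equals exhaustive enumeration exactly
        (rational arithmetic), for every M on several integer length sets."""
        rng = np.random.default_rng(42)
        for _ in range(6):
            n = int(rng.integers(4, 11))
            vals = [int(v) for v in rng.integers(1, 60, n)]
            _, var_pop = exact_moments(vals)
            for M in range(1, n):
                m, v, _ = exact_one_subset_null(vals, M)
                assert m == 0
                assert v == var_pop * (n - M) / (M * (n - 1))

    def test_split_variance_identity_exact(self):
        rng = np.random.default_rng(43)
        for _ in range(6):
            n = int(rng.integers(4, 11))
            vals = [int(v) for v in rng.integers(1, 60, n)]
            _, var_pop = exact_moments(vals)
            for L in range(1, n):
                m, v, _ = exact_split_null(vals, L)
                assert m == 0
                assert v == var_pop * n**2 / (L * (n - L) * (n - 1))


class TestTwoSubset:
    def test_identical_subsets_give_p_one(self, six_length_table):
        res = two_subset_test(six_length_table, "short", "short")
        assert res.delta_observed == 0.0
        assert res.cantelli_p == 1.0

    def test_cantelli_dominates_enumeration_on_toy_union(self):
        """Two disjoint triples drawn from their 6-length union: the exact
        tail probability over all 20 x 20 independent pairs never exceeds
        the Cantelli bound, and the closed-form variance matches exactly."""
        vals = [1, 2, 3, 5, 8, 13, 21, 34]
        ids = [f"g{i}" for i in range(8)]
        t = LengthTable(entity_ids=ids, lengths=np.array(vals, float),
                        annotation_sets={"a": {"g0", "g1", "g2"},
                                         "b": {"g5", "g6", "g7"}})
        res = two_subset_test(t, "a", "b")
        union_vals = [1, 2, 3, 13, 21, 34]
        dist = null_oracle(union_vals, "two_subset", {"L": 3, "M": 3},
                           mode="exhaustive")
        assert len(dist.statistics) == 20 * 20
        assert dist.mean == pytest.approx(0.0, abs=1e-12)
        assert dist.variance == pytest.approx(res.null_variance, rel=1e-12)
        assert dist.tail_probability(res.delta_observed) <= res.cantelli_p

    def test_empty_subset_rejected(self, six_length_table):
        with pytest.raises(ValueError):
            two_subset_test(six_length_table, "short", set())


class TestSplit:
    def test_toy_split_oracle_confirmed(self):
        """Universe (1,2,3,4), part {3,4}: statistic mean(part)-mean(rest)
        = 2, variance sigma_M^2 M^2/(L(M-L)(M-1)) = 5/3, Cantelli p = 5/17;
        enumeration of all 6 splits gives the exact tail 1/6 <= 5/17."""
        ids = list("abcd")
        t = LengthTable(entity_ids=ids, lengths=np.array([1.0, 2.0, 3.0, 4.0]),
                        annotation_sets={"part": {"c", "d"},
                                         "all": set(ids)})
        res = split_test(t, "part", "all")
        assert res.delta_observed == pytest.approx(2.0)
        assert res.null_variance == pytest.approx(5.0 / 3.0)
        assert res.cantelli_p == pytest.approx(5.0 / 17.0)

        m, v, stats = exact_split_null([1, 2, 3, 4], 2)
        assert m == 0 and v == Fraction(5, 3)
        tail = Fraction(sum(1 for s in stats if s >= 2), len(stats))
        assert tail == Fraction(1, 6)
        assert float(tail) <= res.cantelli_p

    def test_constant_universe_gives_p_one(self):
        ids = list("abcd")
        t = LengthTable(entity_ids=ids, lengths=np.full(4, 7.0),
                        annotation_sets={"part": {"a", "b"}, "all": set(ids)})
        res = split_test(t, "part", "all")
        assert res.delta_observed == 0.0
        assert res.null_variance == 0.0
        assert res.cantelli_p == 1.0

    def test_degenerate_partition_rejected(self):
        ids = list("abc")
        t = LengthTable(entity_ids=ids, lengths=np.array([1.0, 2.0, 3.0]),
                        annotation_sets={"all": set(ids)})
        with pytest.raises(ValueError):
            split_test(t, set(), "all")
        with pytest.raises(ValueError):
            split_test(t, set(ids), "all")


class TestNullOracle:
    def test_exhaustive_counts_and_moments(self):
        dist = null_oracle(list(range(1, 7)), "one_subset", {"M": 2})
        assert len(dist.statistics) == 15
        assert dist.mean == pytest.approx(0.0, abs=1e-12)
        assert dist.variance == pytest.approx(7.0 / 6.0, rel=1e-12)

    def test_constant_lengths_degenerate_at_zero(self):
        dist = null_oracle([5] * 6, "one_subset", {"M": 3})
        assert np.all(dist.statistics == 0)

    def test_monte_carlo_seed_deterministic(self):
        a = null_oracle(list(range(20)), "split", {"L": 7},
                        mode="monte_carlo", seed=9, n_reps=500)
        b = null_oracle(list(range(20)), "split", {"L": 7},
                        mode="monte_carlo", seed=9, n_reps=500)
        assert np.array_equal(a.statistics, b.statistics)

    def test_combinatorial_explosion_guarded(self):
        with pytest.raises(ValueError, match="monte_carlo"):
            null_oracle(list(range(40)), "one_subset", {"M": 20})


class TestCantelliProperties:
    def test_monotone_in_displacement(self, six_length_table):
        """With variance fixed, the bound strictly decreases as |delta|
        grows."""
        var = 1.3
        deltas = np.linspace(0, 10, 50)
        ps = var / (var + deltas**2)
        assert np.all(np.diff(ps) < 0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 50), min_size=4, max_size=9),
           st.data())
    def test_cantelli_dominates_exact_tail(self, vals, data):
        """Property: on any small instance the enumerated tail probability
        never exceeds the Cantelli bound, in the observed direction."""
        n = len(vals)
        M = data.draw(st.integers(1, n - 1))
        ids = [f"g{i}" for i in range(n)]
        t = LengthTable(entity_ids=ids, lengths=np.array(vals, float),
                        annotation_sets={"sub": set(ids[:M])})
        res = one_subset_test(t, "sub")
        dist = null_oracle(vals, "one_subset", {"M": M})
        assert dist.tail_probability(res.delta_observed) <= res.cantelli_p + 1e-12


class TestSubsetReport:
    def test_report_columns_and_values(self, six_length_table):
        df = subset_report(six_length_table, ["short"])
        assert list(df.columns) == ["subset", "M", "mean_length_nt",
                                    "delta_nt", "cantelli_p"]
        assert df.loc[0, "M"] == 2
        assert df.loc[0, "cantelli_p"] == pytest.approx(7.0 / 31.0)
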