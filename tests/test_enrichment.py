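"""Overexpression annotation, partitioning and hypergeometric enrichment."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kstest

from translen.enrichment import (ExpressionMatrix, annotate_overexpressed,
                                 consistent_terms, enrichment_scan,
                                 hypergeom_enrichment, partition_subsets)


def toy_matrix(values, conditions=None):
    values = np.asarray(values, float)
    n, m = values.shape
    return ExpressionMatrix(
        values=values,
        entity_ids=tuple(f"g{i}" for i in range(n)),
        sample_ids=tuple(f"s{j}" for j in range(m)),
        conditions=tuple(conditions or ["c"] * m),
    )


def brute_force_flags(values, X, f):
    """Independent oracle: per-sample stable descending sort."""
    n, m = values.shape
    counts = np.zeros(n, int)
    for j in range(m):
        order = sorted(range(n), key=lambda i: (-values[i, j], i))
        for i in order[:X]:
            counts[i] += 1
    return np.array([Fraction(int(c), m) >= Fraction(str(f)) for c in counts])


class TestAnnotateOverexpressed:
    def test_always_top_entity_flagged(self):
        rng = np.random.default_rng(0)
        vals = rng.random((6, 5))
        vals[3] += 10.0  # maximum in every sample
        call = annotate_overexpressed(toy_matrix(vals), "c", X=1)
        assert call.flags.tolist() == [False, False, False, True, False, False]

    def test_cutoff_equal_to_universe_flags_all(self):
        vals = np.random.default_rng(1).random((5, 4))
        call = annotate_overexpressed(toy_matrix(vals), "c", X=5)
        assert call.flags.all()

    def test_matches_brute_force_on_planted_toy(self):
        rng = np.random.default_rng(2)
        vals = rng.random((5, 4)) * 10
        call = annotate_overexpressed(toy_matrix(vals), "c", X=2, f=0.2)
        assert np.array_equal(call.flags, brute_force_flags(vals, 2, 0.2))

    def test_matches_brute_force_random(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(4, 15))
            m = int(rng.integers(2, 8))
            X = int(rng.integers(1, n + 1))
            vals = rng.random((n, m))
            call = annotate_overexpressed(toy_matrix(vals), "c", X=X, f=0.2)
            assert np.array_equal(call.flags, brute_force_flags(vals, X, 0.2))

    def test_invariant_to_monotone_per_sample_transform(self):
        rng = np.random.default_rng(4)
        vals = rng.random((8, 5))
        base = annotate_overexpressed(toy_matrix(vals), "c", X=3)
        warped = vals.copy()
        warped[:, 0] = np.exp(warped[:, 0])
        warped[:, 1] = warped[:, 1] ** 3
        warped[:, 2] = 100 * warped[:, 2] + 4
        again = annotate_overexpressed(toy_matrix(warped), "c", X=3)
        assert np.array_equal(base.flags, again.flags)
        assert np.array_equal(base.counts, again.counts)

    def test_condition_selection_and_errors(self):
        vals = np.random.default_rng(5).random((4, 4))
        E = toy_matrix(vals, conditions=["n", "n", "t", "t"])
        call = annotate_overexpressed(E, "n", X=2)
        assert call.n_samples == 2
        with pytest.raises(ValueError):
            annotate_overexpressed(E, "missing", X=2)
        with pytest.raises(ValueError):
            annotate_overexpressed(E, "n", X=0)

    def test_exact_fraction_threshold(self):
        # 1 of 5 samples is below 20%; 1 of 4 is at 25% >= 20%
        vals = np.zeros((3, 5))
        vals[0, 0] = 5.0
        vals[1] = 1.0
        call5 = annotate_overexpressed(toy_matrix(vals), "c", X=1, f=0.2)
        assert call5.flags[0] == (Fraction(1, 5) >= Fraction(1, 5))
        assert call5.flags[0]


class TestPartition:
    def _call(self, flags, ids):
        vals = np.zeros((len(ids), 6))
        for i, fl in enumerate(flags):
            if fl:
                vals[i, :] = 10 + i
        E = ExpressionMatrix(values=vals, entity_ids=tuple(ids),
                             sample_ids=tuple(f"s{j}" for j in range(6)),
                             conditions=("c",) * 6)
        return annotate_overexpressed(E, "c", X=max(1, sum(flags)))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.booleans(), st.booleans()),
                    min_size=2, max_size=12))
    def test_partition_identities(self, pairs):
        """a_only/b_only/both are disjoint and recompose the overall sets."""
        ids = [f"g{i}" for i in range(len(pairs))]
        a = {g for g, (fa, _) in zip(ids, pairs) if fa}
        b = {g for g, (_, fb) in zip(ids, pairs) if fb}
        from translen.enrichment import SubsetPartition
        part = SubsetPartition(a_only=a - b, b_only=b - a, both=a & b)
        assert part.a_only & part.b_only == set()
        assert part.a_only & part.both == set()
        assert part.b_only & part.both == set()
        assert part.a_overall == a and part.b_overall == b
        assert len(part.a_only) + len(part.both) == len(a)

    def test_disjoint_and_identical_flag_sets(self):
        rng = np.random.default_rng(6)
        vals = rng.random((6, 8))
        vals[0, :4] += 5; vals[1, 4:] += 5
        E = toy_matrix(vals, conditions=["n"] * 4 + ["t"] * 4)
        pn = annotate_overexpressed(E, "n", X=1)
        pt = annotate_overexpressed(E, "t", X=1)
        part = partition_subsets(pn, pt)
        assert part.both == set()
        part2 = partition_subsets(pn, pn)
        assert part2.a_only == set() and part2.b_only == set()

    def test_mismatched_universe_rejected(self):
        vals = np.random.default_rng(7).random((4, 2))
        a = annotate_overexpressed(toy_matrix(vals), "c", X=1)
        other = ExpressionMatrix(values=vals, entity_ids=("x0", "x1", "x2", "x3"),
                                 sample_ids=("s0", "s1"), conditions=("c", "c"))
        b = annotate_overexpressed(other, "c", X=1)
        with pytest.raises(ValueError):
            partition_subsets(a, b)


class TestHypergeom:
    def test_trivial_bounds(self):
        assert hypergeom_enrichment(10, 5, 4, 0) == 1.0
        assert hypergeom_enrichment(10, 10, 4, 4) == pytest.approx(1.0)

    def test_exact_rational_example(self):
        # P(y = 4) = C(5,4) C(5,0) / C(10,4) = 5/210
        assert hypergeom_enrichment(10, 5, 4, 4) == pytest.approx(5 / 210, rel=1e-12)

    def test_matches_fraction_enumeration(self):
        """Log-space tail equals exact rational enumeration for N <= 100."""
        rng = np.random.default_rng(8)
        for _ in range(25):
            N = int(rng.integers(5, 101))
            Y = int(rng.integers(0, N + 1))
            M = int(rng.integers(1, N + 1))
            y = int(rng.integers(max(0, M + Y - N), min(Y, M) + 1))
            exact = sum(Fraction(math.comb(Y, i) * math.comb(N - Y, M - i),
                                 math.comb(N, M))
                        for i in range(y, min(Y, M) + 1))
            assert hypergeom_enrichment(N, Y, M, y) == pytest.approx(
                float(exact), rel=1e-9, abs=1e-15)

    def test_normalization_from_zero(self):
        for (N, Y, M) in [(30, 12, 7), (100, 40, 25), (61, 1, 60)]:
            exact = sum(Fraction(math.comb(Y, i) * math.comb(N - Y, M - i),
                                 math.comb(N, M))
                        for i in range(max(0, M + Y - N), min(Y, M) + 1))
            assert exact == 1
            assert hypergeom_enrichment(N, Y, M, max(0, M + Y - N)) == \
                pytest.approx(1.0, rel=1e-12)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment(10, 5, 4, 5)
        with pytest.raises(ValueError):
            hypergeom_enrichment(10, 12, 4, 2)


class TestEnrichmentScan:
    def test_planted_enrichment_attains_minimum_p(self):
        universe = [f"g{i}" for i in range(200)]
        sub = set(universe[:30])
        annotations = {
            "planted": set(universe[:25]),           # concentrated in sub
            "diffuse": set(universe[::10]),
        }
        df = enrichment_scan({"sub": sub, "rest": set(universe[30:])},
                             annotations, universe)
        assert df.iloc[0]["subset"] == "sub"
        assert df.iloc[0]["term"] == "planted"
        assert df.iloc[0]["p"] == df["p"].min()

    def test_absent_term_skipped_with_warning(self, caplog):
        universe = ["g0", "g1", "g2"]
        with caplog.at_level("WARNING"):
            df = enrichment_scan({"sub": {"g0"}}, {"ghost": {"zz"}}, universe)
        assert df.empty
        assert any("ghost" in r.message for r in caplog.records)

    def test_uniform_annotations_give_roughly_uniform_p(self):
        """Sanity (not a sharp assert): with random annotations the p-values
        should not concentrate near zero."""
        rng = np.random.default_rng(9)
        universe = [f"g{i}" for i in range(300)]
        sub = set(rng.choice(universe, 60, replace=False))
        ps = []
        for t in range(100):
            ann = set(rng.choice(universe, 30, replace=False))
            df = enrichment_scan({"sub": sub}, {"t": ann}, universe)
            ps.append(df["p"].iloc[0])
        stat, _ = kstest(ps, "uniform")
        assert stat < 0.35
        assert np.mean(np.array(ps) < 0.05) < 0.2

    def test_consistent_terms_across_cutoffs(self):
        import pandas as pd
        df1 = pd.DataFrame({"subset": ["s", "s"], "term": ["a", "b"],
                            "p": [0.001, 0.2]})
        df2 = pd.DataFrame({"subset": ["s", "s"], "term": ["a", "b"],
                            "p": [0.003, 0.01]})
        assert consistent_terms({250: df1, 300: df2}, "s") == {"a"}
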