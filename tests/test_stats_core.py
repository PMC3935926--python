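import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from seropanel import (
    bh_fdr,
    hypergeom_upper_tail,
    m_score,
    m_score_matrix,
    rank_features,
    welch_t,
    welch_t_matrix,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def hypergeom_tail_fraction(a: int, k: int, n1: int, n2: int) -> Fraction:
    """Exact tail by the combinatorial formula, in exact arithmetic."""
    total = math.comb(n1 + n2, k)
    num = sum(math.comb(n1, x) * math.comb(n2, k - x) for x in range(a, min(k, n1) + 1))
    return Fraction(num, total)


def hypergeom_tail_enumeration(a: int, k: int, n1: int, n2: int) -> Fraction:
    """Exact tail by brute enumeration of every k-subset of the population."""
    population = [1] * n1 + [0] * n2
    hits = total = 0
    for draw in itertools.combinations(range(n1 + n2), k):
        total += 1
        hits += sum(population[i] for i in draw) >= a
    return Fraction(hits, total)


def m_score_oracle(cases, controls) -> Fraction:
    """Minimum tail over every distinct pooled value used as a cutoff
    (equivalent to midpoint cutoffs under strict '>') in exact arithmetic."""
    n1, n2 = len(cases), len(controls)
    best = Fraction(1)
    for c in sorted(set(list(cases) + list(controls))):
        a = sum(v > c for v in cases)
        b = sum(v > c for v in controls)
        best = min(best, hypergeom_tail_fraction(a, a + b, n1, n2))
    return best


def bh_oracle(p):
    """Direct O(m^2) transcription of the step-up definition."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    rank = {i: r + 1 for r, i in enumerate(order)}
    out = []
    for i in range(m):
        candidates = [p[j] * m / rank[j] for j in range(m) if p[j] >= p[i]]
        out.append(min(1.0, min(candidates)))
    return out


def welch_oracle(x, y):
    """Textbook Welch statistic + Welch-Satterthwaite df, two-sided p."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    t = (x.mean() - y.mean()) / math.sqrt(vx / nx + vy / ny)
    df = (vx / nx + vy / ny) ** 2 / (
        (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
    )
    return 2 * sps.t.sf(abs(t), df)


# ---------------------------------------------------------------------------
# hypergeometric tail
# ---------------------------------------------------------------------------


class TestHypergeomUpperTail:
    def test_all_cases_above(self):
        # C(3,3)C(3,0)/C(6,3) = 1/20
        assert hypergeom_upper_tail(3, 3, 3, 3) == pytest.approx(0.05, rel=1e-12)

    def test_a_zero_is_one(self):
        assert hypergeom_upper_tail(0, 5, 10, 10) == 1.0

    def test_enumeration_example(self):
        assert hypergeom_upper_tail(1, 2, 2, 2) == pytest.approx(5 / 6, rel=1e-12)
        assert hypergeom_tail_enumeration(1, 2, 2, 2) == Fraction(5, 6)

    def test_matches_subset_enumeration_small_populations(self):
        for n1 in range(1, 7):
            for n2 in range(1, 7):
                for k in range(0, n1 + n2 + 1):
                    for a in range(max(0, k - n2), min(k, n1) + 1):
                        expect = float(hypergeom_tail_enumeration(a, k, n1, n2))
                        got = hypergeom_upper_tail(a, k, n1, n2)
                        assert got == pytest.approx(expect, rel=1e-10), (a, k, n1, n2)

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(5, 3, 10, 10)  # a > k
        with pytest.raises(ValueError):
            hypergeom_upper_tail(0, 8, 3, 3)  # k > n1 + n2
        with pytest.raises(ValueError):
            hypergeom_upper_tail(1, 6, 3, 3)  # k - a > n2

    def test_matches_scipy(self):
        got = hypergeom_upper_tail(9, 14, 14, 14)
        assert got == pytest.approx(sps.hypergeom.sf(8, 28, 14, 14), rel=1e-10)


# ---------------------------------------------------------------------------
# M score
# ---------------------------------------------------------------------------


class TestMScore:
    def test_perfect_separation(self):
        res = m_score([10, 9, 8], [1, 2, 3])
        assert res.p_value == pytest.approx(0.05, rel=1e-12)
        assert (res.cases_above, res.controls_above) == (3, 0)
        assert 3 < res.best_cutoff < 8

    def test_identical_small_groups(self):
        res = m_score([1, 2], [1, 2])
        assert res.p_value == pytest.approx(5 / 6, rel=1e-12)
        assert res.best_cutoff == pytest.approx(1.5)

    def test_all_values_identical(self):
        res = m_score([3, 3, 3], [3, 3, 3])
        assert res.p_value == 1.0
        assert (res.cases_above, res.controls_above) == (0, 0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            m_score([], [1, 2])

    def test_exhaustive_small_inputs_match_oracle(self):
        # every multiset pair over {1,2,3,4} with 1..3 values per group
        # (m_score is permutation-invariant; multisets cover all inputs)
        values = [1, 2, 3, 4]
        pools = [
            list(c)
            for size in (1, 2, 3)
            for c in itertools.combinations_with_replacement(values, size)
        ]
        for cases in pools:
            for controls in pools:
                expect = float(m_score_oracle(cases, controls))
                got = m_score(cases, controls).p_value
                assert got == pytest.approx(expect, rel=1e-10), (cases, controls)

    @settings(max_examples=100, deadline=None)
    @given(
        cases=st.lists(st.integers(0, 9), min_size=1, max_size=6),
        controls=st.lists(st.integers(0, 9), min_size=1, max_size=6),
    )
    def test_random_inputs_match_oracle(self, cases, controls):
        expect = float(m_score_oracle(cases, controls))
        assert m_score(cases, controls).p_value == pytest.approx(expect, rel=1e-10)

    @settings(max_examples=100, deadline=None)
    @given(
        cases=st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=6),
        controls=st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=6),
        seed=st.integers(0, 2**32 - 1),
    )
    def test_permutation_invariance(self, cases, controls, seed):
        rng = np.random.default_rng(seed)
        p0 = m_score(cases, controls).p_value
        assert m_score(rng.permutation(cases), rng.permutation(controls)).p_value == p0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        cases = rng.normal(1, 1, size=8)
        controls = rng.normal(0, 1, size=8)
        p0 = m_score(cases, controls).p_value
        pooled = np.concatenate([cases, controls])
        uniq = np.unique(pooled)
        for _ in range(25):
            # random strictly increasing map defined on the observed values
            new_vals = np.sort(rng.uniform(-100, 100, size=uniq.size))
            remap = dict(zip(uniq, new_vals))
            tc = [remap[v] for v in cases]
            tn = [remap[v] for v in controls]
            assert m_score(tc, tn).p_value == p0

    def test_matrix_version_matches_scalar(self):
        rng = np.random.default_rng(9)
        X = rng.normal(10, 1, size=(50, 12))
        X[:, :6] += rng.uniform(0, 1.5, size=(50, 1))
        mask = np.array([True] * 6 + [False] * 6)
        ps = m_score_matrix(X, mask)
        for i in range(50):
            assert ps[i] == pytest.approx(
                m_score(X[i, mask], X[i, ~mask]).p_value, rel=1e-12
            )

    def test_matrix_version_handles_ties(self):
        X = np.array([[1.0, 1.0, 2.0, 1.0, 1.0, 2.0], [5.0, 5.0, 5.0, 1.0, 1.0, 1.0]])
        mask = np.array([True, True, True, False, False, False])
        ps = m_score_matrix(X, mask)
        for i in range(2):
            assert ps[i] == pytest.approx(m_score(X[i, :3], X[i, 3:]).p_value, rel=1e-12)


# ---------------------------------------------------------------------------
# Welch t
# ---------------------------------------------------------------------------


class TestWelchT:
    def test_identical_groups_p_one(self):
        assert welch_t([2, 4], [2, 4]) == pytest.approx(1.0)

    def test_textbook_formula(self):
        cases, controls = [8.0, 9.0, 10.0], [1.0, 2.0, 3.0]
        assert welch_t(cases, controls) == pytest.approx(
            welch_oracle(cases, controls), rel=1e-12
        )

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_random_inputs_match_textbook(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, size=rng.integers(2, 10))
        y = rng.normal(0.5, 2, size=rng.integers(2, 10))
        assert welch_t(x, y) == pytest.approx(welch_oracle(x, y), rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            welch_t([3, 3], [5, 5])

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1], [2, 3])

    def test_matrix_version_matches_scalar(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 10))
        mask = np.array([True] * 5 + [False] * 5)
        ps = welch_t_matrix(X, mask)
        for i in range(20):
            assert ps[i] == pytest.approx(welch_t(X[i, :5], X[i, 5:]), rel=1e-12)


# ---------------------------------------------------------------------------
# BH FDR and ranking
# ---------------------------------------------------------------------------


class TestBhFdr:
    def test_single_p_identity(self):
        assert bh_fdr([0.01]).tolist() == [0.01]

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_matches_direct_definition_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), rtol=1e-12)

    def test_monotone_along_sorted_p(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=100)
        adj = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestRankFeatures:
    def test_basic(self):
        assert rank_features([0.2, 0.1, 0.3], ["a", "b", "c"]).tolist() == [2, 1, 3]

    def test_ties_by_id(self):
        assert rank_features([0.5, 0.5, 0.1], ["z", "a", "m"]).tolist() == [3, 2, 1]

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    def test_positions_are_a_permutation(self, ps):
        ids = [f"f{i}" for i in range(len(ps))]
        pos = rank_features(ps, ids)
        assert sorted(pos.tolist()) == list(range(1, len(ps) + 1))
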