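import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu, rankdata, wilcoxon

from fiducialign import (
    PairedSamples,
    mann_whitney_exact,
    repetition_analysis,
    summarize,
    wilcoxon_signed_rank,
)
from fiducialign.errors import InvalidParameterError, UndefinedTestError
from fiducialign.stats import PRATT, load_table, table_summary


def brute_force_signed_rank_p(d):
    """Literal 2^n sign-assignment enumeration oracle."""
    d = np.asarray(d, dtype=float)
    nz = d[d != 0]
    ranks = rankdata(np.abs(nz))
    w_obs = ranks[nz > 0].sum()
    n = len(nz)
    lower = upper = 0
    total = 2**n
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        lower += w <= w_obs + 1e-9
        upper += w >= w_obs - 1e-9
    return min(1.0, 2.0 * min(lower / total, upper / total))


def brute_force_rank_sum_p(a, b):
    """Literal C(n, n_a) group-assignment enumeration oracle."""
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n_a = len(a)
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    us = [
        ranks[list(c)].sum() - n_a * (n_a + 1) / 2
        for c in itertools.combinations(range(len(pooled)), n_a)
    ]
    us = np.array(us)
    lower = np.mean(us <= u_obs + 1e-9)
    upper = np.mean(us >= u_obs - 1e-9)
    return min(1.0, 2.0 * min(lower, upper))


class TestSummarize:
    def test_table1_sphere_row(self):
        s = summarize([0.23, 0.28, 0.23, 0.24, 0.24])
        assert s.mean_range_str() == "0.24 (0.23–0.28)"

    def test_table2_sphere_row(self):
        df = load_table(2)
        s = summarize(df["rmse_sphere"])
        assert s.mean_range_str() == "0.32 (0.19–0.41)"

    def test_constant_vector(self):
        s = summarize([0.3, 0.3, 0.3])
        assert s.sd == 0.0
        assert s.variance == 0.0

    def test_variance_is_sd_squared(self, rng):
        s = summarize(rng.random(50))
        assert s.variance == pytest.approx(s.sd**2, abs=1e-12)
        assert s.min <= s.mean <= s.max

    def test_empty(self):
        with pytest.raises(InvalidParameterError):
            summarize([])

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0, 10), min_size=2, max_size=12), st.randoms())
    def test_permutation_invariance(self, values, pyrandom):
        shuffled = list(values)
        pyrandom.shuffle(shuffled)
        a, b = summarize(values), summarize(shuffled)
        assert a.mean == pytest.approx(b.mean, abs=1e-12)
        assert a.sd == pytest.approx(b.sd, abs=1e-12)


class TestWilcoxonSignedRank:
    def test_table2_w_plus(self):
        df = load_table(2)
        samples = PairedSamples.from_frame(df)
        w_plus, _ = wilcoxon_signed_rank(samples)
        assert w_plus == 13.0  # zeros dropped, n_eff = 8, tied |d|=0.02 triple

    def test_all_zero_differences(self):
        x = np.array([0.1, 0.2, 0.3])
        with pytest.raises(UndefinedTestError):
            wilcoxon_signed_rank(PairedSamples(x, x))

    def test_exact_matches_brute_force_n6(self, rng):
        a = rng.random(6) + 0.5
        b = a + rng.normal(0, 0.2, 6)
        w, p = wilcoxon_signed_rank(PairedSamples(a, b), mode="exact")
        assert p == pytest.approx(brute_force_signed_rank_p(a - b), abs=1e-12)

    def test_exact_matches_scipy_tie_free(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            a = r.random(9) + 1
            b = a + r.normal(0, 0.3, 9)
            _, p = wilcoxon_signed_rank(PairedSamples(a, b), mode="exact")
            ref = wilcoxon(a, b, mode="exact")
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_pratt_policy_runs(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([1.0, 1.5, 3.5, 3.0])  # one zero difference
        w_drop, _ = wilcoxon_signed_rank(PairedSamples(a, b))
        w_pratt, p = wilcoxon_signed_rank(PairedSamples(a, b), zero_policy=PRATT)
        assert w_pratt >= w_drop  # zeros inflate the ranks of non-zero diffs
        assert 0 < p <= 1

    def test_normal_approx_close_to_exact(self, rng):
        a = rng.random(15) + 1
        b = a + rng.normal(0, 0.3, 15)
        _, p_exact = wilcoxon_signed_rank(PairedSamples(a, b), mode="exact")
        _, p_norm = wilcoxon_signed_rank(PairedSamples(a, b), mode="normal_approx")
        assert p_norm == pytest.approx(p_exact, abs=0.05)

    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 8), st.integers(0, 8)), min_size=3, max_size=8
        )
    )
    def test_exact_equals_enumeration_with_ties(self, pairs):
        a = np.array([p[0] for p in pairs], dtype=float)
        b = np.array([p[1] for p in pairs], dtype=float)
        if np.all(a == b):
            return
        _, p = wilcoxon_signed_rank(PairedSamples(a, b), mode="exact")
        assert p == pytest.approx(brute_force_signed_rank_p(a - b), abs=1e-12)


class TestMannWhitney:
    def test_table1_separation(self):
        df = load_table(1)
        u, p = mann_whitney_exact(df["rmse_sphere"], df["rmse_cross"])
        assert p == pytest.approx(2 / 252, abs=1e-12)
        assert p < 0.008

    def test_identical_multisets(self):
        a = np.array([1.0, 2.0, 3.0])
        u, p = mann_whitney_exact(a, a)
        assert u == pytest.approx(len(a) ** 2 / 2)
        assert p == 1.0

    def test_3v3_matches_brute_force(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            a, b = r.integers(0, 5, 3).astype(float), r.integers(0, 5, 3).astype(float)
            _, p = mann_whitney_exact(a, b)
            assert p == pytest.approx(brute_force_rank_sum_p(a, b), abs=1e-12)

    def test_matches_scipy_exact(self, rng):
        a = rng.random(6)
        b = rng.random(7) + 0.2
        u, p = mann_whitney_exact(a, b)
        ref = mannwhitneyu(a, b, method="exact")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_size_limit(self, rng):
        with pytest.raises(InvalidParameterError):
            mann_whitney_exact(rng.random(11), rng.random(11))

    def test_empty_sample(self):
        with pytest.raises(InvalidParameterError):
            mann_whitney_exact([], [1.0])


class TestRepetitionAnalysis:
    def test_sd_variance_relation(self):
        # any vector with sd 0.078 reports variance 0.006 at 3 decimals
        v = np.array([0.27, 0.27 + 0.078 * np.sqrt(2)])  # two-point vector with sd 0.078
        s = repetition_analysis(v)
        assert s.sd == pytest.approx(np.std(v, ddof=1))
        assert round(s.variance, 3) == pytest.approx(0.006)

    def test_identical_values(self):
        s = repetition_analysis([0.27] * 10)
        assert s.variance == 0.0

    def test_needs_two(self):
        with pytest.raises(InvalidParameterError):
            repetition_analysis([0.3])


class TestFixtures:
    def test_table_schemas(self):
        for which in (1, 2):
            df = load_table(which)
            assert list(df.columns) == ["participant", "rmse_sphere", "rmse_cross"]
        assert len(load_table(1)) == 5
        assert len(load_table(2)) == 10

    def test_table_summary_keys(self):
        s = table_summary(1)
        assert s["sphere_mean_range"] == "0.24 (0.23–0.28)"
        assert 0 < s["p_rank_sum"] <= 1


def test_p_values_in_unit_interval(rng):
    for seed in range(5):
        r = np.random.default_rng(seed)
        a, b = r.random(5), r.random(5)
        _, p1 = wilcoxon_signed_rank(PairedSamples(a, b))
        _, p2 = mann_whitney_exact(a, b)
        assert 0 < p1 <= 1
        assert 0 < p2 <= 1
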