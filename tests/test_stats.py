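"""Unit and property tests for the shared statistical primitives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from clawfc.stats import (
    bh_fdr,
    fisher_z,
    inverse_fisher_z,
    kruskal_dunn,
    t_test,
    wilcoxon_one_sample,
)


class TestFisherZ:
    @pytest.mark.parametrize(
        "r,expected",
        [
            (0.0, 0.0),
            (0.5, 0.5493061443340549),   # atanh(1/2) = ln(3)/2
            (-0.5, -0.5493061443340549),
        ],
    )
    def test_known_values(self, r, expected):
        assert fisher_z(r) == pytest.approx(expected, abs=1e-12)

    def test_clipping_keeps_unity_finite(self):
        # atanh of the clipped value: 0.5*ln((2 - eps)/eps)
        expected = 0.5 * np.log((2 - 1e-7) / 1e-7)
        assert fisher_z(1.0, clip_eps=1e-7) == pytest.approx(expected, rel=1e-6)
        assert fisher_z(-1.0, clip_eps=1e-7) == -fisher_z(1.0, clip_eps=1e-7)

    @given(st.floats(-0.999, 0.999))
    @settings(max_examples=200, deadline=None)
    def test_odd_and_invertible(self, r):
        z = fisher_z(r)
        assert fisher_z(-r) == pytest.approx(-z, abs=1e-12)
        assert inverse_fisher_z(z) == pytest.approx(r, abs=1e-12)

    def test_strictly_increasing(self):
        grid = np.linspace(-1, 1, 2001)
        z = fisher_z(grid)
        assert np.all(np.diff(z) > 0)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError, match="invalid correlation"):
            fisher_z(np.inf)

    def test_nan_passes_through_as_missing(self):
        out = fisher_z(np.array([0.5, np.nan]))
        assert np.isnan(out[1]) and np.isfinite(out[0])


def _bh_stepup_oracle(p, q):
    """Hand step-up: reject the largest i with p_(i) <= i*q/m."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresh = (np.arange(1, m + 1) / m) * q
    below = np.flatnonzero(sorted_p <= thresh)
    k = below.max() + 1 if below.size else 0
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:k]] = True
    adj = np.minimum.accumulate((m / np.arange(m, 0, -1)) * sorted_p[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out, rejected


class TestBhFdr:
    @pytest.mark.parametrize(
        "p,expected_rejections",
        [
            ([0.01, 0.02, 0.03, 0.04, 0.05], 5),
            ([0.001, 0.9, 0.9, 0.9], 1),
            ([0.2], 0),
        ],
    )
    def test_hand_checked_vectors(self, p, expected_rejections):
        dec = bh_fdr(p, q=0.05)
        assert dec.n_rejected == expected_rejections
        adj, rej = _bh_stepup_oracle(p, 0.05)
        np.testing.assert_allclose(dec.adjusted_p, adj, atol=1e-12)
        np.testing.assert_array_equal(dec.rejected, rej)

    def test_empty_family(self):
        dec = bh_fdr([])
        assert dec.adjusted_p.size == 0 and dec.rejected.size == 0

    def test_matches_stepup_oracle_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            dec = bh_fdr(p, q=0.05)
            adj, rej = _bh_stepup_oracle(p, 0.05)
            np.testing.assert_allclose(dec.adjusted_p, adj, atol=1e-12)
            np.testing.assert_array_equal(dec.rejected, rej)
            assert np.all(dec.adjusted_p >= dec.raw_p - 1e-15)
            np.testing.assert_array_equal(dec.rejected,
                                          dec.adjusted_p <= dec.q_threshold)

    def test_global_null_false_rejection_proportion(self):
        # 1000 batches of 50 uniform p-values: batches with any rejection
        # should stay near the nominal q = 0.05
        rng = np.random.default_rng(11)
        hits = sum(
            bh_fdr(rng.uniform(size=50), q=0.05).n_rejected > 0
            for _ in range(1000)
        )
        assert hits / 1000 <= 0.07


class TestTTest:
    def test_one_sample_at_the_mean(self):
        res = t_test([1.0, 2.0, 3.0], mode="one_sample", mu=2.0)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-12)

    def test_unpaired_pooled_hand_value(self):
        # pooled t = -3 / sqrt(2/3)
        res = t_test([1, 2, 3], [4, 5, 6], mode="unpaired")
        assert res.statistic == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), rel=1e-12)
        assert res.n == (3, 3)

    def test_welch_flag(self):
        res = t_test([1, 2, 3], [4, 5, 6, 7], mode="unpaired", equal_var=False)
        ref = sps.ttest_ind([1, 2, 3], [4, 5, 6, 7], equal_var=False)
        assert res.statistic == pytest.approx(ref.statistic)

    def test_paired_identical_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], mode="paired")

    def test_zero_variance_one_sample_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            t_test([2.0, 2.0, 2.0], mode="one_sample", mu=1.0)


def _wilcoxon_enumeration_oracle(x, mu=0.0):
    """Two-sided exact p by enumerating all 2^n sign assignments."""
    d = np.asarray(x, float) - mu
    d = d[d != 0]
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array([
        ranks[[c == "1" for c in np.binary_repr(m, n)]].sum()
        for m in range(2**n)
    ])
    p_ge = np.mean(ws >= w_obs - 1e-9)
    p_le = np.mean(ws <= w_obs + 1e-9)
    return min(1.0, 2 * min(p_ge, p_le))


class TestWilcoxonOneSample:
    def test_perfect_symmetry_is_null(self):
        res = wilcoxon_one_sample([-1, 1, -2, 2, -3, 3])
        assert res.p_value >= 0.9

    def test_all_positive_exact_p(self):
        # all six differences positive: 2 / 2^6
        res = wilcoxon_one_sample([1, 2, 3, 4, 5, 6])
        assert res.p_value == pytest.approx(2 / 64)
        assert res.extra["exact"]

    def test_all_ties_with_mu_error(self):
        with pytest.raises(ValueError, match="no non-zero differences"):
            wilcoxon_one_sample([5.0], mu=5.0)

    def test_zeros_dropped_and_counted(self):
        res = wilcoxon_one_sample([0.0, 0.0, 1.0, 2.0, -1.5])
        assert res.extra["n_zeros_dropped"] == 2
        assert res.n == 3

    def test_exact_p_equals_full_enumeration(self):
        # random small datasets, including exact ties in |d|
        rng = np.random.default_rng(5)
        for _ in range(40):
            n = int(rng.integers(1, 11))
            x = np.round(rng.normal(0.3, 1.0, n), 1)
            x = x[x != 0]
            if x.size == 0:
                continue
            res = wilcoxon_one_sample(x)
            assert res.p_value == pytest.approx(
                _wilcoxon_enumeration_oracle(x), abs=1e-12)

    def test_large_n_normal_approximation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.3, 1.0, 60)
        res = wilcoxon_one_sample(x)
        ref = sps.wilcoxon(x, zero_method="wilcox", correction=True,
                           method="approx")
        assert not res.extra["exact"]
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)


def _kw_h_oracle(groups):
    """Brute-force tie-corrected Kruskal–Wallis H."""
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    idx = 0
    h = 0.0
    for g in groups:
        r = ranks[idx: idx + len(g)]
        idx += len(g)
        h += r.sum() ** 2 / len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie


class TestKruskalDunn:
    def test_identical_groups_null(self):
        omnibus, pairs = kruskal_dunn([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
        assert omnibus.statistic == 0.0 and omnibus.p_value == 1.0
        assert not any(p.extra["significant"] for p in pairs)

    def test_hand_rank_value(self):
        omnibus, _ = kruskal_dunn([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert omnibus.statistic == pytest.approx(7.2, abs=1e-10)

    def test_two_singletons(self):
        omnibus, pairs = kruskal_dunn([[1.0], [2.0]])
        assert np.isfinite(omnibus.statistic)
        assert len(pairs) == 1

    def test_h_matches_bruteforce_on_random_groups(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            k = int(rng.integers(2, 5))
            groups = [
                np.round(rng.normal(size=rng.integers(2, 8)), 1)
                for _ in range(k)
            ]
            if np.ptp(np.concatenate(groups)) == 0:
                continue
            omnibus, _ = kruskal_dunn(groups)
            assert omnibus.statistic == pytest.approx(
                _kw_h_oracle(groups), abs=1e-10)

    def test_dunn_z_hand_formula(self):
        groups = [[1.0, 2.0, 5.0], [3.0, 6.0, 7.0, 9.0], [4.0, 8.0]]
        _, pairs = kruskal_dunn(groups)
        pooled = np.concatenate(groups)
        ranks = sps.rankdata(pooled)
        mr = [ranks[:3].mean(), ranks[3:7].mean(), ranks[7:].mean()]
        n = pooled.size
        base = n * (n + 1) / 12.0
        for t in pairs:
            i, j = t.extra["pair"]
            ns = (len(groups[i]), len(groups[j]))
            z = (mr[i] - mr[j]) / np.sqrt(base * (1 / ns[0] + 1 / ns[1]))
            assert t.statistic == pytest.approx(z, abs=1e-10)

    def test_needs_two_groups(self):
        with pytest.raises(ValueError):
            kruskal_dunn([[1.0, 2.0]])
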