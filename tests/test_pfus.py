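"""Tests of the pfUS analysis chain."""

import numpy as np
import pytest

from clawfc.pfus import (
    FcWindowSeries,
    PfusConfig,
    analyze_pfus_cohort,
    bandpass,
    compare_auc,
    delta_cbv,
    despike,
    group_delta_fc,
    regional_strength,
    windowed_regional_fc,
)
from clawfc.session import SessionEvents
from clawfc.simulate import DEFAULT_ROI_LABELS, PfusSimConfig, gen_pfus

EVENTS = SessionEvents(300.0, 1200.0, 2400.0)


def _ou_trace(rng, n, tau=20.0, sd=1.0):
    phi = np.exp(-1.0 / tau)
    x = np.empty(n)
    x[0] = rng.standard_normal()
    eps = rng.standard_normal(n) * np.sqrt(1 - phi**2)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i]
    return sd * x


class TestDespike:
    def test_constant_trace_untouched(self):
        x = np.full(100, 7.0)
        clean, mask = despike(x)
        np.testing.assert_array_equal(clean, x)
        assert not mask.any()

    def test_inserted_burst_found_and_repaired(self):
        rng = np.random.default_rng(0)
        base = 100 + _ou_trace(rng, 600, sd=2.0) + rng.standard_normal(600)
        corrupted = base.copy()
        corrupted[300:302] *= 1.8
        clean, mask = despike(corrupted)
        assert mask[300] and mask[301]
        rmse_before = np.sqrt(np.mean((corrupted - base) ** 2))
        rmse_after = np.sqrt(np.mean((clean - base) ** 2))
        assert rmse_after <= 0.5 * rmse_before

    def test_burst_at_first_sample(self):
        rng = np.random.default_rng(1)
        base = 100 + rng.standard_normal(200)
        corrupted = base.copy()
        corrupted[0] *= 2.0
        clean, mask = despike(corrupted)
        assert mask[0]
        assert abs(clean[0] - base[1]) < 5  # nearest clean neighbourhood

    def test_too_short_trace(self):
        with pytest.raises(ValueError):
            despike(np.ones(5))


class TestBandpass:
    def test_dc_blocked(self):
        out = bandpass(np.full(2400, 123.0), fs=1.0)
        assert np.max(np.abs(out)) < 1e-6 * 123.0

    @pytest.mark.parametrize("freq,lo,hi", [(0.05, 0.9, 1.1), (0.4, 0.0, 0.1)])
    def test_frequency_response(self, freq, lo, hi):
        t = np.arange(2400.0)
        out = bandpass(np.sin(2 * np.pi * freq * t), fs=1.0)
        # steady-state amplitude away from the edges
        amp = np.max(np.abs(out[400:-400]))
        assert lo <= amp <= hi

    def test_too_short_for_band(self):
        with pytest.raises(ValueError, match="too short"):
            bandpass(np.random.default_rng(0).standard_normal(100), fs=1.0)


class TestDeltaCbv:
    def test_constant_trace_is_zero(self):
        tr = np.full((2400, 2), 100.0)
        _, binned = delta_cbv(tr, 1.0, EVENTS)
        np.testing.assert_allclose(binned, 0.0, atol=1e-12)

    def test_step_change_is_plus_ten_percent(self):
        tr = np.full((2400, 1), 100.0)
        tr[1200:] = 110.0
        bins, binned = delta_cbv(tr, 1.0, EVENTS)
        post = bins >= 1200
        np.testing.assert_allclose(binned[post, 0], 10.0, atol=1e-12)
        np.testing.assert_allclose(binned[~post, 0], 0.0, atol=1e-12)

    def test_non_positive_baseline_rejected(self):
        tr = np.zeros((2400, 1))
        with pytest.raises(ValueError, match="non-positive baseline"):
            delta_cbv(tr, 1.0, EVENTS)

    def test_baseline_window_averages_to_zero(self):
        rng = np.random.default_rng(2)
        tr = 100 + rng.standard_normal((2400, 3))
        _, binned = delta_cbv(tr, 1.0, EVENTS)
        n = tr.shape[0]
        pct = 100 * (tr - tr[900:1200].mean(axis=0)) / tr[900:1200].mean(axis=0)
        assert pct[900:1200].mean() == pytest.approx(0.0, abs=1e-9)


def _fc_oracle(traces, wlen, step):
    """Direct-summation per-window Pearson + atanh, loop form."""
    n, r = traces.shape
    starts = range(0, n - wlen + 1, step)
    out = []
    for s in starts:
        m = np.full((r, r), np.nan)
        for i in range(r):
            for j in range(r):
                if i == j:
                    continue
                xi = traces[s:s + wlen, i]
                xj = traces[s:s + wlen, j]
                num = np.sum((xi - xi.mean()) * (xj - xj.mean()))
                den = np.sqrt(np.sum((xi - xi.mean()) ** 2)
                              * np.sum((xj - xj.mean()) ** 2))
                if den == 0:
                    continue
                rr = np.clip(num / den, -1 + 1e-7, 1 - 1e-7)
                m[i, j] = np.arctanh(rr)
        out.append(m)
    return np.stack(out)


class TestWindowedRegionalFc:
    def test_window_count_standard_session(self):
        rng = np.random.default_rng(0)
        fc = windowed_regional_fc(rng.standard_normal((2400, 4)), 1.0, 300, 60)
        assert fc.n_windows == 36  # floor((2400-300)/60) + 1

    def test_duplicated_roi_hits_clip_ceiling(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(600)
        fc = windowed_regional_fc(np.column_stack([x, x, rng.standard_normal(600)]),
                                  1.0, 100, 50)
        ceiling = np.arctanh(1 - 1e-7)
        np.testing.assert_allclose(fc.z[:, 0, 1], ceiling, rtol=1e-9)

    def test_matches_direct_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((700, 4))
        fc = windowed_regional_fc(x, 1.0, 120, 40)
        oracle = _fc_oracle(x, 120, 40)
        np.testing.assert_allclose(fc.z, oracle, atol=1e-12)

    def test_zero_variance_pair_is_missing(self):
        x = np.column_stack([np.ones(300),
                             np.random.default_rng(0).standard_normal(300)])
        fc = windowed_regional_fc(x, 1.0, 100, 100)
        assert np.all(np.isnan(fc.z[:, 0, 1]))

    def test_no_window_fits(self):
        with pytest.raises(ValueError, match="window"):
            windowed_regional_fc(np.random.default_rng(0).standard_normal((50, 3)),
                                 1.0, 100, 10)


class TestRegionalStrength:
    def _series(self, z):
        n_w, r, _ = z.shape
        return FcWindowSeries(np.arange(n_w) * 60.0, z, 300,
                              list(DEFAULT_ROI_LABELS[:r]), window_s=300.0)

    def test_constant_edges(self):
        z = np.full((3, 8, 8), 0.4)
        for w in range(3):
            np.fill_diagonal(z[w], np.nan)
        s = regional_strength(self._series(z), "ACA-L")
        np.testing.assert_allclose(s, 0.4, atol=1e-12)

    def test_edge_list_oracle(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal((4, 8, 8))
        z = (z + z.transpose(0, 2, 1)) / 2
        for w in range(4):
            np.fill_diagonal(z[w], np.nan)
        fcs = self._series(z)
        for j, lbl in enumerate(fcs.roi_labels):
            manual = np.array([
                np.mean([z[w, j, i] for i in range(8) if i != j])
                for w in range(4)
            ])
            np.testing.assert_allclose(regional_strength(fcs, lbl), manual,
                                       atol=1e-12)
        # 7 incident edges per ROI in the 8-ROI set
        assert sum(i != 0 for i in range(8)) == 7


def _make_series(values, starts, window_s=300.0):
    """FcWindowSeries whose PFC-SM mean equals `values` per window."""
    n_w = len(values)
    z = np.zeros((n_w, 8, 8))
    for w, v in enumerate(values):
        z[w] = v
        np.fill_diagonal(z[w], np.nan)
    return FcWindowSeries(np.asarray(starts, float), z, int(window_s),
                          list(DEFAULT_ROI_LABELS), window_s=window_s)


class TestGroupDeltaFc:
    def test_identical_windows_give_zero_delta_and_auc(self):
        starts = np.arange(0, 2101, 60.0)
        fcs = [_make_series([0.5] * len(starts), starts) for _ in range(3)]
        summary = group_delta_fc(fcs, EVENTS)
        np.testing.assert_allclose(summary.delta, 0.0, atol=1e-12)
        np.testing.assert_allclose(summary.auc, 0.0, atol=1e-12)

    def test_constant_delta_rectangle_auc(self):
        # post-drug window starts span 1200 s with a constant +0.2 delta
        events = SessionEvents(300.0, 1200.0, 2700.0)
        starts = np.arange(0, 2401, 60.0)
        values = [0.3 if s < 1200 else 0.5 for s in starts]
        fcs = [_make_series(values, starts) for _ in range(2)]
        summary = group_delta_fc(fcs, events)
        assert summary.baseline_time_s == 900.0
        np.testing.assert_allclose(summary.auc, 0.2 * 1200.0, atol=1e-9)

    def test_auc_group_comparison(self):
        res = compare_auc(np.array([1.0, 1.2, 0.9, 1.1]),
                          np.array([0.1, -0.2, 0.05, 0.0]))
        assert res.p_value < 0.01

    def test_baseline_window_is_final_predrug(self):
        starts = np.arange(0, 2101, 60.0)
        fcs = [_make_series(np.linspace(0, 1, len(starts)), starts)]
        summary = group_delta_fc(fcs, EVENTS)
        assert summary.baseline_time_s == 900.0  # [900, 1200) before drug


class TestCohortPipeline:
    def test_deterministic(self):
        subs, _ = gen_pfus(PfusSimConfig(n_subjects=2, seed=11))
        r1 = analyze_pfus_cohort(subs)
        r2 = analyze_pfus_cohort(subs)
        np.testing.assert_array_equal(r1.delta_fc.delta, r2.delta_fc.delta)
        np.testing.assert_array_equal(r1.cbv.percent, r2.cbv.percent)

    def test_positive_coupling_gives_positive_delta(self):
        subs, _ = gen_pfus(PfusSimConfig(n_subjects=6, seed=21))
        res = analyze_pfus_cohort(subs)
        post = res.delta_fc.times >= 1200
        assert np.nanmean(res.delta_fc.mean_delta[post]) > 0

    def test_cbv_trough_near_injected_drop(self):
        subs, _ = gen_pfus(PfusSimConfig(n_subjects=10, seed=31))
        res = analyze_pfus_cohort(subs)
        trough = res.cbv.trough(["ACA-L", "ACA-R", "MOs-L", "MOs-R"])
        assert -22.0 < trough < -8.0
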