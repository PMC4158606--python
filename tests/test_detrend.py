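import math

import numpy as np
import pandas as pd
import pytest

from lspdetrend import (
    MonthlyCounts,
    SimConfig,
    TrendAdjuster,
    build_shared_seasonal,
    detotal_series,
    detrend_series,
    scan_all,
    smooth_series,
    simulate_counts,
)
from lspdetrend.detrend import SharedSeasonal
from lspdetrend.periodicity import lomb_scargle, period_grid, scan_series
from lspdetrend.synthetic import expected_means


def _axis(n, start=2000.0):
    return start + (np.arange(n) + 0.5) / 12.0


def _nw_oracle(y, tm, h):
    """Independent brute-force Nadaraya-Watson evaluation."""
    out = np.empty_like(y, dtype=float)
    for j in range(len(y)):
        w = [math.exp(-0.5 * ((tm[i] - tm[j]) / h) ** 2) for i in range(len(y))]
        out[j] = sum(wi * yi for wi, yi in zip(w, y)) / sum(w)
    return out


class TestSmoothSeries:
    def test_constant_series_maps_to_itself(self):
        trend, h = smooth_series(np.full(60, 7.0), _axis(60))
        assert np.allclose(trend, 7.0)
        assert h >= 9.0

    def test_matches_independent_weighted_average(self):
        rng = np.random.default_rng(3)
        y = 50 + 2 * np.arange(80) + rng.normal(0, 3, 80)
        trend, h = smooth_series(y, _axis(80), bandwidth=10.0)
        assert np.allclose(trend, _nw_oracle(y, np.arange(80.0), 10.0), rtol=1e-12)

    def test_linear_ramp_tracked_in_interior(self):
        y = 10.0 + 1.5 * np.arange(120)
        trend, h = smooth_series(y, _axis(120))
        interior = slice(math.ceil(2 * h), 120 - math.ceil(2 * h))
        dev = np.abs(trend[interior] - y[interior])
        assert dev.max() < 0.05 * (y.max() - y.min())

    def test_seasonal_signal_survives_detrending(self):
        # Gaussian smoothing attenuates a cosine of period T by
        # exp(-(2*pi*h/T)^2/2); at h=12, T=12 the trend holds ~none of it,
        # so the detrended series keeps essentially the full amplitude.
        t = np.arange(120.0)
        y = 100 + 20 * np.cos(2 * np.pi * t / 12)
        adj = detrend_series(y, _axis(120), bandwidth=12.0)
        kept = adj.detrended
        amp = (kept.max() - kept.min()) / 2
        assert amp >= 0.8 * 20

    def test_all_zero_series_returns_zero_trend(self):
        trend, h = smooth_series(np.zeros(48), _axis(48))
        assert not trend.any() and math.isnan(h)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            smooth_series(np.ones(12), _axis(12))


class TestDetrendSeries:
    def test_constant_series_detrends_to_zero(self):
        adj = detrend_series(np.full(120, 42.0), _axis(120))
        assert np.allclose(adj.detrended, 0.0, atol=1e-9)

    def test_trim_is_two_bandwidths_each_end(self):
        adj = detrend_series(np.full(120, 5.0), _axis(120), bandwidth=6.0)
        assert adj.trim == 12
        assert adj.time.size == 96

    def test_detrended_mean_near_zero_for_noisy_ramp(self):
        rng = np.random.default_rng(8)
        mu = 100 + np.arange(120)
        y = rng.poisson(mu).astype(float)
        adj = detrend_series(y, _axis(120))
        se = y[adj.trim:-adj.trim].std() / math.sqrt(adj.time.size)
        assert abs(adj.detrended.mean()) < 2 * se

    def test_overtrimmed_series_rejected(self):
        with pytest.raises(ValueError, match="fewer than"):
            detrend_series(np.full(40, 5.0), _axis(40), bandwidth=9.0)

    def test_detrending_removes_low_frequency_power(self):
        rng = np.random.default_rng(21)
        y = rng.poisson(100 + 2.0 * np.arange(156)).astype(float)
        adj = detrend_series(y, _axis(156))
        tm = np.arange(156.0)[adj.trim:-adj.trim]
        freqs = 1.0 / np.linspace(60, 100, 25)  # periods beyond 5 years
        before = lomb_scargle(adj.raw, tm, freqs)
        after = lomb_scargle(adj.detrended, tm, freqs)
        assert before.max() / after.max() >= 10


class TestSharedSeasonal:
    def test_identical_codes_have_half_scale(self):
        months = pd.period_range("2000-01", periods=120, freq="M")
        row = np.random.default_rng(0).poisson(50, 120)
        counts = MonthlyCounts(pd.DataFrame([row, row], index=["a", "b"],
                                            columns=months))
        shared = build_shared_seasonal(counts)
        assert shared.scale["a"] == pytest.approx(0.5)
        assert shared.scale["b"] == pytest.approx(0.5)
        assert abs(np.mean(shared.total_detrended)) < 1.0

    def test_single_code_matrix_rejected(self):
        months = pd.period_range("2000-01", periods=60, freq="M")
        counts = MonthlyCounts(pd.DataFrame([np.ones(60, int)], index=["a"],
                                            columns=months))
        with pytest.raises(ValueError, match="at least 2"):
            build_shared_seasonal(counts)

    def test_total_with_six_month_oscillation_peaks_at_six(self):
        cfg = SimConfig(n_codes=6, months=156, baseline_rates=800.0, seed=4)
        sim = simulate_counts(cfg, materialize_events=False)
        shared = build_shared_seasonal(sim.counts)
        r = scan_series(shared.total_detrended, shared.time * 12.0)
        assert r.best_period == pytest.approx(6.0, abs=0.25)
        assert r.p_value < 1e-6


class TestDetotal:
    def test_exact_fixed_proportion_code_flattens(self):
        # chronic code = 10% of a large seasonal total, counts rounded
        cfg = SimConfig(n_codes=4, months=156, baseline_rates=40000.0,
                        chronic_fraction={3: 0.01}, seed=0)
        mu = expected_means(cfg)
        months = pd.period_range("1997-01", periods=156, freq="M")
        counts = MonthlyCounts(pd.DataFrame(np.round(mu).astype(int),
                                            index=list("abcd"), columns=months))
        adj = TrendAdjuster().fit(counts)
        chronic = adj.adjusted_["d"]
        assert np.abs(chronic.detotaled).max() < 0.01 * chronic.raw.mean()

    def test_independent_code_keeps_its_own_power(self):
        # noiseless 12-month signal on a code while the total carries only
        # the shared 6-month factor elsewhere
        t = np.arange(156.0)
        own = 100 * (1 + 0.4 * np.cos(2 * np.pi * t / 12))
        ax = _axis(156)
        adj = detrend_series(own, ax, code="x")
        tot = 5000 * (1 + 0.1 * np.cos(2 * np.pi * t / 6))
        adj_tot = detrend_series(tot, ax, code="<total>", trim=adj.trim)
        shared = SharedSeasonal(
            time=adj_tot.time, total_detrended=adj_tot.detrended,
            scale={"x": own.mean() / tot.mean()},
            bandwidth=adj_tot.bandwidth, trim=adj_tot.trim)
        out = detotal_series(adj, shared)
        tm = t[adj.trim:-adj.trim]
        grid = period_grid(tm)
        p_before = lomb_scargle(adj.detrended, tm, grid)
        p_after = lomb_scargle(out.detotaled, tm, grid)
        i = np.argmin(np.abs(1 / grid - 12.0))
        assert p_after[i] == pytest.approx(p_before[i], rel=0.10)

    def test_zero_shared_component_is_identity(self):
        adj = detrend_series(np.random.default_rng(1).poisson(50, 120).astype(float),
                             _axis(120), code="x")
        shared = SharedSeasonal(time=adj.time,
                                total_detrended=np.zeros_like(adj.time),
                                scale={"x": 0.3}, bandwidth=9.0, trim=adj.trim)
        out = detotal_series(adj, shared)
        assert np.array_equal(out.detotaled, adj.detrended)

    def test_axis_mismatch_rejected(self):
        adj = detrend_series(np.full(120, 30.0), _axis(120), code="x")
        shared = SharedSeasonal(time=adj.time[:-1] + 1,
                                total_detrended=np.zeros(adj.time.size - 1),
                                scale={"x": 0.5}, bandwidth=9.0, trim=adj.trim)
        with pytest.raises(ValueError, match="axis"):
            detotal_series(adj, shared)


class TestTrendAdjuster:
    def test_confound_reproduced_then_removed(self, confound_sim):
        """Chronic-fraction codes look 6-month periodic after de-trending
        alone and are flattened by de-totaling (the false-detection
        mechanism and its correction)."""
        sim, chronic = confound_sim
        adj = TrendAdjuster().fit(sim.counts)
        detrended = scan_all(adj.adjusted_, stage="detrended")
        detotaled = scan_all(adj.adjusted_, stage="detotaled")
        d = detrended.set_index("code").loc[chronic]
        flagged = d["significant"]
        assert flagged.mean() > 0.5
        assert (np.abs(d.loc[flagged, "best_period"] - 6.0) < 0.5).mean() > 0.9
        assert detotaled.set_index("code").loc[chronic, "significant"].mean() <= 0.05

    def test_transform_shape_and_alignment(self):
        cfg = SimConfig(n_codes=5, months=120, baseline_rates=60.0, seed=3)
        sim = simulate_counts(cfg, materialize_events=False)
        adj = TrendAdjuster().fit(sim.counts)
        mat = adj.transform(sim.counts)
        assert mat.shape == (5, 120 - 2 * adj.trim_)
        assert list(mat.index) == sim.counts.codes
        a = adj.adjusted_[sim.counts.codes[0]]
        assert a.time.size == a.raw.size == a.detrended.size == a.detotaled.size

    def test_sklearn_params_round_trip(self):
        est = TrendAdjuster(bandwidth=11.0, detotal=False)
        params = est.get_params()
        assert params["bandwidth"] == 11.0 and params["detotal"] is False
        est.set_params(bandwidth=None)
        assert est.get_params()["bandwidth"] is None
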