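"""Correlation estimators against a literal brute-force oracle, plus the
multi-tau scheme's grid and equivalence guarantees."""

import numpy as np
import pytest

from polfcs import (
    CorrelationCurve,
    PhotonTrace,
    average_curves,
    direct_correlate,
    multitau_correlate,
    multitau_lag_grid,
)

from conftest import light_config


def brute_force_g(i1, i2, k):
    """Literal symmetric-normalized estimator, written independently."""
    n = len(i1)
    num = sum(i1[t] * i2[t + k] for t in range(n - k)) / (n - k)
    m1 = sum(i1[t] for t in range(n - k)) / (n - k)
    m2 = sum(i2[t + k] for t in range(n - k)) / (n - k)
    return num / (m1 * m2) - 1.0


def make_trace(c0, c1, bin_width=1e-6):
    return PhotonTrace(np.asarray(c0), np.asarray(c1), bin_width=bin_width)


class TestDirectCorrelate:
    def test_constant_trace_has_zero_correlation(self):
        trace = make_trace([3] * 100, [3] * 100)
        curve = direct_correlate(trace, max_lag_bins=10)
        np.testing.assert_allclose(curve.values, 0.0, atol=1e-14)

    def test_alternating_trace_anticorrelates_at_one_bin(self):
        c = [0, 1] * 50
        curve = direct_correlate(make_trace(c, c), max_lag_bins=4)
        assert curve.values[0] == pytest.approx(-1.0, abs=1e-12)
        assert curve.values[1] == pytest.approx(1.0, abs=0.05)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        i1 = rng.poisson(2.0, size=400)
        i2 = rng.poisson(3.0, size=400)
        trace = make_trace(i1, i2)
        curve = direct_correlate(trace, max_lag_bins=25)
        expected = [brute_force_g(i1, i2, k) for k in range(1, 26)]
        np.testing.assert_allclose(curve.values, expected, atol=1e-12)

    def test_independent_streams_decorrelate(self):
        rng = np.random.default_rng(11)
        trace = make_trace(rng.poisson(5.0, 200_000), rng.poisson(5.0, 200_000))
        curve = direct_correlate(trace, max_lag_bins=50)
        assert np.all(np.abs(curve.values) < 5e-3)

    def test_zero_mean_channel_rejected(self):
        with pytest.raises(ValueError):
            direct_correlate(make_trace([0] * 100, [1] * 100), max_lag_bins=5)

    def test_max_lag_bounds_enforced(self):
        with pytest.raises(ValueError):
            direct_correlate(make_trace([1] * 100, [1] * 100), max_lag_bins=60)


class TestMultiTau:
    def test_stage_zero_equals_direct(self):
        rng = np.random.default_rng(3)
        trace = make_trace(rng.poisson(1.0, 5000), rng.poisson(1.0, 5000))
        mt = multitau_correlate(trace, m=16, p=2)
        direct = direct_correlate(trace, max_lag_bins=16)
        np.testing.assert_allclose(mt.values[:16], direct.values, atol=1e-13)

    def test_coarsened_stages_equal_direct_on_rebinned_trace(self):
        rng = np.random.default_rng(5)
        trace = make_trace(rng.poisson(0.8, 20000), rng.poisson(1.2, 20000))
        m, p = 16, 2
        mt = multitau_correlate(trace, m=m, p=p)
        for stage, raw_lags in multitau_lag_grid(len(trace), m, p):
            if stage == 0:
                continue
            f = p**stage
            nb = (len(trace) // f) * f
            reb = make_trace(
                trace.counts_ch0[:nb].reshape(-1, f).sum(axis=1),
                trace.counts_ch1[:nb].reshape(-1, f).sum(axis=1),
                bin_width=trace.bin_width * f,
            )
            ref = direct_correlate(reb, max_lag_bins=m)
            for lag in raw_lags:
                i_mt = np.nonzero(np.isclose(mt.lags, lag * trace.bin_width))[0][0]
                i_ref = np.nonzero(np.isclose(ref.lags, lag * trace.bin_width))[0][0]
                assert mt.values[i_mt] == pytest.approx(ref.values[i_ref], abs=1e-12)

    def test_lag_grid_spans_six_decades_for_30s_measurement(self):
        # bin width 10 ns, duration 30 s
        n_bins = int(30.0 / 1e-8)
        grid = multitau_lag_grid(n_bins, m=16, p=2)
        lags = np.concatenate([raw for _, raw in grid]) * 1e-8
        assert lags.min() == pytest.approx(1e-8)
        assert lags.max() / lags.min() >= 1e6

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            multitau_correlate(make_trace([1] * 40, [1] * 40), m=16, p=2)


class TestAverageCurves:
    def _curve(self, values, errors=None):
        lags = np.arange(1, len(values) + 1) * 1e-6
        return CorrelationCurve(lags=lags, values=np.asarray(values, float), errors=errors)

    def test_identical_curves_average_to_input_with_zero_errors(self):
        curves = [self._curve([1.0, 0.5, 0.2])] * 10
        avg = average_curves(curves)
        np.testing.assert_allclose(avg.values, [1.0, 0.5, 0.2])
        np.testing.assert_allclose(avg.errors, 0.0, atol=1e-15)
        assert avg.n_repeats == 10

    def test_symmetric_pair_mean_zero_sd_sqrt2(self):
        v = np.array([0.3, -0.1, 0.7])
        avg = average_curves([self._curve(v), self._curve(-v)])
        np.testing.assert_allclose(avg.values, 0.0, atol=1e-15)
        np.testing.assert_allclose(avg.errors, np.abs(v) * np.sqrt(2.0), rtol=1e-12)

    def test_mismatched_grids_rejected(self):
        a = self._curve([1.0, 0.5, 0.2])
        b = CorrelationCurve(lags=[1e-6, 2e-6], values=[1.0, 0.5])
        with pytest.raises(ValueError):
            average_curves([a, b])


class TestTraceIO:
    def test_csv_round_trip_with_metadata(self, tmp_path):
        rng = np.random.default_rng(2)
        trace = PhotonTrace(rng.poisson(1, 100), rng.poisson(1, 100),
                            bin_width=2e-9, config="X-XX", seed=42)
        path = tmp_path / "trace.csv"
        trace.write(path)
        back = PhotonTrace.read(path)
        np.testing.assert_array_equal(back.counts_ch0, trace.counts_ch0)
        np.testing.assert_array_equal(back.counts_ch1, trace.counts_ch1)
        assert back.bin_width == trace.bin_width
        assert back.config.label == "X-XX"
        assert back.seed == 42

    def test_invalid_traces_rejected(self):
        with pytest.raises(ValueError):
            PhotonTrace(np.array([1, 2]), np.array([1]), bin_width=1e-9)
        with pytest.raises(ValueError):
            PhotonTrace(np.array([-1, 2]), np.array([1, 1]), bin_width=1e-9)


class TestStatisticalProperties:
    def test_channel_swap_symmetry_in_expectation(self, monomer):
        # cross-correlating (ch0, ch1) vs (ch1, ch0): estimator means agree
        # over seeds within Monte Carlo error for a stationary process
        diffs = []
        for seed in range(61, 73):
            cfg = light_config(seed=seed, duration=4e-3)
            from polfcs import simulate_photon_traces

            tr = simulate_photon_traces(monomer, cfg)
            fwd = direct_correlate(tr, max_lag_bins=30).values
            swapped = PhotonTrace(tr.counts_ch1, tr.counts_ch0, bin_width=tr.bin_width)
            rev = direct_correlate(swapped, max_lag_bins=30).values
            diffs.append(fwd - rev)
        diffs = np.asarray(diffs)
        mean = diffs.mean(axis=0)
        se = diffs.std(axis=0, ddof=1) / np.sqrt(diffs.shape[0])
        assert np.all(np.abs(mean) <= 4 * se + 1e-3)

    def test_rescaling_both_channels_leaves_g_invariant(self):
        rng = np.random.default_rng(17)
        i1 = rng.poisson(2.0, 5000)
        i2 = rng.poisson(2.0, 5000)
        a = direct_correlate(make_trace(i1, i2), max_lag_bins=20).values
        b = direct_correlate(make_trace(7 * i1, 3 * i2), max_lag_bins=20).values
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_amplitude_matches_occupancy(self, light_xx_fit):
        # fitted 1/G(0+) approximates the mean occupancy of the volume
        result, _, cfg = light_xx_fit
        fitted_n = result.params_per_curve[0].n_molecules
        assert fitted_n == pytest.approx(cfg.mean_occupancy(), rel=0.2)

    def test_repeat_error_band_covers_model_curve(self, monomer):
        # 10 seeded repeats: the mean +/- 2 SD band contains the noiseless
        # model at >= 90% of lags
        from polfcs import FCSModelParams, model_ccf, simulate_photon_traces

        curves = []
        for k in range(10):
            cfg = light_config(seed=700 + 13 * k, duration=4e-3)
            tr = simulate_photon_traces(monomer, cfg)
            curves.append(multitau_correlate(tr, max_lag=5e-5))
        avg = average_curves(curves)
        from conftest import SPEC4
        from polfcs import FitSpec, fit_curve

        fit = fit_curve(avg, FitSpec(**SPEC4))
        model = model_ccf(avg.lags, fit.params_per_curve[0])
        inside = np.abs(model - avg.values) <= 2 * avg.errors + 1e-12
        assert inside.mean() >= 0.9
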