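import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lumigain.errors import DivisionDegenerateError, InvalidSpecError
from lumigain.imaging_analysis import (
    FWHM_PER_SIGMA,
    STRF,
    RoiTraceSet,
    compute_strf,
    contrast_luminance_map,
    dff,
    edge_response,
    epoch_f1_amplitudes,
    extract_filters,
    f1_amplitude,
    filter_strfs,
    fit_gaussian_1d,
    luminance_slope,
    map_rf_center,
    roi_reliability,
)


class TestDff:
    def test_constant_trace_maps_to_zero(self):
        np.testing.assert_allclose(dff(np.full((1, 10), 5.0)), 0.0)

    def test_two_point_trace(self):
        np.testing.assert_allclose(dff(np.array([[1.0, 3.0]])), [[-0.5, 0.5]])

    def test_prelude_baseline(self):
        trace = np.concatenate([np.full(40, 2.0), np.full(10, 3.0)])[None]
        out = dff(trace, baseline_mode="prelude_mean", frame_rate=10.0)
        assert out[0, -1] == pytest.approx(0.5)

    def test_trace_mean_output_has_zero_mean(self, rng):
        out = dff(rng.uniform(1, 5, size=(3, 200)))
        assert np.max(np.abs(out.mean(axis=1))) < 1e-12

    def test_zero_baseline_names_roi(self):
        with pytest.raises(DivisionDegenerateError, match=r"\[1\]"):
            dff(np.array([[1.0, 2.0], [0.0, 0.0]]))


class TestReliability:
    def test_identical_trials_fully_reliable(self, rng):
        t = rng.normal(size=50)
        value, keep = roi_reliability([t, t.copy(), t.copy()])
        assert value == pytest.approx(1.0)
        assert keep

    def test_anticorrelated_trials_rejected(self, rng):
        t = rng.normal(size=50)
        value, keep = roi_reliability([t, -t])
        assert value == pytest.approx(-1.0)
        assert not keep

    def test_mean_of_pairwise_correlations(self, rng):
        trials = [rng.normal(size=80) for _ in range(4)]
        value, _ = roi_reliability(trials)
        # independent oracle: explicit loop over pairs
        corrs = []
        for i in range(4):
            for j in range(i + 1, 4):
                corrs.append(np.corrcoef(trials[i], trials[j])[0, 1])
        assert value == pytest.approx(np.mean(corrs), abs=1e-12)

    def test_zero_variance_trial_flagged(self):
        value, keep = roi_reliability([np.zeros(10), np.arange(10.0)])
        assert np.isnan(value) and not keep


class TestF1Amplitude:
    def test_pure_tone_returns_its_amplitude(self):
        t = np.arange(0, 4, 0.1)
        assert f1_amplitude(2 * np.sin(2 * np.pi * t), 1.0, 10.0) == pytest.approx(2.0)

    def test_constant_trace_is_zero(self):
        assert f1_amplitude(np.ones(40), 1.0, 10.0) == pytest.approx(0.0)

    def test_orthogonal_tones_ignored(self):
        t = np.arange(0, 4, 0.05)
        trace = 1.5 * np.sin(2 * np.pi * t) + 0.7 * np.sin(2 * np.pi * 3 * t)
        assert f1_amplitude(trace, 1.0, 20.0) == pytest.approx(1.5, abs=1e-10)

    @settings(max_examples=25, deadline=None)
    @given(
        amp=st.floats(0.01, 10.0),
        phase=st.floats(0.0, 2 * np.pi),
    )
    def test_linear_in_amplitude_invariant_to_phase(self, amp, phase):
        t = np.arange(0, 4, 0.05)
        trace = amp * np.sin(2 * np.pi * t + phase)
        assert f1_amplitude(trace, 1.0, 20.0) == pytest.approx(amp, rel=1e-9)

    def test_above_nyquist_rejected(self):
        with pytest.raises(InvalidSpecError):
            f1_amplitude(np.ones(100), 6.0, 10.0)


class TestLuminanceSlope:
    def test_recovers_planted_log_slope(self):
        L = np.array([0.05, 0.1, 0.2, 0.4, 0.5])
        assert luminance_slope(L, 0.2 * np.log10(L) + 1) == pytest.approx(0.2)

    def test_flat_responses_have_zero_slope(self):
        assert luminance_slope([0.1, 0.2, 0.4], [1.0, 1.0, 1.0]) == pytest.approx(0.0)

    def test_matches_normal_equations_oracle(self, rng):
        L = np.array([0.05, 0.1, 0.2, 0.4, 0.5])
        y = 0.3 * np.log10(L) + rng.normal(0, 0.05, 5)
        x = np.log10(L)
        beta = np.linalg.solve(
            np.array([[len(x), x.sum()], [x.sum(), (x**2).sum()]]),
            np.array([y.sum(), (x * y).sum()]),
        )
        assert luminance_slope(L, y) == pytest.approx(beta[1], abs=1e-12)

    def test_single_luminance_rejected(self):
        with pytest.raises(InvalidSpecError):
            luminance_slope([0.3, 0.3], [1.0, 2.0])


class TestEdgeResponse:
    def test_peak_minus_pre_mean(self):
        trace = np.concatenate([np.full(10, 1.0), [2.0, 3.0, 2.0], np.full(5, 1.0)])
        out = edge_response(trace, frame_rate=10.0, edge_start=1.0, edge_end=1.3)
        assert out == pytest.approx(2.0)

    def test_flat_trace_gives_zero(self):
        out = edge_response(np.ones(30), frame_rate=10.0, edge_start=1.0)
        assert out == pytest.approx(0.0)

    def test_windows_validated(self):
        with pytest.raises(InvalidSpecError):
            edge_response(np.ones(5), frame_rate=10.0, edge_start=2.0)


class TestContrastLuminanceMap:
    def test_zoom_by_five_gives_25x25(self):
        out = contrast_luminance_map(np.random.default_rng(0).random((5, 5)))
        assert out.interpolated.shape == (25, 25)

    def test_constant_grid_flags_degenerate(self):
        out = contrast_luminance_map(np.full((5, 5), 2.0))
        assert out.degenerate
        np.testing.assert_allclose(out.interpolated, 2.0)

    def test_order1_zoom_exact_on_linear_ramp(self):
        i, j = np.mgrid[:5, :5]
        grid = 2.0 * i + 3.0 * j
        out = contrast_luminance_map(grid, smoothing_sigma=0.0)
        ii, jj = np.mgrid[:25, :25]
        expected = 2.0 * ii * (4 / 24) + 3.0 * jj * (4 / 24)
        np.testing.assert_allclose(out.interpolated, expected, atol=1e-9)

    def test_eight_contour_levels(self):
        out = contrast_luminance_map(np.random.default_rng(1).random((5, 5)))
        assert len(out.contour_levels) == 8
        assert np.all(np.diff(out.contour_levels) > 0)


def _ln_simulation(n_updates, weights, noise_sd, seed, gain=1.0):
    """Instantaneous linear neuron driven by ternary noise (fluorescence)."""
    rng = np.random.default_rng(seed)
    S = rng.integers(0, 3, size=(n_updates, len(weights))) - 1.0  # {-1,0,1}
    r = gain * (S @ weights)
    r = r + noise_sd * r.std() * rng.standard_normal(n_updates)
    return S, 100.0 * (1.0 + 0.2 * r / np.abs(r).max())


class TestStrf:
    def test_recovers_planted_instantaneous_filter(self):
        x = np.arange(12)
        w = np.exp(-((x - 5.0) ** 2) / (2 * 2.0**2))
        S, trace = _ln_simulation(12000, w, noise_sd=0.5, seed=0)
        strf = compute_strf(trace, 20.0, S, prelude_duration=0.0)
        corr = np.corrcoef(strf.kernel[0], w)[0, 1]
        assert corr > 0.95

    def test_constant_response_gives_null_kernel(self):
        rng = np.random.default_rng(2)
        S = rng.integers(0, 3, size=(4000, 8)) - 1.0
        strf = compute_strf(np.full(4000, 50.0), 20.0, S, prelude_duration=0.0)
        # mean-centering makes a stimulus-independent response exactly null
        assert strf.amplitude < 1e-12

    def test_shift_equivariance(self):
        x = np.arange(10)
        w = np.exp(-((x - 4.0) ** 2) / (2 * 1.5**2))
        rng = np.random.default_rng(3)
        S = rng.integers(0, 3, size=(8000, 10)) - 1.0
        r = S @ w
        k_shift = 5
        r_shifted = np.concatenate([np.zeros(k_shift), r[:-k_shift]])
        s0 = compute_strf(100 + r, 20.0, S, prelude_duration=0.0)
        s1 = compute_strf(100 + r_shifted, 20.0, S, prelude_duration=0.0)
        lag0 = np.unravel_index(np.argmax(np.abs(s0.kernel)), s0.kernel.shape)[0]
        lag1 = np.unravel_index(np.argmax(np.abs(s1.kernel)), s1.kernel.shape)[0]
        assert lag1 - lag0 == k_shift

    def test_error_halves_when_data_quadruples(self):
        x = np.arange(10)
        w = np.exp(-((x - 4.0) ** 2) / (2 * 1.5**2))
        w = w / np.linalg.norm(w)

        def kernel_error(n, seed):
            rng = np.random.default_rng(seed)
            S = rng.integers(0, 3, size=(n, 10)) - 1.0
            r = S @ w + 2.0 * rng.standard_normal(n)
            strf = compute_strf(100 + r, 20.0, S, prelude_duration=0.0)
            k0 = strf.kernel[0]
            scale = k0 @ w
            return np.linalg.norm(k0 - scale * w)

        errs_small = np.mean([kernel_error(3000, s) for s in range(6)])
        errs_big = np.mean([kernel_error(12000, s + 100) for s in range(6)])
        ratio = errs_big / errs_small
        assert 0.5 * 0.7 < ratio < 0.5 * 1.3

    def test_too_short_stimulus_rejected(self):
        with pytest.raises(InvalidSpecError):
            compute_strf(np.ones(10), 20.0, np.ones((10, 4)), prelude_duration=0.0)


class TestFilterStrfs:
    def _make(self, amp, structured=False):
        k = np.zeros((40, 8))
        if structured:
            k[5, 3] = -amp  # single sharp peak: high SNR
        else:
            k += amp / 3
            k[5, 3] = amp
        return STRF(kernel=k, update_rate=20.0, window=2.0)

    def test_default_amplitude_threshold(self):
        low, high = self._make(0.004), self._make(0.006)
        kept = filter_strfs([low, high])
        assert kept == [high]
        assert not low.accepted and high.accepted

    def test_low_snr_mode_requires_both(self):
        sharp = self._make(0.004, structured=True)  # SNR = 320 >> 10
        kept = filter_strfs([sharp], mode="low_snr")
        assert sharp.snr > 10
        assert kept == [sharp]
        flat = self._make(0.004)  # SNR ~ 2.3
        assert filter_strfs([flat], mode="low_snr") == []


class TestExtractFilters:
    def test_fwhm_constant(self):
        x = np.linspace(-20, 20, 81)
        fit = fit_gaussian_1d(x, np.exp(-(x**2) / 2))
        assert fit.fwhm / fit.sigma == pytest.approx(2.355, abs=5e-4)
        assert FWHM_PER_SIGMA == pytest.approx(2.3548, abs=1e-4)

    def test_sigma_4_25_gives_fwhm_10(self):
        x = np.linspace(-30, 30, 121)
        fit = fit_gaussian_1d(x, 0.8 * np.exp(-(x**2) / (2 * 4.25**2)))
        assert fit.fwhm == pytest.approx(10.0, abs=0.05)

    def test_separable_strf_profiles_recovered(self):
        lags = np.arange(40)
        x = np.arange(16)
        w_t = -np.exp(-((lags - 8.0) ** 2) / (2 * 3.0**2))  # OFF: negative
        g_x = np.exp(-((x - 7.0) ** 2) / (2 * 2.0**2))
        strf = STRF(kernel=np.outer(w_t, g_x), update_rate=20.0, window=2.0)
        spatial, temporal, fit = extract_filters(strf)
        for got, want in [(spatial, w_t.min() * g_x), (temporal, w_t * g_x.max())]:
            got_n = got / np.linalg.norm(got)
            want_n = want / np.linalg.norm(want)
            assert np.abs(got_n @ want_n) > 0.99


class TestRfCenter:
    @staticmethod
    def _rf(cx, cy, h=-1.0, wx=3.0, wy=3.0, n=24, extent=60.0, noise=0.0, rng=None):
        coords = (np.arange(n) + 0.5) * (extent / n) - extent / 2
        xx, yy = np.meshgrid(coords, coords)
        rf = h * np.exp(-(((cx - xx) / wx) ** 2 + ((cy - yy) / wy) ** 2) / 2)
        if noise:
            rf = rf + noise * abs(h) * rng.standard_normal(rf.shape)
        return coords, rf

    def test_noiseless_self_fit(self):
        coords, rf = self._rf(10.0, -5.0)
        fit = map_rf_center(rf, x_deg=coords, y_deg=coords)
        assert fit.center_x == pytest.approx(10.0, abs=0.1)
        assert fit.center_y == pytest.approx(-5.0, abs=0.1)

    def test_symmetric_input_centers_at_symmetry_point(self):
        coords, rf = self._rf(0.0, 0.0)
        fit = map_rf_center(rf, x_deg=coords, y_deg=coords)
        assert abs(fit.center_x) < 1e-6 and abs(fit.center_y) < 1e-6

    def test_center_within_one_degree_under_noise(self):
        errs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            coords, rf = self._rf(8.0, 3.0, noise=0.1, rng=rng)
            fit = map_rf_center(rf, x_deg=coords, y_deg=coords)
            errs.append(np.hypot(fit.center_x - 8.0, fit.center_y - 3.0))
        assert np.max(errs) < 1.0


class TestEpochF1:
    def test_per_epoch_amplitudes(self):
        fs, f = 20.0, 1.0
        t = np.arange(0, 4, 1 / fs)
        trace = np.concatenate([2.0 * np.sin(2 * np.pi * t), 0.5 * np.sin(2 * np.pi * t)])
        labels = np.concatenate([np.zeros(len(t), int), np.ones(len(t), int)])
        out = epoch_f1_amplitudes(trace, labels, fs, f)
        assert out[0] == pytest.approx(2.0, rel=1e-6)
        assert out[1] == pytest.approx(0.5, rel=1e-6)


class TestRoiTraceSet:
    def test_overlapping_trials_rejected(self):
        with pytest.raises(InvalidSpecError):
            RoiTraceSet(np.ones((1, 10)), 10.0, trial_bounds=[(0, 6), (4, 10)])

    def test_hdf5_roundtrip(self, tmp_path, rng):
        rec = RoiTraceSet(
            rng.random((2, 20)) + 1, 10.0, trial_bounds=[(0, 10), (10, 20)],
            epoch_labels=np.zeros(20, int),
        )
        path = tmp_path / "rec.h5"
        rec.to_hdf5(path)
        back = RoiTraceSet.from_hdf5(path)
        np.testing.assert_allclose(back.traces, rec.traces)
        assert back.trial_bounds == rec.trial_bounds
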