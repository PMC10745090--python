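"""HRF, design construction, preprocessing and the nested-CV ridge engine."""

import numpy as np
import pytest

from semsyn.encoding import (BoldRun, HrfSpec, RidgeConfig, WordEventSeries,
                             delta_r, fit_encoder, make_baseline, make_design,
                             make_regressor, preprocess_bold, ridge_fit,
                             spm_hrf)

SPEC = HrfSpec()
TR = 2.0


class TestHrf:
    def test_vanishes_at_origin(self):
        assert spm_hrf(SPEC, TR)[0] == 0.0

    def test_peak_near_five_seconds(self):
        dense = HrfSpec(oversampling=200)
        h = spm_hrf(dense, TR)
        t = np.arange(h.size) * TR / dense.oversampling
        assert 4.5 <= t[np.argmax(h)] <= 5.5
        assert h.max() == pytest.approx(1.0)  # peak-normalised

    def test_undershoot_is_negative(self):
        dense = HrfSpec(oversampling=200)
        h = spm_hrf(dense, TR)
        t = np.arange(h.size) * TR / dense.oversampling
        assert h[(t > 10) & (t < 25)].min() < 0

    def test_shape_matches_nilearn_reference(self):
        """Independent implementation check against nilearn's SPM kernel
        (different normalisation, so compare shapes by correlation)."""
        from nilearn.glm.first_level import spm_hrf as nil_spm
        ours = spm_hrf(SPEC, TR)
        theirs = nil_spm(TR, oversampling=SPEC.oversampling,
                         time_length=SPEC.duration)
        n = min(ours.size, theirs.size)
        r = np.corrcoef(ours[:n], theirs[:n])[0, 1]
        assert r > 0.999


class TestRegressor:
    scan_times = np.arange(20) * TR

    def test_zero_amplitudes_give_zero_column(self):
        ev = WordEventSeries(times=np.array([1.0, 3.0]), amplitudes=np.zeros(2))
        assert np.allclose(make_regressor(ev, SPEC, self.scan_times, TR), 0.0)

    def test_linearity_in_amplitudes(self, rng):
        times = np.sort(rng.uniform(0, 30, 8))
        a, b = rng.standard_normal(8), rng.standard_normal(8)
        reg = lambda amp: make_regressor(
            WordEventSeries(times=times, amplitudes=amp), SPEC, self.scan_times, TR)
        np.testing.assert_allclose(reg(a + b), reg(a) + reg(b), atol=1e-12)

    def test_unit_event_reproduces_kernel(self):
        ev = WordEventSeries(times=np.array([0.0]), amplitudes=np.ones(1))
        col = make_regressor(ev, SPEC, self.scan_times, TR)
        kernel = spm_hrf(SPEC, TR)
        expected = np.zeros_like(col)
        idx = (self.scan_times / (TR / SPEC.oversampling)).astype(int)
        expected[idx < kernel.size] = kernel[idx[idx < kernel.size]]
        np.testing.assert_allclose(col, expected, atol=1e-9)

    def test_direct_summation_oracle(self, rng):
        """Convolution path equals the direct sum over events of shifted
        kernel values (both on the oversampled grid)."""
        dt = TR / SPEC.oversampling
        times = np.round(np.sort(rng.uniform(0, 35, 12)) / dt) * dt
        amps = rng.standard_normal(12)
        col = make_regressor(WordEventSeries(times=times, amplitudes=amps),
                             SPEC, self.scan_times, TR)
        kernel = spm_hrf(SPEC, TR)
        direct = np.zeros_like(col)
        for t_ev, a in zip(times, amps):
            lags = np.round((self.scan_times - t_ev) / dt).astype(int)
            ok = (lags >= 0) & (lags < kernel.size)
            direct[ok] += a * kernel[lags[ok]]
        assert np.max(np.abs(col - direct)) < 1e-6

    def test_event_past_the_end_warns(self):
        ev = WordEventSeries(times=np.array([500.0]), amplitudes=np.ones(1))
        with pytest.warns(UserWarning, match="after the last scan"):
            col = make_regressor(ev, SPEC, self.scan_times, TR)
        assert np.allclose(col, 0.0)


class TestBaseline:
    scan_times = np.arange(30) * TR

    def _events(self, n=10):
        times = np.linspace(1.0, 40.0, n)
        return WordEventSeries(times=times, amplitudes=np.ones(n))

    def test_constant_frequency_zeroes_modulator(self):
        ev = self._events()
        rms = (np.arange(0, 50, 0.01), np.ones(5000))
        dm = make_baseline(ev, rms, np.full(10, -3.2), SPEC, self.scan_times, TR)
        assert np.allclose(dm.matrix[:, 2], 0.0, atol=1e-12)
        assert dm.labels == ["acoustic_energy", "word_rate", "log_frequency"]

    def test_silent_audio_zeroes_energy_column(self):
        ev = self._events()
        rms = (np.arange(0, 50, 0.01), np.zeros(5000))
        dm = make_baseline(ev, rms, np.linspace(-5, -1, 10), SPEC, self.scan_times, TR)
        assert np.allclose(dm.matrix[:, 0], 0.0)

    def test_modulator_linear_in_deviations(self):
        ev = self._events()
        rms = (np.arange(0, 50, 0.01), np.ones(5000))
        f = np.linspace(-5, -1, 10)
        base = f.mean()
        dm1 = make_baseline(ev, rms, f, SPEC, self.scan_times, TR)
        dm2 = make_baseline(ev, rms, base + 2 * (f - base), SPEC, self.scan_times, TR)
        np.testing.assert_allclose(dm2.matrix[:, 2], 2 * dm1.matrix[:, 2], atol=1e-12)

    def test_missing_frequency_is_an_error(self):
        ev = self._events()
        rms = (np.arange(0, 50, 0.01), np.ones(5000))
        f = np.linspace(-5, -1, 10)
        f[3] = np.nan
        with pytest.raises(ValueError, match="token index 3"):
            make_baseline(ev, rms, f, SPEC, self.scan_times, TR)


class TestPreprocess:
    def test_linear_trend_removed(self):
        t = np.arange(40, dtype=float)
        data = np.column_stack([2 * t + 5, np.sin(t)])
        out = preprocess_bold(BoldRun(data=data))
        assert np.allclose(out.data[:, 0], 0.0, atol=1e-8)
        assert out.constant_voxels[0]

    def test_zero_mean_unit_variance(self, rng):
        data = rng.standard_normal((50, 7)) + 3.0
        out = preprocess_bold(BoldRun(data=data))
        np.testing.assert_allclose(out.data.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.data.std(axis=0), 1.0, atol=1e-12)

    def test_constant_voxel_flagged_and_zeroed(self):
        data = np.column_stack([np.full(10, 7.0), np.arange(10, dtype=float) ** 2])
        out = preprocess_bold(BoldRun(data=data))
        assert out.constant_voxels[0] and not out.constant_voxels[1]
        assert np.allclose(out.data[:, 0], 0.0)


def _simulated_runs(rng, n_runs=4, n_scans=40, n_feat=5, n_vox=6, noise=0.0):
    Xs = [rng.standard_normal((n_scans, n_feat)) for _ in range(n_runs)]
    W = rng.standard_normal((n_feat, n_vox))
    Ys = [X @ W + noise * rng.standard_normal((n_scans, n_vox)) for X in Xs]
    return Xs, Ys, W


class TestFitEncoder:
    def test_noiseless_recovery(self, rng):
        Xs, Ys, _ = _simulated_runs(rng)
        res = fit_encoder(Xs, Ys, RidgeConfig(standardize=False))
        assert np.all(res.r_cv >= 0.99)

    def test_fixed_alpha_matches_closed_form(self, rng):
        """SVD path vs direct solve of the penalised normal equations and
        scikit-learn's Ridge."""
        from sklearn.linear_model import Ridge
        X = rng.standard_normal((50, 8))
        Y = rng.standard_normal((50, 3))
        for alpha in (0.01, 1.0, 100.0):
            W = ridge_fit(X, Y, alpha)
            direct = np.linalg.solve(X.T @ X + alpha * np.eye(8), X.T @ Y)
            assert np.max(np.abs(W - direct)) < 1e-8
            sk = Ridge(alpha=alpha, fit_intercept=False).fit(X, Y)
            assert np.max(np.abs(W - sk.coef_.T)) < 1e-8

    def test_r_bounded(self, rng):
        Xs, Ys, _ = _simulated_runs(rng, noise=5.0)
        res = fit_encoder(Xs, Ys)
        assert np.all(res.r_cv <= 1.0) and np.all(res.r_cv >= -1.0)
        assert res.per_fold.shape == (4, 6)

    def test_fold_hygiene_with_leak_detector(self, rng):
        """A column informative only in the held-out run must earn ~zero
        weight: training never sees the held-out data."""
        n_runs, n_scans, n_vox = 4, 200, 10
        Ys = [rng.standard_normal((n_scans, n_vox)) for _ in range(n_runs)]
        Xs = [rng.standard_normal((n_scans, 4)) for _ in range(n_runs)]
        Xs[0][:, 3] = Ys[0][:, 0]  # perfect predictor of voxel 0, run 0 only
        res = fit_encoder(Xs, Ys, RidgeConfig(standardize=False))
        # the fold holding out run 0 fits on runs 1-3 where the column is pure
        # noise; had any run-0 data influenced alpha selection or fitting, the
        # held-out correlation for voxel 0 would approach 1
        assert abs(res.per_fold[0, 0]) < 0.5
        assert np.mean(np.abs(res.per_fold)) < 0.15

    def test_scale_invariance_with_matched_alpha_grid(self, rng):
        Xs, Ys, _ = _simulated_runs(rng, noise=1.0)
        c = 7.0
        alphas = np.logspace(-2, 2, 5)
        r1 = fit_encoder(Xs, Ys, RidgeConfig(alphas=alphas, standardize=False))
        r2 = fit_encoder([c * X for X in Xs], Ys,
                         RidgeConfig(alphas=c * c * alphas, standardize=False))
        np.testing.assert_allclose(r1.r_cv, r2.r_cv, atol=1e-10)

    def test_preconditions(self, rng):
        Xs, Ys, _ = _simulated_runs(rng, n_runs=2)
        with pytest.raises(ValueError, match="at least 3 runs"):
            fit_encoder(Xs, Ys)
        Xs, Ys, _ = _simulated_runs(rng)
        with pytest.raises(ValueError, match="all zero"):
            fit_encoder([np.zeros_like(X) for X in Xs], Ys)


class TestDeltaR:
    def test_baseline_vs_itself_is_exactly_zero(self, rng):
        Xs, Ys, _ = _simulated_runs(rng, noise=1.0)
        res = fit_encoder(Xs, Ys)
        assert np.all(delta_r(res, res) == 0.0)

    def test_fold_mismatch_rejected(self, rng):
        Xs, Ys, _ = _simulated_runs(rng, noise=1.0)
        a = fit_encoder(Xs, Ys)
        b = fit_encoder(Xs[:3], Ys[:3])
        with pytest.raises(ValueError, match="mismatch"):
            delta_r(a, b)
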