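"""FFT denoising, blank subtraction, window integration and feature
assembly."""

import numpy as np
import pytest

import voltpls as vp


def _sweep(currents, grid=None):
    grid = grid or vp.GridSpec()
    return vp.Voltammogram(grid.potentials(), currents)


class TestFftDenoise:
    def test_passband_sinusoid_unchanged(self):
        n = vp.GridSpec().n_points
        currents = np.sin(2 * np.pi * 5 * np.arange(n) / n)
        v = _sweep(currents)
        out = vp.fft_denoise(v, vp.FilterSpec(cutoff_fraction=0.1))
        np.testing.assert_allclose(out.currents, currents, atol=1e-9)

    def test_white_noise_power_reduced(self):
        rng = np.random.default_rng(0)
        v = _sweep(rng.normal(size=vp.GridSpec().n_points))
        out = vp.fft_denoise(v, vp.FilterSpec(cutoff_fraction=0.1))
        assert out.currents.var() < v.currents.var()

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        v = _sweep(rng.normal(size=vp.GridSpec().n_points))
        once = vp.fft_denoise(v)
        twice = vp.fft_denoise(once)
        np.testing.assert_allclose(twice.currents, once.currents, atol=1e-9)

    def test_linearity(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=vp.GridSpec().n_points)
        y = rng.normal(size=vp.GridSpec().n_points)
        a, b = 2.5, -1.3
        lhs = vp.fft_denoise(_sweep(a * x + b * y)).currents
        rhs = a * vp.fft_denoise(_sweep(x)).currents + b * vp.fft_denoise(_sweep(y)).currents
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_energy_never_increases(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=vp.GridSpec().n_points)
        out = vp.fft_denoise(_sweep(x), vp.FilterSpec(cutoff_fraction=0.3))
        assert np.sum(out.currents**2) <= np.sum(x**2) + 1e-9

    def test_full_band_is_identity(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=vp.GridSpec().n_points)
        out = vp.fft_denoise(_sweep(x), vp.FilterSpec(cutoff_fraction=1.0))
        np.testing.assert_allclose(out.currents, x, atol=1e-9)

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValueError):
            vp.FilterSpec(cutoff_fraction=0.0)


class TestSubtractBlank:
    def test_self_subtraction_is_zero(self, modified_profile, quiet_noise):
        v = vp.generate_voltammogram({"MET": 5.0}, modified_profile, noise=quiet_noise)
        out = vp.subtract_blank(v, v)
        np.testing.assert_array_equal(out.currents, 0.0)

    def test_noiseless_subtraction_leaves_peak_sum(
        self, modified_profile, quiet_noise, conditions, grid
    ):
        conc = {"MOR": 2.0, "MET": 4.0, "UA": 6.0}
        v = vp.generate_voltammogram(conc, modified_profile, conditions, quiet_noise)
        blank = vp.generate_voltammogram({}, modified_profile, conditions, quiet_noise)
        pure = vp.peak_signal(conc, modified_profile, conditions, grid.potentials())
        np.testing.assert_allclose(
            vp.subtract_blank(v, blank).currents, pure, atol=1e-12
        )

    def test_grid_length_mismatch_rejected(self):
        a = _sweep(np.zeros(vp.GridSpec().n_points))
        b = vp.Voltammogram(np.linspace(0, 1.1, 100), np.zeros(100))
        with pytest.raises(ValueError, match="mismatch"):
            vp.subtract_blank(a, b)

    def test_commutes_with_filtering(self, modified_profile):
        noise = vp.NoiseModel(white_sd=0.3, seed=5)
        v = vp.generate_voltammogram({"MET": 5.0}, modified_profile, noise=noise)
        blank = vp.generate_voltammogram(
            {}, modified_profile, noise=vp.NoiseModel(white_sd=0.3, seed=6)
        )
        spec = vp.FilterSpec()
        a = vp.fft_denoise(vp.subtract_blank(v, blank), spec).currents
        b = vp.subtract_blank(
            vp.fft_denoise(v, spec), vp.fft_denoise(blank, spec)
        ).currents
        np.testing.assert_allclose(a, b, atol=1e-9)


class TestIntegrateResponse:
    def test_zero_signal(self):
        v = _sweep(np.zeros(vp.GridSpec().n_points))
        assert vp.integrate_response(v, vp.ResponseWindow(0.2, 0.8)) == 0.0

    def test_unit_rectangle(self):
        grid = vp.GridSpec()
        pot = grid.potentials()
        currents = np.where((pot >= 0.2) & (pot <= 0.4), 1.0, 0.0)
        v = _sweep(currents)
        got = vp.integrate_response(v, vp.ResponseWindow(0.25, 0.35))
        assert got == pytest.approx(0.1, abs=1e-12)

    def test_gaussian_closed_form(self):
        grid = vp.GridSpec()
        h, w = 7.0, 0.03
        v = _sweep(h * np.exp(-((grid.potentials() - 0.5) ** 2) / (2 * w**2)))
        got = vp.integrate_response(v, vp.ResponseWindow(0.2, 0.8))
        assert got == pytest.approx(h * w * np.sqrt(2 * np.pi), rel=1e-3)

    def test_window_outside_grid_rejected(self):
        v = _sweep(np.zeros(vp.GridSpec().n_points))
        with pytest.raises(ValueError, match="outside"):
            vp.integrate_response(v, vp.ResponseWindow(0.5, 1.5))

    def test_inverted_window_rejected(self):
        with pytest.raises(ValueError):
            vp.ResponseWindow(0.8, 0.2)


class TestBuildFeatureMatrix:
    def _scans(self, profile, n=5, white_sd=0.0):
        design = vp.generate_design(n, 1, profile, seed=3)
        scans, blank = vp.simulate_design_scans(
            design, profile, vp.ConditionSet(),
            vp.NoiseModel(white_sd=white_sd, drift_amplitude=2.0),
            vp.GridSpec(), seed=4,
        )
        return scans, blank

    def test_full_profile_shape(self, modified_profile):
        scans, blank = self._scans(modified_profile, n=16)
        fm = vp.build_feature_matrix(scans, vp.FilterSpec(), blank)
        assert fm.values.shape == (17, vp.GridSpec().n_points)
        assert fm.sample_ids[0] == "train01"

    def test_all_blank_rows_are_zero(self, modified_profile, quiet_noise):
        blank = vp.generate_voltammogram({}, modified_profile, noise=quiet_noise)
        scans = [
            vp.generate_voltammogram({}, modified_profile, noise=quiet_noise)
            for _ in range(3)
        ]
        fm = vp.build_feature_matrix(scans, vp.FilterSpec(), blank)
        np.testing.assert_allclose(fm.values, 0.0, atol=1e-9)

    def test_peak_window_mode_columns(self, modified_profile):
        scans, blank = self._scans(modified_profile)
        windows = [
            vp.ResponseWindow(c - 0.09, c + 0.09) for c in (0.34, 0.39, 0.73, 0.81)
        ]
        fm = vp.build_feature_matrix(
            scans, vp.FilterSpec(), blank, mode="peak_windows", windows=windows
        )
        assert fm.values.shape == (len(scans), 4)

    def test_mixed_grids_rejected(self, modified_profile):
        scans, _ = self._scans(modified_profile)
        other = vp.Voltammogram(np.linspace(0, 1.0, 100), np.zeros(100))
        with pytest.raises(ValueError, match="mismatch"):
            vp.build_feature_matrix(scans + [other])

    def test_rows_match_pure_peak_sum_without_white_noise(
        self, modified_profile, conditions, grid
    ):
        scans, blank = self._scans(modified_profile, n=4)
        fm = vp.build_feature_matrix(scans, vp.FilterSpec(), blank)
        for row, scan in zip(fm.values, scans):
            pure = vp.peak_signal(
                scan.meta["conc_uM"], modified_profile, conditions, grid.potentials()
            )
            rms_err = np.sqrt(np.mean((row - pure) ** 2))
            assert rms_err < 0.01 * np.sqrt(np.mean(pure**2))
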