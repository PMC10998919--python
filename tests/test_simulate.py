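"""Synthetic voltammetry: profile fidelity, condition response, signal
synthesis and mixture designs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import voltpls as vp


class TestPaperProfile:
    @pytest.mark.parametrize(
        "analyte, peak_idx, center, slope, intercept",
        [
            ("MOR", 0, 0.39, 0.7839, 0.6571),
            ("MOR", 1, 0.81, 1.4612, 1.6195),
            ("MET", 0, 0.73, 2.1876, 2.084),
            ("UA", 0, 0.34, 1.3644, -0.097),
        ],
    )
    def test_modified_sensor_calibration_lines(
        self, modified_profile, analyte, peak_idx, center, slope, intercept
    ):
        peak = modified_profile.analyte(analyte).peaks[peak_idx]
        assert peak.center_potential == center
        assert peak.sensitivity_m == slope
        assert peak.offset_b == intercept

    @pytest.mark.parametrize(
        "analyte, centers",
        [("MOR", {0.42, 0.83}), ("MET", {0.79}), ("UA", {0.33})],
    )
    def test_unmodified_sensor_peak_potentials(
        self, unmodified_profile, analyte, centers
    ):
        got = {p.center_potential for p in unmodified_profile.analyte(analyte).peaks}
        assert got == centers

    @pytest.mark.parametrize(
        "analyte, low, high", [("MOR", 1.5, 15), ("MET", 1, 15), ("UA", 1, 20)]
    )
    def test_linear_ranges(self, modified_profile, analyte, low, high):
        assert modified_profile.analyte(analyte).linear_range == (low, high)

    def test_unknown_label_lists_valid_labels(self):
        with pytest.raises(ValueError, match="modified"):
            vp.paper_profile("bare")

    def test_peak_count_invariant(self):
        with pytest.raises(ValueError, match="2 peak"):
            vp.AnalyteDef("MOR", (vp.PeakSpec(0.39, 1.0),), (1, 15))


class TestConditionMultiplier:
    @pytest.mark.parametrize(
        "analyte, peak_idx", [("MOR", 0), ("MOR", 1), ("MET", 0), ("UA", 0)]
    )
    def test_optimum_gives_unity(self, conditions, analyte, peak_idx):
        assert vp.condition_multiplier(conditions, analyte, peak_idx) == 1.0

    def test_met_silent_below_ph6(self):
        assert vp.condition_multiplier(vp.ConditionSet(ph=5.0), "MET") == 0.0

    def test_ua_stable_beyond_90s(self):
        m120 = vp.condition_multiplier(vp.ConditionSet(accumulation_time=120), "UA")
        m150 = vp.condition_multiplier(vp.ConditionSet(accumulation_time=150), "UA")
        assert m120 == m150 == 1.0

    @pytest.mark.parametrize(
        "conds",
        [
            vp.ConditionSet(ph=6.5),
            vp.ConditionSet(frequency=100.0),
            vp.ConditionSet(frequency=500.0),
            vp.ConditionSet(amplitude=8.0),
            vp.ConditionSet(amplitude=29.0),
            vp.ConditionSet(accumulation_time=60.0),
            vp.ConditionSet(ph=10.0),
        ],
    )
    def test_off_optimum_attenuates(self, conds):
        m = vp.condition_multiplier(conds, "MET")
        assert 0.0 <= m < 1.0

    def test_monotone_decay_above_frequency_plateau(self):
        freqs = [256, 300, 400, 500, 564]
        mults = [
            vp.condition_multiplier(vp.ConditionSet(frequency=f), "MET")
            for f in freqs
        ]
        assert all(a >= b for a, b in zip(mults, mults[1:]))


class TestGenerateVoltammogram:
    def test_blank_equals_background(self, modified_profile, quiet_noise, grid):
        v = vp.generate_voltammogram(
            {"MOR": 0, "MET": 0, "UA": 0}, modified_profile, noise=quiet_noise
        )
        expected = vp.background_current(grid.potentials(), quiet_noise)
        np.testing.assert_allclose(v.currents, expected, atol=0)

    def test_met_peak_height_matches_calibration_line(
        self, modified_profile, quiet_noise
    ):
        v = vp.generate_voltammogram({"MET": 5.0}, modified_profile, noise=quiet_noise)
        blank = vp.generate_voltammogram({}, modified_profile, noise=quiet_noise)
        height = vp.peak_height(vp.subtract_blank(v, blank), 0.73)
        assert height == pytest.approx(2.1876 * 5 + 2.084, abs=1e-9)

    def test_mixture_is_sum_of_single_analyte_scans(
        self, modified_profile, quiet_noise, grid
    ):
        mix = vp.generate_voltammogram(
            {"MOR": 3.0, "MET": 5.0, "UA": 8.0}, modified_profile, noise=quiet_noise
        )
        singles = [
            vp.generate_voltammogram({a: c}, modified_profile, noise=quiet_noise)
            for a, c in [("MOR", 3.0), ("MET", 5.0), ("UA", 8.0)]
        ]
        background = vp.background_current(grid.potentials(), quiet_noise)
        summed = sum(s.currents for s in singles) - 2 * background
        np.testing.assert_allclose(mix.currents, summed, atol=1e-12)

    def test_negative_concentration_rejected(self, modified_profile):
        with pytest.raises(ValueError, match="negative"):
            vp.generate_voltammogram({"MET": -1.0}, modified_profile)

    def test_same_seed_same_noise(self, modified_profile):
        noise = vp.NoiseModel(white_sd=0.3, seed=11)
        a = vp.generate_voltammogram({"MET": 5.0}, modified_profile, noise=noise)
        b = vp.generate_voltammogram({"MET": 5.0}, modified_profile, noise=noise)
        np.testing.assert_array_equal(a.currents, b.currents)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(c=st.floats(0.5, 20.0))
    def test_peak_height_affine_in_concentration(self, c):
        profile = vp.paper_profile("modified")
        noise = vp.NoiseModel(white_sd=0.0)
        conds = vp.ConditionSet(frequency=300.0)  # off the MET plateau
        mult = vp.condition_multiplier(conds, "MET")
        v = vp.generate_voltammogram({"MET": c}, profile, conds, noise)
        blank = vp.generate_voltammogram({}, profile, conds, noise)
        height = vp.peak_height(vp.subtract_blank(v, blank), 0.73)
        assert height == pytest.approx((2.1876 * c + 2.084) * mult, abs=1e-9)

    def test_nonuniform_grid_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            vp.Voltammogram(np.array([0.0, 0.1, 0.3]), np.zeros(3))


class TestGenerateDesign:
    def test_counts_and_roles(self, modified_profile):
        design = vp.generate_design(17, 12, modified_profile, seed=0)
        assert len(design.train) == 17
        assert len(design.test) == 12
        assert not set(design.train["sample_id"]) & set(design.test["sample_id"])

    @pytest.mark.parametrize("method", ["uniform", "lhs"])
    def test_concentrations_within_linear_ranges(self, modified_profile, method):
        design = vp.generate_design(17, 12, modified_profile, seed=5, method=method)
        conc = design.concentrations()
        for j, analyte in enumerate(vp.ANALYTES):
            low, high = modified_profile.analyte(analyte).linear_range
            assert conc[:, j].min() >= low
            assert conc[:, j].max() <= high

    def test_seed_reproducibility(self, modified_profile):
        a = vp.generate_design(10, 5, modified_profile, seed=9)
        b = vp.generate_design(10, 5, modified_profile, seed=9)
        assert a.table.equals(b.table)

    def test_unknown_method_rejected(self, modified_profile):
        with pytest.raises(ValueError, match="method"):
            vp.generate_design(5, 5, modified_profile, seed=0, method="sobol")
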