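"""Tests of dose conversion, dose-difference summaries and gamma analysis."""

import numpy as np
import pytest

from epidose import invert_quadratic
from epidose.analysis import (
    DoseImage,
    dose_diff_summary,
    gamma_2d,
    profile_1d,
    thickness_to_intensity,
)


def _dose(arr, pitch=0.1):
    arr = np.asarray(arr, dtype=float)
    return DoseImage(dose=arr, alpha_conv=0.05, beta_conv=1e-4,
                     valid_mask=np.ones(arr.shape, bool), pixel_pitch=pitch)


class TestThicknessToIntensity:
    def test_zero_thickness_gives_i0(self):
        d = thickness_to_intensity(np.zeros((4, 4)))
        np.testing.assert_allclose(d.dose, 1.0)

    def test_ten_cm_value(self):
        d = thickness_to_intensity(np.full((2, 2), 10.0))
        np.testing.assert_allclose(d.dose, np.exp(-0.51))

    def test_inverse_pair_with_invert_quadratic(self):
        t = np.linspace(0.0, 21.0, 64)
        dose = thickness_to_intensity(t.reshape(8, 8)).dose
        t_back, valid = invert_quadratic(dose, 1.0, 0.05, 1e-4)
        assert valid.all()
        np.testing.assert_allclose(t_back.ravel(), t, atol=1e-9)


class TestDoseDiffSummary:
    def test_identical_images_all_within(self):
        ref = _dose(np.full((6, 6), 0.7))
        s = dose_diff_summary(ref, ref, np.ones((6, 6), bool))
        assert s.pct_within == (100.0, 100.0, 100.0, 100.0)

    def test_counting_example(self):
        ref = _dose(np.ones((2, 2)))
        ev = _dose(np.array([[1.005, 1.015], [1.025, 1.06]]))
        s = dose_diff_summary(ev, ref, np.ones((2, 2), bool))
        assert s.pct_within == (75.0, 75.0, 50.0, 25.0)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        ref = _dose(np.ones((16, 16)))
        ev = _dose(1.0 + rng.normal(0, 0.03, (16, 16)))
        s = dose_diff_summary(ev, ref, np.ones((16, 16), bool))
        assert all(a >= b for a, b in zip(s.pct_within, s.pct_within[1:]))

    def test_empty_roi_rejected(self):
        ref = _dose(np.ones((4, 4)))
        with pytest.raises(ValueError, match="empty ROI"):
            dose_diff_summary(ref, ref, np.zeros((4, 4), bool))


class TestGamma2d:
    def test_identical_images_gamma_zero(self):
        ref = _dose(np.ones((12, 12)) * 0.8)
        roi = np.zeros((12, 12), bool)
        roi[3:9, 3:9] = True
        gm = gamma_2d(ref, ref, roi, 2.0, 2.0)
        assert np.nanmax(gm.gamma) == 0.0
        assert gm.pass_rate == 100.0

    def test_uniform_offset_at_criterion(self):
        """A flat 3% offset sits exactly at the 3% local criterion."""
        ref = _dose(np.ones((16, 16)))
        ev = _dose(np.full((16, 16), 1.03))
        roi = np.zeros((16, 16), bool)
        roi[4:12, 4:12] = True
        gm = gamma_2d(ev, ref, roi, 3.0, 3.0)
        np.testing.assert_allclose(gm.gamma[roi], 1.0, atol=1e-9)

    def test_undersampled_search_rejected(self):
        ref = _dose(np.ones((8, 8)))
        with pytest.raises(ValueError, match="undersampled"):
            gamma_2d(ref, ref, np.ones((8, 8), bool), 3.0, 0.5,
                     pixel_pitch_cm=0.1, interp_factor=1)

    def test_shifted_edge_passes_at_matching_distance_criterion(self):
        ny, nx = 24, 24
        a = np.where(np.arange(nx)[None, :] < 12, 1.0, 0.7) * np.ones((ny, 1))
        b = np.where(np.arange(nx)[None, :] < 14, 1.0, 0.7) * np.ones((ny, 1))
        roi = np.zeros((ny, nx), bool)
        roi[6:18, 6:18] = True
        g33 = gamma_2d(_dose(b), _dose(a), roi, 3.0, 3.0)
        g11 = gamma_2d(_dose(b), _dose(a), roi, 1.0, 1.0)
        assert g33.pass_rate == 100.0  # 2 mm shift within 3 mm DTA
        assert g11.pass_rate < 100.0  # but beyond 1 mm DTA at the edge

    def test_pass_rate_monotone_in_criteria(self):
        rng = np.random.default_rng(9)
        ref = _dose(1.0 + 0.1 * np.cos(np.linspace(0, 3, 24))[None, :]
                    * np.ones((24, 1)))
        ev = _dose(ref.dose * (1.0 + rng.normal(0, 0.02, (24, 24))))
        roi = np.zeros((24, 24), bool)
        roi[4:20, 4:20] = True
        rates = [gamma_2d(ev, ref, roi, c, c).pass_rate
                 for c in (5.0, 3.0, 2.0, 1.0)]
        assert all(a >= b for a, b in zip(rates, rates[1:]))

    def test_gamma_pass_not_below_dose_only_pass(self):
        rng = np.random.default_rng(4)
        ref = _dose(np.ones((20, 20)))
        ev = _dose(1.0 + rng.normal(0, 0.025, (20, 20)))
        roi = np.ones((20, 20), bool)
        gm = gamma_2d(ev, ref, roi, 2.0, 2.0)
        dd = dose_diff_summary(ev, ref, roi, thresholds=(2.0,))
        assert gm.pass_rate >= dd.pct_within[0]


class TestProfile1d:
    def test_constant_map_constant_profile(self):
        pos, vals = profile_1d(np.full((8, 8), 3.0), row=4)
        np.testing.assert_allclose(vals, 3.0)
        assert pos.shape == vals.shape

    def test_breast_phantom_profile_peaks_at_apex(self, breast_recon_small):
        _, _, tmap, _, spec = breast_recon_small
        row = spec.pixels_y // 2
        pos, vals = profile_1d(tmap, row=row)
        apex_col = np.argmin(np.abs(pos))  # dome centred at x = 0
        assert abs(int(np.argmax(vals)) - apex_col) <= 1

    def test_repeated_noiseless_reconstructions_identical_profiles(
            self, breast_recon_small, calibrator_small, calib_series_small,
            forward):
        from epidose import dark_correct, reconstruct
        from epidose import simulate as sim

        phantom, beam, tmap, _, spec = breast_recon_small
        trace = sim.make_static_trace(30.0)

        def rerun():
            img = dark_correct(
                sim.acquire(phantom, beam, trace, forward, spec,
                            start_offset=0.0),
                calib_series_small.dark)
            return reconstruct(img, calibrator_small,
                               area_treat=beam.field_area).t

        _, v1 = profile_1d(rerun(), row=32, pixel_pitch=spec.pixel_pitch)
        _, v2 = profile_1d(rerun(), row=32, pixel_pitch=spec.pixel_pitch)
        np.testing.assert_array_equal(v1 - v2, 0.0)

    def test_oblique_line_and_bounds(self):
        arr = np.arange(64, dtype=float).reshape(8, 8)
        pos, vals = profile_1d(arr, line=((0, 0), (7, 7)), pixel_pitch=0.1)
        assert vals[0] == 0.0 and vals[-1] == 63.0
        with pytest.raises(ValueError):
            profile_1d(arr, line=((0, 0), (9, 2)), pixel_pitch=0.1)

    def test_requires_exactly_one_selector(self):
        arr = np.zeros((4, 4))
        with pytest.raises(ValueError):
            profile_1d(arr)
        with pytest.raises(ValueError):
            profile_1d(arr, row=1, line=((0, 0), (1, 1)))


class TestMotionBlurBand:
    def test_moving_edges_blurred_over_peak_to_peak_band(self, calibrator_small,
                                                         calib_series_small,
                                                         small_spec, forward):
        """A 1.5 cm sinusoid smears the dome edges over a ~3 cm band."""
        from epidose import dark_correct, reconstruct
        from epidose import simulate as sim

        ph = sim.make_breast_phantom(
            12.0, outline_params={"dome_rx": 1.5, "dome_ry": 1.2,
                                  "ramp_height": 0.0})
        beam = sim.treatment_beam(6.0, 4.0, wedge_min=1.0)
        tr_static = sim.make_static_trace(30.0)
        tr_mov = sim.make_sinusoid_trace(1.5, 12.0, duration=30.0)

        def tmap_for(trace):
            img = dark_correct(
                sim.acquire(ph, beam, trace, forward, small_spec,
                            start_offset=0.0),
                calib_series_small.dark)
            return reconstruct(img, calibrator_small,
                               area_treat=beam.field_area).t

        t_s = tmap_for(tr_static)
        t_m = tmap_for(tr_mov)
        diff = np.abs(t_m - t_s)[32]  # mid row through the dome
        band_cols = np.flatnonzero(diff > 0.25)
        band_width_cm = (band_cols.max() - band_cols.min() + 1) \
            * small_spec.pixel_pitch
        # edge blur extends over roughly the dome width + peak-to-peak motion
        assert 2.0 <= band_width_cm <= 7.0
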