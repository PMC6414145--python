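"""Tests of the synthetic phantom, motion traces and image formation."""

import numpy as np
import pytest
from scipy.signal import find_peaks

from epidose import simulate as sim


class TestBreastPhantom:
    def test_apex_thickness_equals_separation(self):
        ph = sim.make_breast_phantom(16.0)
        assert ph.thickness(0.0, 0.0) == pytest.approx(16.0)

    def test_zero_outside_body_extent(self):
        ph = sim.make_breast_phantom(16.0)
        xmin, xmax, ymin, ymax = ph.body_extent
        pts = [(xmin - 1.0, 0.0), (xmax + 1.0, 0.0), (0.0, ymax + 1.0)]
        for x, y in pts:
            assert ph.thickness(x, y) == 0.0

    def test_range_and_continuity_on_dense_grid(self):
        ph = sim.make_breast_phantom(16.0)
        spec = sim.AcquisitionSpec(noise_scale=0.0)
        x, y = sim.grid_coords(spec)
        X, Y = np.meshgrid(x, y)
        t = ph.thickness(X, Y)
        assert t.min() >= 0.0
        assert t.max() <= 16.0 + 1e-12
        assert np.abs(np.diff(t, axis=0)).max() < 0.5
        assert np.abs(np.diff(t, axis=1)).max() < 0.5

    def test_outline_inside_body_extent(self):
        ph = sim.make_breast_phantom(10.0)
        xmin, xmax, ymin, ymax = ph.body_extent
        ox, oy = ph.breast_outline[:, 0], ph.breast_outline[:, 1]
        assert ox.min() >= xmin and ox.max() <= xmax
        assert oy.min() >= ymin and oy.max() <= ymax

    @pytest.mark.parametrize("bad", [0.0, -1.0, 21.5])
    def test_separation_outside_calibrated_range_rejected(self, bad):
        with pytest.raises(ValueError):
            sim.make_breast_phantom(bad)


class TestSinusoidTrace:
    def test_closed_form_displacement(self):
        tr = sim.make_sinusoid_trace(1.0, 12.0, duration=25.8, dt=0.001)
        # 12 cpm over 25.8 s is 5.16 cycles; peak displacement is the amplitude
        assert 12.0 / 60.0 * 25.8 == pytest.approx(5.16)
        assert np.max(np.abs(tr.displacement)) == pytest.approx(1.0, abs=1e-4)
        expect = 1.0 * np.sin(2 * np.pi * 12.0 / 60.0 * tr.times)
        np.testing.assert_allclose(tr.displacement, expect, atol=1e-12)

    def test_period_of_agility_setting(self):
        # 18 cycles/min -> 3.333 s period, visible as the peak spacing
        tr = sim.make_sinusoid_trace(1.5, 18.0, duration=30.0, dt=0.001)
        peaks, _ = find_peaks(tr.displacement)
        assert np.diff(tr.times[peaks]).mean() == pytest.approx(60.0 / 18.0,
                                                                rel=1e-3)

    def test_zero_amplitude_is_static(self):
        tr = sim.make_sinusoid_trace(0.0, 12.0, duration=10.0)
        assert tr.kind == "static"
        assert np.all(tr.displacement == 0.0)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            sim.make_sinusoid_trace(1.0, 12.0, duration=0.0)


class TestPatientTrace:
    def test_seeded_determinism(self):
        a = sim.make_patient_trace(duration=40.0, seed=3)
        b = sim.make_patient_trace(duration=40.0, seed=3)
        np.testing.assert_array_equal(a.displacement, b.displacement)
        c = sim.make_patient_trace(duration=40.0, seed=4)
        assert not np.array_equal(a.displacement, c.displacement)

    def test_degenerate_limit_is_periodic(self):
        tr = sim.make_patient_trace(mean_period=4.0, period_cv=0.0,
                                    mean_amplitude=1.0, amplitude_cv=0.0,
                                    baseline_drift=0.0, duration=20.0, dt=0.01)
        one_period = int(round(4.0 / 0.01))
        d = tr.displacement
        np.testing.assert_allclose(d[:-one_period], d[one_period:], atol=1e-9)

    def test_mean_cycle_period_matches_parameter(self):
        tr = sim.make_patient_trace(mean_period=4.0, duration=400.0, seed=1)
        peaks, _ = find_peaks(tr.displacement, height=0.3, distance=100)
        mean_period = np.diff(tr.times[peaks]).mean()
        assert mean_period == pytest.approx(4.0, rel=0.05)

    def test_baseline_drift_superposed(self):
        tr = sim.make_patient_trace(baseline_drift=0.6, duration=120.0, seed=2)
        half = len(tr.times) // 2
        # 0.6 cm/min drift shifts the second-minute baseline up by ~0.6 cm
        assert tr.displacement[half:].mean() - tr.displacement[:half].mean() \
            == pytest.approx(0.6, abs=0.15)


class TestRenderAndAcquire:
    def test_open_field_is_i0_times_fluence(self, small_spec, forward_clean):
        beam = sim.treatment_beam(5.0, 4.0, wedge_min=0.5)
        img = sim.render_transit_image(None, beam, 0.0, forward_clean, small_spec)
        x, y = sim.grid_coords(small_spec)
        X, Y = np.meshgrid(x, y)
        np.testing.assert_allclose(img, forward_clean.i0 * beam.fluence(X, Y))

    def test_uniform_slab_attenuation_ratio(self, small_spec, forward_clean):
        beam = sim.calibration_beam()
        slab = sim.make_uniform_slab(10.0)
        img = sim.render_transit_image(slab, beam, 0.0, forward_clean, small_spec)
        open_f = sim.render_transit_image(None, beam, 0.0, forward_clean,
                                          small_spec)
        ratio = img[32, 32] / open_f[32, 32]
        assert ratio == pytest.approx(np.exp(-0.51), rel=1e-12)

    def test_displacement_translates_phantom_only(self, small_spec, forward):
        ph = sim.make_breast_phantom(
            12.0, outline_params={"dome_rx": 1.5, "dome_ry": 1.2,
                                  "ramp_height": 0.0})
        beam = sim.treatment_beam(5.0, 4.0, wedge_min=1.0)
        a = sim.render_transit_image(ph, beam, 0.0, forward, small_spec)
        b = sim.render_transit_image(ph, beam, 1.0, forward, small_spec)
        shift = int(round(1.0 / small_spec.pixel_pitch))
        # inside the aperture the image content shifts by exactly 10 px
        interior = a[20:44, 18:38]
        np.testing.assert_allclose(b[20:44, 18 + shift:38 + shift], interior,
                                   rtol=1e-12)

    def test_static_noiseless_acquire_is_single_render(self, small_spec, forward):
        ph = sim.make_uniform_slab(5.0)
        beam = sim.calibration_beam()
        tr = sim.make_static_trace(30.0)
        img = sim.acquire(ph, beam, tr, forward, small_spec, start_offset=0.0)
        single = sim.render_transit_image(ph, beam, 0.0, forward, small_spec)
        np.testing.assert_allclose(img.pixels, small_spec.dark_level + single)
        assert not img.is_dark_corrected

    def test_zero_amplitude_bitwise_identical_to_static(self, forward):
        spec = sim.AcquisitionSpec(pixels_x=32, pixels_y=32, noise_scale=0.005,
                                   seed=11)
        ph = sim.make_uniform_slab(5.0)
        beam = sim.calibration_beam()
        st = sim.make_static_trace(30.0)
        s0 = sim.make_sinusoid_trace(0.0, 12.0, duration=30.0)
        a = sim.acquire(ph, beam, st, forward, spec, start_offset=0.0)
        b = sim.acquire(ph, beam, s0, forward, spec, start_offset=0.0)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_short_trace_rejected(self, small_spec, forward):
        tr = sim.make_static_trace(5.0)  # delivery needs 25.8 s
        with pytest.raises(ValueError):
            sim.acquire(None, sim.calibration_beam(), tr, forward, small_spec,
                        start_offset=0.0)

    def test_integer_cycle_average_recovers_static_thickness(self):
        # linear-in-x thickness: averaging over whole motion cycles leaves
        # the frame-mean displacement (hence mean thickness) unchanged
        spec = sim.AcquisitionSpec(noise_scale=0.0)
        k_cycles = 5
        freq = 60.0 * k_cycles / spec.delivery_time
        tr = sim.make_sinusoid_trace(1.0, freq, duration=30.0, dt=0.001)
        mids = (np.arange(spec.n_frames) + 0.5) * spec.frame_time
        disps = tr.displacement_at(mids)
        assert disps.mean() == pytest.approx(0.0, abs=1e-12)

    def test_extrapolation_flagged_beyond_calibrated_range(self, small_spec,
                                                           forward):
        slab = sim.make_uniform_slab(22.0)
        tr = sim.make_static_trace(30.0)
        with pytest.warns(RuntimeWarning, match="extrapolation"):
            img = sim.acquire(slab, sim.calibration_beam(), tr, forward,
                              small_spec, start_offset=0.0)
        assert img.meta["extrapolated_thickness"]

    def test_frame_average_converges_to_dense_quadrature(self, forward):
        spec = sim.AcquisitionSpec(pixels_x=48, pixels_y=48, noise_scale=0.0)
        ph = sim.make_breast_phantom(
            12.0, outline_params={"dome_rx": 1.5, "dome_ry": 1.2,
                                  "ramp_height": 0.0})
        beam = sim.treatment_beam(4.0, 3.0, wedge_min=1.0)
        tr = sim.make_sinusoid_trace(1.0, 13.7, duration=30.0, dt=0.001)
        coarse = sim.acquire(ph, beam, tr, forward, spec, start_offset=0.0)
        from dataclasses import replace
        dense_spec = replace(spec, n_frames=6000, frame_time=spec.delivery_time / 6000)
        dense = sim.acquire(ph, beam, tr, forward, dense_spec, start_offset=0.0)
        open_level = forward.i0
        diff = np.abs(coarse.pixels - dense.pixels).max()
        assert diff < 0.002 * open_level


class TestCalibrationSeries:
    def test_default_series_has_seven_images_plus_dark(self, calib_series_small):
        assert len(calib_series_small.images) == 7
        np.testing.assert_array_equal(calib_series_small.thicknesses,
                                      [0, 2, 4, 7, 11, 16, 21])
        assert calib_series_small.dark.pixels.shape == (64, 64)

    def test_attenuation_monotone(self, calib_series_small):
        means = [img.pixels.mean() for img in calib_series_small.images]
        open_mean = means[0]
        assert all(m < open_mean for m in means[1:])

    @pytest.mark.parametrize("bad", [[0.0], [0.0, 5.0], [5.0, 7.0, 9.0]])
    def test_underdetermined_series_rejected(self, bad, small_spec, forward):
        with pytest.raises(ValueError):
            sim.make_calibration_series(bad, calib=forward, spec=small_spec)
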