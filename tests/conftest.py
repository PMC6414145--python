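"""Shared fixtures: small noiseless simulation setups reused across modules."""

import numpy as np
import pytest

from epidose import QuadraticCalibrator, dark_correct
from epidose import simulate as sim


@pytest.fixture(scope="session")
def small_spec():
    """64x64 noiseless acquisition grid (fast unit-test scale)."""
    return sim.AcquisitionSpec(pixels_x=64, pixels_y=64, pixel_pitch=0.1,
                               noise_scale=0.0, seed=7)


@pytest.fixture(scope="session")
def forward():
    """Forward model with the default scatter constant."""
    return sim.ForwardModel()


@pytest.fixture(scope="session")
def forward_clean():
    """Scatter-free forward model (pure quadratic attenuation)."""
    return sim.ForwardModel(k0=0.0)


@pytest.fixture(scope="session")
def calib_series_small(small_spec, forward):
    return sim.make_calibration_series(calib=forward, spec=small_spec)


@pytest.fixture(scope="session")
def calibrator_small(calib_series_small):
    return QuadraticCalibrator.from_series(calib_series_small)


@pytest.fixture(scope="session")
def calib_series_clean(small_spec, forward_clean):
    return sim.make_calibration_series(calib=forward_clean, spec=small_spec)


@pytest.fixture(scope="session")
def calibrator_clean(calib_series_clean):
    return QuadraticCalibrator.from_series(calib_series_clean)


@pytest.fixture(scope="session")
def breast_recon_small(small_spec, forward, calib_series_small, calibrator_small):
    """Static breast-phantom reconstruction at unit-test scale.

    Returns (phantom, beam, thickness_map, truth_array, spec).
    """
    from epidose import reconstruct

    # small grid: shrink the phantom so dome and chest wall fit in 6.4 cm
    phantom = sim.make_breast_phantom(
        12.0, outline_params={"dome_rx": 2.0, "dome_ry": 1.6, "ramp_height": 0.0})
    beam = sim.treatment_beam(5.0, 4.0, wedge_min=0.5)
    trace = sim.make_static_trace(30.0)
    img = dark_correct(
        sim.acquire(phantom, beam, trace, forward, small_spec, start_offset=0.0),
        calib_series_small.dark)
    open_tx = dark_correct(
        sim.acquire(None, beam, trace, forward, small_spec, start_offset=0.0),
        calib_series_small.dark)
    tmap = reconstruct(img, calibrator_small, open_treat=open_tx,
                       area_treat=beam.field_area)
    x, y = sim.grid_coords(small_spec)
    X, Y = np.meshgrid(x, y)
    truth = phantom.thickness(X, Y)
    return phantom, beam, tmap, truth, small_spec
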