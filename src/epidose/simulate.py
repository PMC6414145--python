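"""Synthetic phantom, beam, motion and portal-image generation.

This module provides every input the transit-dosimetry pipeline needs:

* an analytic breast-on-chest-wall phantom expressed as a water-equivalent
  thickness function ``t(x, y)`` in beam's-eye-view coordinates,
* beam models for the flood calibration field and the (wedged) treatment
  field,
* 1D longitudinal motion traces — static, sinusoidal, and irregular
  patient-like breathing,
* a frame-integrating portal-image acquisition model with per-frame
  multiplicative noise and dark-current offset, and
* the uniform-slab calibration series (open field + slabs + dark image).

The forward image model is the quadratic attenuation law
``I = I0 * fluence * exp(-a*t - b*t^2)`` with a first-order
scatter-to-primary factor ``(1 + k0 * A * t)``, so the reconstruction
module's scatter-correction loop removes exactly what is added here.

Coordinates: arrays are indexed ``[row, col] = [y, x]``; ``x`` increases with
column index and is the longitudinal (motion) axis.  Physical coordinates are
pixel centres in cm at the isocentre plane, with the grid centred on (0, 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "PhantomModel",
    "BeamModel",
    "MotionTrace",
    "AcquisitionSpec",
    "PortalImage",
    "ForwardModel",
    "CalibrationSeries",
    "CALIB_THICKNESSES_CM",
    "MAX_CALIB_THICKNESS_CM",
    "K0_DEFAULT",
    "grid_coords",
    "make_breast_phantom",
    "make_uniform_slab",
    "make_static_trace",
    "make_sinusoid_trace",
    "make_patient_trace",
    "render_transit_image",
    "acquire",
    "make_calibration_series",
    "calibration_beam",
    "treatment_beam",
]

#: Plastic-Water slab thicknesses of the seven-image calibration set (cm).
CALIB_THICKNESSES_CM: tuple[float, ...] = (0.0, 2.0, 4.0, 7.0, 11.0, 16.0, 21.0)

#: Largest calibrated thickness (cm); thicker objects are extrapolation.
MAX_CALIB_THICKNESS_CM: float = 21.0

#: Scatter-to-primary geometry constant (1/cm^3) for SPR = k0 * A * t.
K0_DEFAULT: float = 1.93e-5


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomModel:
    """Analytic water-equivalent phantom in beam's-eye-view coordinates.

    Attributes
    ----------
    thickness_fn
        Vectorized callable ``t(x, y)`` returning thickness in cm for
        coordinates in cm at the isocentre plane.  Non-negative everywhere
        and exactly zero outside ``body_extent``.
    breast_outline
        Closed polygon ``(N, 2)`` of (x, y) cm tracing the breast edge.
    body_extent
        ``(xmin, xmax, ymin, ymax)`` bounding box of non-zero thickness.
    """

    thickness_fn: Callable[[np.ndarray, np.ndarray], np.ndarray]
    breast_outline: np.ndarray
    body_extent: tuple[float, float, float, float]

    def thickness(self, x, y) -> np.ndarray:
        """Evaluate the thickness function, enforcing the support box."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        t = np.asarray(self.thickness_fn(x, y), dtype=float)
        xmin, xmax, ymin, ymax = self.body_extent
        inside = (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)
        return np.where(inside, t, 0.0)


@dataclass(frozen=True)
class BeamModel:
    """Rectangular field aperture with an optional wedge fluence ramp.

    The fluence is 1.0 (or a linear wedge ramp ``wedge_min -> 1.0`` along
    +x) inside the aperture and exactly 0 outside.  ``field_area`` is the
    aperture area at the isocentre plane, the ``A`` of the scatter model.
    """

    field_size_x: float
    field_size_y: float
    wedge_min: float = 1.0  # 1.0 = open field; < 1.0 = wedge ramp along x

    def __post_init__(self):
        if self.field_size_x <= 0 or self.field_size_y <= 0:
            raise ValueError("field sizes must be positive")
        if not 0.0 < self.wedge_min <= 1.0:
            raise ValueError("wedge_min must be in (0, 1]")

    @property
    def field_area(self) -> float:
        """Aperture area A (cm^2) at the isocentre plane."""
        return self.field_size_x * self.field_size_y

    def fluence(self, x, y) -> np.ndarray:
        """Per-pixel multiplicative fluence: wedge ramp inside, 0 outside."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        hx, hy = self.field_size_x / 2.0, self.field_size_y / 2.0
        inside = (np.abs(x) <= hx) & (np.abs(y) <= hy)
        if self.wedge_min >= 1.0:
            f = np.ones_like(x)
        else:
            frac = np.clip((x + hx) / (2.0 * hx), 0.0, 1.0)
            f = self.wedge_min + (1.0 - self.wedge_min) * frac
        return np.where(inside, f, 0.0)


def calibration_beam(field_size: float = 26.0) -> BeamModel:
    """The flat flood field used for the slab calibration series."""
    return BeamModel(field_size, field_size, wedge_min=1.0)


def treatment_beam(
    field_size_x: float = 14.0, field_size_y: float = 8.0, wedge_min: float = 0.5
) -> BeamModel:
    """The asymmetric wedged treatment field (wedge as a static fluence ramp)."""
    return BeamModel(field_size_x, field_size_y, wedge_min=wedge_min)


@dataclass(frozen=True)
class MotionTrace:
    """Sampled 1D longitudinal displacement versus time.

    ``times`` are strictly increasing seconds; ``displacement`` is cm along
    +x.  ``kind`` is one of ``static``, ``sinusoid``, ``patient_like``.
    """

    times: np.ndarray
    displacement: np.ndarray
    kind: str
    seed: int | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.displacement, dtype=float)
        if t.ndim != 1 or t.shape != d.shape:
            raise ValueError("times and displacement must be matching 1D arrays")
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing with >= 2 samples")
        if not np.all(np.isfinite(d)):
            raise ValueError("displacement must be finite")
        if self.kind == "static" and np.any(d != 0.0):
            raise ValueError("a static trace must have zero displacement")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "displacement", d)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def displacement_at(self, t) -> np.ndarray:
        """Linear interpolation of displacement at arbitrary times (s)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < self.times[0] - 1e-9) or np.any(t > self.times[-1] + 1e-9):
            raise ValueError("requested time outside the trace support")
        return np.interp(t, self.times, self.displacement)

    def to_csv(self, path) -> None:
        """Write the two-column trace CSV (header: time_s, displacement_cm)."""
        arr = np.column_stack([self.times, self.displacement])
        np.savetxt(path, arr, delimiter=",", header="time_s,displacement_cm",
                   comments="", fmt="%.6f")

    @classmethod
    def from_csv(cls, path, kind: str = "patient_like") -> "MotionTrace":
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(times=arr[:, 0], displacement=arr[:, 1], kind=kind)


@dataclass(frozen=True)
class AcquisitionSpec:
    """Frame-integrated acquisition parameters.

    Defaults follow the clinical acquisition emulated here: 60 frames of
    430 ms each (a ~25.8 s delivery at 100 MU), a 256x256 grid with 0.1 cm
    pixels at the isocentre plane, 0.5% per-frame multiplicative noise and a
    constant dark-current offset.
    """

    n_frames: int = 60
    frame_time: float = 0.43
    pixels_x: int = 256
    pixels_y: int = 256
    pixel_pitch: float = 0.1
    noise_scale: float = 0.005
    dark_level: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.frame_time <= 0:
            raise ValueError("frame_time must be positive")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")

    @property
    def delivery_time(self) -> float:
        return self.n_frames * self.frame_time

    @property
    def shape(self) -> tuple[int, int]:
        return (self.pixels_y, self.pixels_x)


@dataclass
class PortalImage:
    """A 2D portal image with acquisition provenance.

    ``pixels`` is a non-negative float array ``(ny, nx)``; ``pixel_pitch``
    is the pixel spacing in cm at the isocentre plane.
    """

    pixels: np.ndarray
    pixel_pitch: float
    is_dark_corrected: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ForwardModel:
    """Ground-truth coefficients of the synthetic image formation model.

    ``alpha0`` (1/cm) and ``beta0`` (1/cm^2) parameterize the quadratic
    attenuation exponent; ``i0`` is the open-field signal in counts; ``k0``
    (1/cm^3) scales the first-order scatter-to-primary ratio.  Setting
    ``k0 = 0`` produces scatter-free images (pure quadratic attenuation).
    """

    alpha0: float = 0.05
    beta0: float = 1.0e-4
    i0: float = 10000.0
    k0: float = K0_DEFAULT

    def __post_init__(self):
        if self.alpha0 <= 0:
            raise ValueError("alpha0 must be positive")
        if self.beta0 < 0 or self.k0 < 0 or self.i0 <= 0:
            raise ValueError("beta0, k0 must be >= 0 and i0 > 0")


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------


def _cos_step(u: np.ndarray) -> np.ndarray:
    """Smooth 0->1 step on [0, 1] (cosine easing), clipped outside."""
    u = np.clip(u, 0.0, 1.0)
    return 0.5 - 0.5 * np.cos(np.pi * u)


def make_breast_phantom(
    separation_max: float = 16.0,
    outline_params: dict | None = None,
) -> PhantomModel:
    """Build the analytic breast phantom: a smooth dome on a chest-wall ramp.

    The thickness function is a saturating chest-wall ramp (height
    ``ramp_height``) plus an elliptical cos^2 dome centred at
    ``(dome_cx, dome_cy)`` whose apex brings the total to exactly
    ``separation_max``.  The dome support (the breast outline) is the
    ellipse with semi-axes ``(dome_rx, dome_ry)``; the ramp saturates
    before the dome starts so the apex is the global maximum.

    Parameters
    ----------
    separation_max : float
        Peak water-equivalent thickness in cm; must lie in (0, 21], the
        calibrated range.
    outline_params : dict, optional
        Overrides for ``dome_rx, dome_ry, dome_cx, dome_cy, ramp_height``.

    Returns
    -------
    PhantomModel
    """
    if not 0.0 < separation_max <= MAX_CALIB_THICKNESS_CM:
        raise ValueError(
            f"separation_max must be in (0, {MAX_CALIB_THICKNESS_CM}] cm "
            f"(calibrated thickness range); got {separation_max}"
        )
    p = {
        "dome_rx": 5.0,
        "dome_ry": 3.6,
        "dome_cx": 0.0,
        "dome_cy": 0.0,
        "ramp_height": min(6.0, separation_max / 2.0),
    }
    if outline_params:
        unknown = set(outline_params) - set(p)
        if unknown:
            raise ValueError(f"unknown outline parameters: {sorted(unknown)}")
        p.update(outline_params)

    ramp_height = float(p["ramp_height"])
    if not 0.0 <= ramp_height < separation_max:
        raise ValueError("ramp_height must satisfy 0 <= ramp_height < separation_max")
    dome_height = separation_max - ramp_height
    rx, ry = float(p["dome_rx"]), float(p["dome_ry"])
    cx, cy = float(p["dome_cx"]), float(p["dome_cy"])

    # ramp rises over [-10, -6], plateaus, falls over [7, 10]; the dome
    # support must sit inside the plateau so the apex equals separation_max
    x_rise0, x_rise1, x_fall0, x_fall1 = -10.0, -6.0, 7.0, 10.0
    if cx - rx < x_rise1 or cx + rx > x_fall0:
        raise ValueError("dome support must lie within the chest-wall plateau")
    extent = (x_rise0, x_fall1, -12.8, 12.8)

    def thickness_fn(x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ramp = ramp_height * _cos_step((x - x_rise0) / (x_rise1 - x_rise0))
        ramp = ramp * (1.0 - _cos_step((x - x_fall0) / (x_fall1 - x_fall0)))
        r = np.sqrt(((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2)
        dome = np.where(r < 1.0, dome_height * np.cos(np.pi * r / 2.0) ** 2, 0.0)
        return ramp + dome

    theta = np.linspace(0.0, 2.0 * np.pi, 73)
    outline = np.column_stack([cx + rx * np.cos(theta), cy + ry * np.sin(theta)])
    return PhantomModel(thickness_fn=thickness_fn, breast_outline=outline,
                        body_extent=extent)


def make_uniform_slab(thickness: float, extent_half: float = 50.0) -> PhantomModel:
    """A uniform slab of the given thickness covering the whole field."""
    if thickness < 0:
        raise ValueError("thickness must be >= 0")
    e = float(extent_half)

    def thickness_fn(x, y):
        return np.full(np.broadcast(np.asarray(x), np.asarray(y)).shape,
                       float(thickness))

    outline = np.array([[-e, -e], [e, -e], [e, e], [-e, e], [-e, -e]])
    return PhantomModel(thickness_fn=thickness_fn, breast_outline=outline,
                        body_extent=(-e, e, -e, e))


# ---------------------------------------------------------------------------
# motion traces
# ---------------------------------------------------------------------------


def make_static_trace(duration: float = 60.0, dt: float = 0.01) -> MotionTrace:
    """A zero-displacement trace (the static phantom)."""
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    times = np.arange(0.0, duration + dt / 2.0, dt)
    return MotionTrace(times=times, displacement=np.zeros_like(times), kind="static")


def make_sinusoid_trace(
    amplitude: float,
    frequency: float,
    duration: float = 60.0,
    phase: float = 0.0,
    dt: float = 0.01,
) -> MotionTrace:
    """Sinusoidal longitudinal motion.

    ``displacement(t) = amplitude * sin(2*pi*frequency/60 * t + phase)`` with
    ``frequency`` in cycles/min, so peak-to-peak excursion is 2*amplitude.
    An amplitude of exactly 0 degenerates to a static trace.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if frequency <= 0:
        raise ValueError("frequency must be positive (cycles/min)")
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    times = np.arange(0.0, duration + dt / 2.0, dt)
    if amplitude == 0.0:
        return MotionTrace(times=times, displacement=np.zeros_like(times),
                           kind="static")
    disp = amplitude * np.sin(2.0 * np.pi * frequency / 60.0 * times + phase)
    return MotionTrace(times=times, displacement=disp, kind="sinusoid")


def make_patient_trace(
    mean_period: float = 4.0,
    period_cv: float = 0.15,
    mean_amplitude: float = 1.0,
    amplitude_cv: float = 0.2,
    baseline_drift: float = 0.0,
    duration: float = 60.0,
    seed: int = 0,
    dt: float = 0.01,
) -> MotionTrace:
    """Irregular patient-like breathing: cycle-resampled quasi-sinusoid.

    Each breathing cycle draws its period and amplitude from lognormal
    distributions with the given means and coefficients of variation.  The
    within-cycle shape is ``a * sin^4(pi * u)`` (u = cycle phase in [0, 1)),
    which spends most of each cycle near the exhale baseline — the
    asymmetric plateau typical of external-marker respiratory traces — and
    a linear baseline drift in cm/min may be superposed.  Fully
    deterministic given ``seed``.
    """
    for name, v in [("mean_period", mean_period), ("mean_amplitude", mean_amplitude)]:
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    if period_cv < 0 or amplitude_cv < 0:
        raise ValueError("dispersion parameters must be >= 0")
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")

    rng = np.random.default_rng(seed)

    def _lognormal(mean, cv, size):
        if cv == 0.0:
            return np.full(size, mean)
        sigma2 = np.log1p(cv**2)
        mu = np.log(mean) - sigma2 / 2.0
        return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)

    # draw a fixed batch of cycles (deterministic consumption), extend if short
    n_guess = max(4, int(np.ceil(duration / mean_period * 3)) + 4)
    periods = _lognormal(mean_period, period_cv, n_guess)
    amps = _lognormal(mean_amplitude, amplitude_cv, n_guess)
    while periods.sum() < duration + mean_period:
        periods = np.concatenate([periods, _lognormal(mean_period, period_cv, 8)])
        amps = np.concatenate([amps, _lognormal(mean_amplitude, amplitude_cv, 8)])

    times = np.arange(0.0, duration + dt / 2.0, dt)
    starts = np.concatenate([[0.0], np.cumsum(periods)])
    idx = np.searchsorted(starts, times, side="right") - 1
    idx = np.clip(idx, 0, len(periods) - 1)
    u = (times - starts[idx]) / periods[idx]
    disp = amps[idx] * np.sin(np.pi * u) ** 4
    disp = disp + baseline_drift * times / 60.0
    return MotionTrace(times=times, displacement=disp, kind="patient_like", seed=seed)


# ---------------------------------------------------------------------------
# image formation
# ---------------------------------------------------------------------------


def grid_coords(spec: AcquisitionSpec) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-centre coordinate vectors (x, y) in cm, grid centred on (0, 0)."""
    x = (np.arange(spec.pixels_x) - (spec.pixels_x - 1) / 2.0) * spec.pixel_pitch
    y = (np.arange(spec.pixels_y) - (spec.pixels_y - 1) / 2.0) * spec.pixel_pitch
    return x, y


def render_transit_image(
    phantom: PhantomModel | None,
    beam: BeamModel,
    displacement: float,
    calib: ForwardModel,
    spec: AcquisitionSpec,
) -> np.ndarray:
    """Noise-free transit image of the phantom at a fixed displacement.

    The phantom thickness is sampled at ``t(x - displacement, y)`` (the
    phantom moves along +x; the field aperture stays fixed), attenuated by
    the quadratic law and augmented by the first-order scatter factor
    ``1 + k0 * A * t`` with ``A`` the aperture area of ``beam``.

    Returns the bare signal grid in counts (no dark level, no noise).
    A warning is emitted when the sampled thickness exceeds the calibrated
    range (extrapolation).
    """
    if not np.isfinite(displacement):
        raise ValueError("displacement must be finite")
    x, y = grid_coords(spec)
    X, Y = np.meshgrid(x, y)
    fluence = beam.fluence(X, Y)
    if phantom is None:
        t = np.zeros_like(X)
    else:
        t = phantom.thickness(X - displacement, Y)
    if np.any(t > MAX_CALIB_THICKNESS_CM + 1e-9):
        warnings.warn(
            "phantom thickness exceeds the calibrated range "
            f"({MAX_CALIB_THICKNESS_CM} cm): thickness extrapolation",
            RuntimeWarning,
            stacklevel=2,
        )
    primary = calib.i0 * fluence * np.exp(-calib.alpha0 * t - calib.beta0 * t**2)
    return primary * (1.0 + calib.k0 * beam.field_area * t)


def acquire(
    phantom: PhantomModel | None,
    beam: BeamModel,
    trace: MotionTrace,
    calib: ForwardModel,
    spec: AcquisitionSpec,
    start_offset: float | None = None,
) -> PortalImage:
    """Frame-integrated acquisition of the (possibly moving) phantom.

    The image is the mean over ``spec.n_frames`` frames of the transit image
    evaluated at the trace displacement at each frame midpoint, each frame
    optionally perturbed by multiplicative Gaussian noise of relative
    standard deviation ``spec.noise_scale``, plus the dark-current offset.

    ``start_offset`` shifts the delivery start within the trace ("an
    arbitrary point in the respiratory cycle"); when None it is drawn
    uniformly from the available slack using ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    delivery = spec.delivery_time
    slack = trace.duration - delivery
    if start_offset is None:
        start_offset = float(rng.uniform(0.0, slack)) if slack > 1e-12 else 0.0
    if slack < -1e-9 or start_offset < 0 or start_offset - 1e-9 > slack:
        raise ValueError(
            f"trace duration {trace.duration:.2f}s cannot cover a "
            f"{delivery:.2f}s delivery starting at offset {start_offset:.2f}s"
        )

    midpoints = trace.times[0] + start_offset + (np.arange(spec.n_frames) + 0.5) * spec.frame_time
    disps = trace.displacement_at(midpoints)

    frames = np.empty((spec.n_frames,) + spec.shape)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for k, d in enumerate(disps):
            frames[k] = render_transit_image(phantom, beam, float(d), calib, spec)
        extrapolated = any(issubclass(w.category, RuntimeWarning) for w in caught)
    if extrapolated:  # re-emit one summary warning for the whole delivery
        warnings.warn(
            "phantom thickness exceeds the calibrated range during the "
            "delivery: thickness extrapolation",
            RuntimeWarning,
            stacklevel=2,
        )
    if spec.noise_scale > 0:
        noise = rng.normal(0.0, spec.noise_scale, size=frames.shape)
        frames = frames * (1.0 + noise)
    acc = frames.mean(axis=0)

    meta = {
        "field_size_x": beam.field_size_x,
        "field_size_y": beam.field_size_y,
        "field_area": beam.field_area,
        "motion_kind": trace.kind,
        "seed": spec.seed,
        "start_offset_s": start_offset,
        "n_frames": spec.n_frames,
        "frame_time_s": spec.frame_time,
        "extrapolated_thickness": extrapolated,
    }
    return PortalImage(pixels=spec.dark_level + acc, pixel_pitch=spec.pixel_pitch,
                       is_dark_corrected=False, meta=meta)


# ---------------------------------------------------------------------------
# calibration series
# ---------------------------------------------------------------------------


@dataclass
class CalibrationSeries:
    """The slab calibration set: one flood image per thickness plus a dark."""

    images: list[PortalImage]
    thicknesses: np.ndarray
    dark: PortalImage


def make_calibration_series(
    thicknesses: Sequence[float] = CALIB_THICKNESSES_CM,
    beam: BeamModel | None = None,
    calib: ForwardModel | None = None,
    spec: AcquisitionSpec | None = None,
) -> CalibrationSeries:
    """Generate the uniform-slab flood calibration series plus a dark image.

    The default seven-point thickness set {0, 2, 4, 7, 11, 16, 21} cm
    includes the open field (t = 0).  Each slab image is a static
    frame-integrated acquisition through the flood field; the scatter factor
    uses the calibration field area, so the fitted coefficients absorb the
    calibration-field scatter exactly as a measured series would.
    """
    beam = beam if beam is not None else calibration_beam()
    calib = calib if calib is not None else ForwardModel()
    spec = spec if spec is not None else AcquisitionSpec()

    t_arr = np.asarray(list(thicknesses), dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("thicknesses must be >= 0")
    if len(np.unique(t_arr)) != len(t_arr):
        raise ValueError("thicknesses must be distinct")
    if len(t_arr) < 3 or 0.0 not in t_arr:
        raise ValueError(
            "need at least 3 distinct thicknesses including 0 (open field); "
            "the quadratic fit is underdetermined otherwise"
        )

    child_seeds = np.random.default_rng(spec.seed).integers(0, 2**31 - 1,
                                                            size=len(t_arr))
    trace = make_static_trace(duration=spec.delivery_time + 1.0)
    images = []
    for t, s in zip(t_arr, child_seeds):
        slab = None if t == 0.0 else make_uniform_slab(t)
        img = acquire(slab, beam, trace, calib, replace(spec, seed=int(s)),
                      start_offset=0.0)
        img.meta["slab_thickness_cm"] = float(t)
        images.append(img)
    dark = PortalImage(
        pixels=np.full(spec.shape, spec.dark_level),
        pixel_pitch=spec.pixel_pitch,
        is_dark_corrected=False,
        meta={"kind": "dark"},
    )
    return CalibrationSeries(images=images, thicknesses=t_arr, dark=dark)
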