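"""Motion-effect analysis: dose conversion, dose differences, 2D gamma.

Reconstructed thickness maps are converted back to relative intensity
("dose") images with fixed conversion coefficients (alpha = 0.05 /cm,
beta = 1e-4 /cm^2), so that motion and static deliveries can be compared
the way portal-dose distributions are:

* per-pixel relative dose differences over the breast ROI, summarized as
  the percentage of pixels within 5/3/2/1% of the static reference, and
* a 2D gamma analysis with *local* dose normalization at criteria from
  5%/5 mm down to 1%/1 mm, reporting the pass rate (gamma < 1).

``motion_experiment`` runs the entire chain — simulate, calibrate,
reconstruct, segment, compare — for a static reference plus a set of
motion sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from . import simulate as sim
from .calibration import QuadraticCalibrator, dark_correct
from .reconstruction import ThicknessMap, ThicknessReconstructor
from .segmentation import RoiPolygon, field_mask, roi_from_outline_cm

__all__ = [
    "DoseImage",
    "GammaMap",
    "DoseDiffSummary",
    "thickness_to_intensity",
    "dose_diff_summary",
    "gamma_2d",
    "profile_1d",
    "MotionStudyConfig",
    "MotionStudyReport",
    "motion_experiment",
]

#: Conversion coefficients used to map thickness back to intensity.
ALPHA_CONV_DEFAULT = 0.05  # 1/cm
BETA_CONV_DEFAULT = 1.0e-4  # 1/cm^2

#: Gamma criteria (dose %, distance mm) mirroring the standard ladder.
GAMMA_CRITERIA_DEFAULT: tuple[tuple[float, float], ...] = (
    (5.0, 5.0), (3.0, 3.0), (2.0, 2.0), (1.0, 1.0)
)

DOSE_DIFF_THRESHOLDS_DEFAULT: tuple[float, ...] = (5.0, 3.0, 2.0, 1.0)


@dataclass
class DoseImage:
    """Relative intensity image derived from a thickness map."""

    dose: np.ndarray
    alpha_conv: float
    beta_conv: float
    valid_mask: np.ndarray
    pixel_pitch: float = 0.1
    source: str = ""


@dataclass
class GammaMap:
    """Per-pixel gamma over the ROI plus the pass rate.

    ``gamma`` is NaN outside the ROI; ``pass_rate`` is the percentage of
    ROI pixels with gamma < 1.
    """

    gamma: np.ndarray
    dose_crit: float  # % (local)
    dist_crit: float  # mm
    pass_rate: float  # %
    n_roi: int


@dataclass
class DoseDiffSummary:
    """Percent of ROI pixels within each |relative dose difference| level."""

    thresholds: tuple[float, ...]
    pct_within: tuple[float, ...]
    n_roi: int

    def as_dict(self) -> dict[str, float]:
        return {f"{thr:g}%": pct for thr, pct in zip(self.thresholds, self.pct_within)}


def thickness_to_intensity(
    t_map,
    alpha_conv: float = ALPHA_CONV_DEFAULT,
    beta_conv: float = BETA_CONV_DEFAULT,
    i0: float = 1.0,
) -> DoseImage:
    """Convert a thickness map to a relative intensity (dose) image.

    ``dose = i0 * exp(-alpha_conv * t - beta_conv * t**2)``; the validity
    mask of a :class:`ThicknessMap` input propagates.
    """
    if isinstance(t_map, ThicknessMap):
        t = t_map.t
        valid = t_map.valid_mask
        pitch = t_map.pixel_pitch
        source = "thickness_map"
    else:
        t = np.asarray(t_map, dtype=float)
        valid = np.isfinite(t) & (t >= 0)
        pitch = 0.1
        source = "array"
    if np.any(t[valid] < 0):
        raise ValueError("thickness must be >= 0 on valid pixels")
    dose = i0 * np.exp(-alpha_conv * t - beta_conv * t**2)
    return DoseImage(dose=dose, alpha_conv=alpha_conv, beta_conv=beta_conv,
                     valid_mask=np.asarray(valid, dtype=bool),
                     pixel_pitch=pitch, source=source)


def _roi_mask(roi, shape) -> np.ndarray:
    if isinstance(roi, RoiPolygon):
        mask = roi.filled_mask
    else:
        mask = np.asarray(roi, dtype=bool)
    if mask.shape != tuple(shape):
        raise ValueError("ROI mask shape does not match the images")
    return mask


def dose_diff_summary(
    evaluated: DoseImage,
    reference: DoseImage,
    roi,
    thresholds: Sequence[float] = DOSE_DIFF_THRESHOLDS_DEFAULT,
) -> DoseDiffSummary:
    """Relative (local) dose differences within the ROI, per threshold.

    The per-pixel difference is ``(evaluated - reference) / reference``;
    the summary reports the percentage of ROI pixels whose absolute
    difference is at or below each threshold (in %).
    """
    ev, ref = np.asarray(evaluated.dose), np.asarray(reference.dose)
    if ev.shape != ref.shape:
        raise ValueError("evaluated and reference grids differ")
    mask = _roi_mask(roi, ev.shape)
    mask = mask & evaluated.valid_mask & reference.valid_mask & (ref > 0)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty ROI")
    rel = np.abs((ev[mask] - ref[mask]) / ref[mask]) * 100.0
    pct = tuple(float(np.mean(rel <= thr) * 100.0) for thr in thresholds)
    return DoseDiffSummary(thresholds=tuple(thresholds), pct_within=pct, n_roi=n)


def gamma_2d(
    evaluated: DoseImage,
    reference: DoseImage,
    roi,
    dose_crit_pct: float,
    dist_crit_mm: float,
    pixel_pitch_cm: float | None = None,
    search_factor: float = 3.0,
    interp_factor: int = 10,
) -> GammaMap:
    """Local-dose 2D gamma of ``evaluated`` against ``reference`` over an ROI.

    For each ROI pixel r the gamma index is the minimum over reference
    positions p of

        sqrt( (|p - r| / dist_crit)^2
              + (D_eval(r) - D_ref(p))^2 / (dose_crit/100 * D_ref(p))^2 )

    with the dose criterion normalized *locally* to the reference dose at
    the compared position.  The search is restricted to
    ``|p - r| <= search_factor * dist_crit`` and the reference is sampled
    on a sub-grid of ``dist_crit / interp_factor`` via bilinear
    interpolation.

    Raises when the distance criterion is below the pixel pitch and no
    interpolation is requested (the search would be undersampled).
    """
    ev, ref = np.asarray(evaluated.dose), np.asarray(reference.dose)
    if ev.shape != ref.shape:
        raise ValueError("evaluated and reference grids differ")
    pitch = pixel_pitch_cm if pixel_pitch_cm is not None else reference.pixel_pitch
    dist_cm = dist_crit_mm / 10.0
    if interp_factor < 1:
        raise ValueError("interp_factor must be >= 1")
    if interp_factor == 1 and dist_cm < pitch:
        raise ValueError(
            f"distance criterion {dist_crit_mm} mm is below the pixel pitch "
            f"({pitch * 10:g} mm) without interpolation: undersampled search"
        )
    mask = _roi_mask(roi, ev.shape)
    mask = mask & evaluated.valid_mask & reference.valid_mask
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty ROI")

    # search lattice: the reference up-sampled interp_factor times relative
    # to the pixel grid (never coarser than dist_crit/interp_factor)
    step = min(dist_cm, pitch) / interp_factor
    radius = search_factor * dist_cm
    m = int(np.floor(radius / step + 1e-9))
    offs = np.arange(-m, m + 1) * step
    OX, OY = np.meshgrid(offs, offs)
    d2 = OX**2 + OY**2
    keep = d2 <= radius**2 + 1e-12
    ox, oy, od2 = OX[keep], OY[keep], d2[keep]
    order = np.argsort(od2)  # nearest offsets first enable early exit
    ox, oy, od2 = ox[order], oy[order], od2[order]

    rr, cc = np.nonzero(mask)
    d_eval = ev[rr, cc]
    dose_frac = dose_crit_pct / 100.0
    g2_min = np.full(n, np.inf)

    # a pixel is finished once its best gamma^2 is below the pure distance
    # term of all remaining (radius-sorted) offsets
    chunk = max(16, int(2e6 // max(n, 1)))
    for i0 in range(0, len(ox), chunk):
        sl = slice(i0, min(i0 + chunk, len(ox)))
        thr = od2[sl.start] / dist_cm**2
        active = np.nonzero(g2_min > thr)[0]
        if active.size == 0:
            break
        rows = rr[active][None, :] + oy[sl, None] / pitch
        cols = cc[active][None, :] + ox[sl, None] / pitch
        d_ref = map_coordinates(ref, [rows.ravel(), cols.ravel()], order=1,
                                mode="nearest").reshape(rows.shape)
        with np.errstate(divide="ignore", invalid="ignore"):
            dose_term = (d_eval[active][None, :] - d_ref) ** 2 \
                / (dose_frac * d_ref) ** 2
        dose_term = np.where(d_ref > 0, dose_term, np.inf)
        g2 = od2[sl, None] / dist_cm**2 + dose_term
        g2_min[active] = np.minimum(g2_min[active], g2.min(axis=0))

    gamma_vals = np.sqrt(g2_min)
    gamma = np.full(ev.shape, np.nan)
    gamma[rr, cc] = gamma_vals
    pass_rate = float(np.mean(gamma_vals < 1.0) * 100.0)
    return GammaMap(gamma=gamma, dose_crit=dose_crit_pct, dist_crit=dist_crit_mm,
                    pass_rate=pass_rate, n_roi=n)


def profile_1d(map_like, row: int | None = None, line=None,
               pixel_pitch: float | None = None):
    """Extract a 1D profile from a 2D map.

    Either ``row`` (nearest-neighbour row extraction) or ``line`` (a pair
    of (x_px, y_px) endpoints, sampled with bilinear interpolation at pixel
    spacing) must be given.  Returns ``(positions_cm, values)``.
    """
    if isinstance(map_like, ThicknessMap):
        arr = map_like.t
        pitch = map_like.pixel_pitch
    elif isinstance(map_like, DoseImage):
        arr = map_like.dose
        pitch = map_like.pixel_pitch
    else:
        arr = np.asarray(map_like, dtype=float)
        pitch = pixel_pitch if pixel_pitch is not None else 0.1
    ny, nx = arr.shape
    if (row is None) == (line is None):
        raise ValueError("give exactly one of row or line")
    if row is not None:
        if not 0 <= row < ny:
            raise ValueError(f"row {row} outside grid of {ny} rows")
        pos = (np.arange(nx) - (nx - 1) / 2.0) * pitch
        return pos, arr[row].copy()
    (x0, y0), (x1, y1) = line
    for x, y in ((x0, y0), (x1, y1)):
        if not (0 <= x <= nx - 1 and 0 <= y <= ny - 1):
            raise ValueError("line endpoint outside the grid")
    length = float(np.hypot(x1 - x0, y1 - y0))
    n = max(2, int(np.ceil(length)) + 1)
    s = np.linspace(0.0, 1.0, n)
    cols = x0 + s * (x1 - x0)
    rows = y0 + s * (y1 - y0)
    vals = map_coordinates(arr, [rows, cols], order=1, mode="nearest")
    return s * length * pitch, vals


# ---------------------------------------------------------------------------
# end-to-end motion experiment
# ---------------------------------------------------------------------------


@dataclass
class MotionStudyConfig:
    """Configuration of a full simulate-calibrate-reconstruct-compare run.

    The defaults reproduce the experimental design emulated by the
    simulator: a 0.5/1.0/1.5 cm x 12/15/20 cycles/min sinusoid grid plus
    irregular patient-like traces, a 14 x 8 cm wedged treatment field, a
    26 x 26 cm flood calibration and a 60-frame (430 ms) acquisition.
    """

    separation_max: float = 16.0
    field_size_x: float = 14.0
    field_size_y: float = 8.0
    wedge_min: float = 0.5
    calib_field_size: float = 26.0
    amplitudes: tuple[float, ...] = (0.5, 1.0, 1.5)
    frequencies: tuple[float, ...] = (12.0, 15.0, 20.0)
    n_patient_traces: int = 2
    trace_duration: float = 60.0
    gamma_criteria: tuple[tuple[float, float], ...] = GAMMA_CRITERIA_DEFAULT
    diff_thresholds: tuple[float, ...] = DOSE_DIFF_THRESHOLDS_DEFAULT
    gamma_interp_factor: int = 10
    noise_scale: float = 0.005
    n_frames: int = 60
    frame_time: float = 0.43
    pixels: int = 256
    pixel_pitch: float = 0.1
    seed: int = 0


@dataclass
class MotionStudyReport:
    """Tables and maps produced by :func:`motion_experiment`."""

    dose_diff_table: pd.DataFrame
    gamma_table: pd.DataFrame
    thickness_maps: dict[str, ThicknessMap]
    gamma_maps: dict[str, dict[str, GammaMap]]
    profiles: pd.DataFrame
    roi: RoiPolygon
    config: MotionStudyConfig

    def to_csv(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.dose_diff_table.to_csv(outdir / "dose_diff_summary.csv", index=False)
        self.gamma_table.to_csv(outdir / "gamma_pass_rates.csv", index=False)
        self.profiles.to_csv(outdir / "profiles.csv", index=False)


def _motion_set(cfg: MotionStudyConfig) -> list[tuple[str, sim.MotionTrace]]:
    traces: list[tuple[str, sim.MotionTrace]] = []
    for amp in cfg.amplitudes:
        for freq in cfg.frequencies:
            name = f"sin_a{amp:g}_f{freq:g}"
            traces.append((name, sim.make_sinusoid_trace(
                amp, freq, duration=cfg.trace_duration)))
    for i in range(cfg.n_patient_traces):
        traces.append((f"patient_{i}", sim.make_patient_trace(
            duration=cfg.trace_duration, seed=cfg.seed + 1000 + i)))
    return traces


def motion_experiment(cfg: MotionStudyConfig | None = None) -> MotionStudyReport:
    """Run the full chain for a static reference plus each motion sequence.

    Simulates the calibration series and treatment deliveries, fits the
    per-pixel calibration, reconstructs thickness maps, segments the field
    and breast ROI from the static case, converts thickness to intensity,
    and tabulates dose-difference percentages and gamma pass rates for
    every motion sequence against the static reference.
    """
    cfg = cfg if cfg is not None else MotionStudyConfig()
    rng = np.random.default_rng(cfg.seed)
    seeds = iter(rng.integers(0, 2**31 - 1, size=1024).tolist())

    phantom = sim.make_breast_phantom(cfg.separation_max)
    beam_cal = sim.calibration_beam(cfg.calib_field_size)
    beam_tx = sim.treatment_beam(cfg.field_size_x, cfg.field_size_y, cfg.wedge_min)
    forward = sim.ForwardModel()
    spec = sim.AcquisitionSpec(
        n_frames=cfg.n_frames, frame_time=cfg.frame_time,
        pixels_x=cfg.pixels, pixels_y=cfg.pixels, pixel_pitch=cfg.pixel_pitch,
        noise_scale=cfg.noise_scale, seed=next(seeds),
    )

    # calibration
    series = sim.make_calibration_series(beam=beam_cal, calib=forward,
                                         spec=_reseed(spec, next(seeds)))
    calibrator = QuadraticCalibrator.from_series(series)

    # treatment open field (defines the per-pixel output factor F)
    static_trace = sim.make_static_trace(duration=cfg.trace_duration)
    open_tx = sim.acquire(None, beam_tx, static_trace, forward,
                          _reseed(spec, next(seeds)), start_offset=0.0)
    open_tx = dark_correct(open_tx, series.dark)

    recon = ThicknessReconstructor(
        calibration=calibrator, area_treat=beam_tx.field_area,
        open_treat=open_tx, k0=forward.k0,
    ).fit()

    def _deliver(trace: sim.MotionTrace, seed: int) -> ThicknessMap:
        img = sim.acquire(phantom, beam_tx, trace, forward, _reseed(spec, seed))
        return recon.reconstruct(dark_correct(img, series.dark))

    static_map = _deliver(static_trace, next(seeds))
    fmask = field_mask(open_tx)
    roi = roi_from_outline_cm(phantom.breast_outline, cfg.pixel_pitch,
                              static_map.shape)
    roi_mask = roi.filled_mask & fmask.mask
    roi = RoiPolygon(vertices=roi.vertices, filled_mask=roi_mask)

    dose_static = thickness_to_intensity(static_map)

    maps: dict[str, ThicknessMap] = {"static": static_map}
    gamma_maps: dict[str, dict[str, GammaMap]] = {}
    diff_rows, gamma_rows, profile_rows = [], [], []
    mid_row = static_map.shape[0] // 2
    pos, vals = profile_1d(static_map, row=mid_row)
    profile_rows.append(pd.DataFrame(
        {"sequence": "static", "position_cm": pos, "thickness_cm": vals}))

    for name, trace in _motion_set(cfg):
        tmap = _deliver(trace, next(seeds))
        maps[name] = tmap
        dose_mov = thickness_to_intensity(tmap)
        diff = dose_diff_summary(dose_mov, dose_static, roi, cfg.diff_thresholds)
        diff_rows.append({"sequence": name, **diff.as_dict()})
        grow: dict[str, float] = {"sequence": name}
        gamma_maps[name] = {}
        for dose_c, dist_c in cfg.gamma_criteria:
            gm = gamma_2d(dose_mov, dose_static, roi, dose_c, dist_c,
                          pixel_pitch_cm=cfg.pixel_pitch,
                          interp_factor=cfg.gamma_interp_factor)
            key = f"{dose_c:g}%/{dist_c:g}mm"
            grow[key] = gm.pass_rate
            gamma_maps[name][key] = gm
        gamma_rows.append(grow)
        pos, vals = profile_1d(tmap, row=mid_row)
        profile_rows.append(pd.DataFrame(
            {"sequence": name, "position_cm": pos, "thickness_cm": vals}))

    return MotionStudyReport(
        dose_diff_table=pd.DataFrame(diff_rows),
        gamma_table=pd.DataFrame(gamma_rows),
        thickness_maps=maps,
        gamma_maps=gamma_maps,
        profiles=pd.concat(profile_rows, ignore_index=True),
        roi=roi,
        config=cfg,
    )


def _reseed(spec: sim.AcquisitionSpec, seed: int) -> sim.AcquisitionSpec:
    from dataclasses import replace

    return replace(spec, seed=int(seed))
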