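"""File interfaces: 16-bit TIFF images with JSON sidecars, CSV grids,
motion-trace CSVs and calibration-model directories.

Images are stored as 16-bit grayscale TIFF scaled by a counts-per-unit
factor recorded in a ``<name>.json`` sidecar next to the file, so physical
values round-trip to within one quantization step.  Plain CSV grids are
supported as a lossless text alternative.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .calibration import CalibrationModel
from .simulate import MotionTrace, PortalImage

__all__ = [
    "write_image_tiff",
    "read_image_tiff",
    "write_grid_csv",
    "read_grid_csv",
    "save_calibration",
    "load_calibration",
    "write_trace_csv",
    "read_trace_csv",
]

_U16_MAX = 65535


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_image_tiff(path, array, pixel_pitch: float = 0.1, meta: dict | None = None,
                     counts_per_unit: float | None = None) -> None:
    """Write a float array as scaled uint16 TIFF plus a JSON sidecar."""
    path = Path(path)
    arr = np.asarray(array, dtype=float)
    if not np.all(np.isfinite(arr)):
        arr = np.nan_to_num(arr, nan=0.0, posinf=0.0, neginf=0.0)
    lo = float(min(arr.min(), 0.0))
    hi = float(arr.max())
    if counts_per_unit is None:
        span = hi - lo
        counts_per_unit = _U16_MAX / span if span > 0 else 1.0
    scaled = np.clip((arr - lo) * counts_per_unit, 0, _U16_MAX)
    tifffile.imwrite(path, np.round(scaled).astype(np.uint16))
    side = {
        "counts_per_unit": counts_per_unit,
        "offset": lo,
        "pixel_pitch_cm": pixel_pitch,
        "meta": _jsonable(meta or {}),
    }
    _sidecar(path).write_text(json.dumps(side, indent=2))


def read_image_tiff(path) -> PortalImage:
    """Read a scaled TIFF + sidecar back into a :class:`PortalImage`."""
    path = Path(path)
    raw = tifffile.imread(path).astype(float)
    side = json.loads(_sidecar(path).read_text())
    arr = raw / side["counts_per_unit"] + side.get("offset", 0.0)
    meta = side.get("meta", {})
    return PortalImage(
        pixels=arr,
        pixel_pitch=side.get("pixel_pitch_cm", 0.1),
        is_dark_corrected=bool(meta.get("is_dark_corrected", False)),
        meta=meta,
    )


def write_grid_csv(path, array) -> None:
    np.savetxt(path, np.asarray(array, dtype=float), delimiter=",", fmt="%.8g")


def read_grid_csv(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=","))


def save_calibration(model: CalibrationModel, outdir) -> None:
    """Serialize a calibration model as alpha/beta/i0 TIFFs + metadata JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_image_tiff(outdir / "alpha.tiff", model.alpha_map)
    write_image_tiff(outdir / "beta.tiff", model.beta_map)
    write_image_tiff(outdir / "i0.tiff", model.i0_map)
    write_image_tiff(outdir / "residual.tiff", model.fit_residual_map)
    tifffile.imwrite(outdir / "valid.tiff",
                     model.valid_mask.astype(np.uint16) * _U16_MAX)
    meta = {
        "calib_field_area": model.calib_field_area,
        "thicknesses_cm": list(map(float, model.thicknesses)),
    }
    (outdir / "calibration.json").write_text(json.dumps(meta, indent=2))


def load_calibration(indir) -> CalibrationModel:
    indir = Path(indir)
    meta = json.loads((indir / "calibration.json").read_text())
    alpha = read_image_tiff(indir / "alpha.tiff").pixels
    beta = read_image_tiff(indir / "beta.tiff").pixels
    i0 = read_image_tiff(indir / "i0.tiff").pixels
    resid = read_image_tiff(indir / "residual.tiff").pixels
    valid = tifffile.imread(indir / "valid.tiff") > 0
    return CalibrationModel(
        alpha_map=alpha, beta_map=beta, i0_map=i0,
        calib_field_area=meta["calib_field_area"],
        thicknesses=np.asarray(meta["thicknesses_cm"]),
        fit_residual_map=resid, valid_mask=valid,
    )


def write_trace_csv(path, trace: MotionTrace) -> None:
    trace.to_csv(path)


def read_trace_csv(path, kind: str = "patient_like") -> MotionTrace:
    return MotionTrace.from_csv(path, kind=kind)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
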