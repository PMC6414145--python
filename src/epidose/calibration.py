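"""Per-pixel quadratic thickness calibration of portal images.

The detector signal behind a uniform slab of water-equivalent thickness
``t`` is modelled as

    I(x, y) = I0(x, y) * exp(-alpha(x, y) * t - beta(x, y) * t**2)

The quadratic term absorbs beam-hardening and spectral effects that make
the response deviate from a pure exponential.  Fitting a flood series of
known slab thicknesses (plus the open field giving ``I0``) yields per-pixel
coefficient maps ``alpha`` and ``beta``; the fit is linear least squares in
the log domain, ``-ln(I_t / I0) = alpha * t + beta * t**2``, with no
intercept because I(t=0) = I0 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .simulate import CalibrationSeries, PortalImage

__all__ = [
    "CalibrationModel",
    "QuadraticCalibrator",
    "dark_correct",
    "fit_quadratic",
]


def dark_correct(raw: PortalImage, dark: PortalImage) -> PortalImage:
    """Subtract the dark-current offset image, clamping at zero.

    Raises if the grids disagree or if ``raw`` is already corrected
    (double subtraction would bias the signal low).
    """
    if raw.shape != dark.shape:
        raise ValueError(f"shape mismatch: raw {raw.shape} vs dark {dark.shape}")
    if raw.is_dark_corrected:
        raise ValueError("image is already dark-corrected")
    corrected = np.clip(raw.pixels - dark.pixels, 0.0, None)
    return PortalImage(
        pixels=corrected,
        pixel_pitch=raw.pixel_pitch,
        is_dark_corrected=True,
        meta=dict(raw.meta),
    )


@dataclass
class CalibrationModel:
    """Fitted per-pixel calibration: alpha, beta maps plus the open field.

    ``valid_mask`` flags pixels where the fit is trustworthy: positive open
    field, positive slab signals and positive fitted alpha.  Invalid pixels
    keep their fitted values but must not be used downstream.
    """

    alpha_map: np.ndarray  # 1/cm
    beta_map: np.ndarray  # 1/cm^2
    i0_map: np.ndarray  # counts
    calib_field_area: float  # cm^2
    thicknesses: np.ndarray  # cm
    fit_residual_map: np.ndarray  # RMS log-domain residual
    valid_mask: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.alpha_map.shape


class QuadraticCalibrator(BaseEstimator):
    """Least-squares per-pixel fit of the quadratic attenuation model.

    Follows the scikit-learn estimator protocol: ``fit(X, y)`` takes a stack
    of dark-corrected flood images ``X`` of shape ``(n_images, ny, nx)`` and
    their slab thicknesses ``y`` in cm (one of which must be 0, the open
    field).  Fitted attributes carry the per-pixel maps.

    Parameters
    ----------
    calib_field_area : float
        Area of the flood calibration field at the isocentre plane (cm^2),
        recorded for the downstream scatter correction.

    Attributes
    ----------
    alpha_map_, beta_map_ : ndarray
        Per-pixel coefficients of the attenuation exponent.
    i0_map_ : ndarray
        Open-field signal per pixel.
    fit_residual_map_ : ndarray
        RMS residual of the log-domain fit per pixel.
    valid_mask_ : ndarray of bool
        False where any slab signal or the open field is non-positive, or
        where the fitted alpha is non-positive.
    model_ : CalibrationModel
        The same content bundled for serialization.
    """

    def __init__(self, calib_field_area: float = 26.0 * 26.0):
        self.calib_field_area = calib_field_area

    def fit(self, X, y):
        """Fit per-pixel (alpha, beta) from a dark-corrected flood series.

        Parameters
        ----------
        X : ndarray (n_images, ny, nx) or list of PortalImage
            Dark-corrected flood images, one per thickness.
        y : array-like of float
            Slab thicknesses in cm; must contain 0 (the open field) and at
            least two further distinct values.
        """
        if isinstance(X, (list, tuple)) and X and isinstance(X[0], PortalImage):
            for img in X:
                if not img.is_dark_corrected:
                    raise ValueError("calibration images must be dark-corrected")
            X = np.stack([img.pixels for img in X])
        X = np.asarray(X, dtype=float)
        t = np.asarray(y, dtype=float)
        if X.ndim != 3 or X.shape[0] != t.shape[0]:
            raise ValueError("X must be (n_images, ny, nx) matching len(y)")
        if len(np.unique(t)) != len(t):
            raise ValueError("thicknesses must be distinct")
        if 0.0 not in t:
            raise ValueError("the series must include the open field (t = 0)")
        t_pos = t[t > 0]
        if t_pos.size < 2:
            raise ValueError(
                "underdetermined fit: need >= 2 positive thicknesses "
                "besides the open field"
            )

        open_idx = np.flatnonzero(t == 0.0)
        i0 = X[open_idx].mean(axis=0)
        slabs = X[t > 0]

        with np.errstate(divide="ignore", invalid="ignore"):
            Y = -np.log(slabs / i0)  # (n_pos, ny, nx)
        bad = (slabs <= 0).any(axis=0) | (i0 <= 0)
        Y = np.where(np.isfinite(Y), Y, 0.0)

        # shared design matrix [t, t^2]: one pseudo-inverse serves all pixels
        A = np.column_stack([t_pos, t_pos**2])
        if np.linalg.matrix_rank(A) < 2:
            raise ValueError("rank-deficient design: thicknesses degenerate")
        coef = np.linalg.pinv(A) @ Y.reshape(len(t_pos), -1)
        alpha = coef[0].reshape(i0.shape)
        beta = coef[1].reshape(i0.shape)
        resid = A @ coef - Y.reshape(len(t_pos), -1)
        rms = np.sqrt(np.mean(resid**2, axis=0)).reshape(i0.shape)

        self.alpha_map_ = alpha
        self.beta_map_ = beta
        self.i0_map_ = i0
        self.fit_residual_map_ = rms
        self.valid_mask_ = ~bad & (alpha > 0) & (i0 > 0)
        self.thicknesses_ = np.sort(t)
        self.model_ = CalibrationModel(
            alpha_map=alpha,
            beta_map=beta,
            i0_map=i0,
            calib_field_area=float(self.calib_field_area),
            thicknesses=np.sort(t),
            fit_residual_map=rms,
            valid_mask=self.valid_mask_,
        )
        return self

    @classmethod
    def from_series(cls, series: CalibrationSeries,
                    calib_field_area: float | None = None) -> "QuadraticCalibrator":
        """Dark-correct a synthetic calibration series and fit it."""
        imgs = [dark_correct(img, series.dark) for img in series.images]
        if calib_field_area is None:
            calib_field_area = imgs[0].meta.get("field_area", 26.0 * 26.0)
        est = cls(calib_field_area=calib_field_area)
        return est.fit(imgs, series.thicknesses)


def fit_quadratic(images, thicknesses, calib_field_area: float = 676.0) -> CalibrationModel:
    """Functional wrapper over :class:`QuadraticCalibrator`.

    ``images`` is a stack or list of dark-corrected flood images;
    ``thicknesses`` the matching slab thicknesses in cm (0 = open field).
    """
    est = QuadraticCalibrator(calib_field_area=calib_field_area)
    est.fit(images, thicknesses)
    return est.model_
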