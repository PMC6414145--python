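"""Radiation-field segmentation and region-of-interest handling.

The radiation field is segmented by thresholding at a fraction of the
robust image maximum, keeping the largest connected component, and tracing
its boundary with a Moore-neighbourhood chain-code walk (8-connectivity,
Freeman direction codes).  The "breast" region of interest is a polygon —
either supplied as vertices (the stand-in for a manual contour) or
projected from the synthetic phantom outline — filled by an even-odd
scanline rule with pixel-centre inclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon
from skimage import measure

from .simulate import PortalImage

__all__ = [
    "NoFieldDetected",
    "FieldMask",
    "RoiPolygon",
    "field_mask",
    "trace_boundary",
    "fill_polygon",
    "roi_from_outline_cm",
]


class NoFieldDetected(RuntimeError):
    """Raised when thresholding finds no field pixels."""


#: Freeman 8-direction codes, clockwise from east, as (drow, dcol) steps.
#: Rows increase downwards, so code 1 (north-east on screen) is (-1, +1).
FREEMAN_STEPS: tuple[tuple[int, int], ...] = (
    (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)
)
_STEP_TO_CODE = {s: c for c, s in enumerate(FREEMAN_STEPS)}


@dataclass
class FieldMask:
    """Binary field mask with its chain-coded boundary.

    ``boundary_chain`` is the ordered list of boundary pixels (row, col);
    ``chain_codes[i]`` is the Freeman code of the step from pixel i to
    pixel i+1, the last code closing the loop back to the start, so the
    chain length equals the number of boundary pixels.
    """

    mask: np.ndarray
    boundary_chain: list[tuple[int, int]]
    chain_codes: list[int]
    threshold_used: float

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class RoiPolygon:
    """A closed polygon ROI and its filled pixel mask."""

    vertices: np.ndarray  # (N, 2) of (x_px, y_px), closed or open
    filled_mask: np.ndarray
    degenerate: bool = False

    @property
    def n_pixels(self) -> int:
        return int(self.filled_mask.sum())


def trace_boundary(mask: np.ndarray) -> tuple[list[tuple[int, int]], list[int]]:
    """Moore-neighbourhood boundary trace of a single connected component.

    Starts from the first mask pixel in raster order and walks the outer
    boundary clockwise, scanning the 8-neighbourhood from the backtrack
    direction (Jacob's stopping criterion).  Returns the ordered boundary
    pixels and the Freeman chain codes linking them (closed: the final code
    steps back to the start pixel).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot trace an empty mask")
    pad = np.zeros((mask.shape[0] + 2, mask.shape[1] + 2), dtype=bool)
    pad[1:-1, 1:-1] = mask

    rs, cs = np.nonzero(pad)
    start = (int(rs[0]), int(cs[0]))  # raster order: west neighbour is outside

    if len(rs) == 1:
        return [(start[0] - 1, start[1] - 1)], []

    # walk states are (pixel, backtrack direction); the start pixel counts as
    # entered "from the west" (raster order guarantees that side is outside).
    # The walk is deterministic on a finite state set, so it must eventually
    # revisit a state; the chain between the two visits is the closed
    # boundary cycle (a variant of Jacob's stopping criterion that is also
    # correct when the boundary passes through the start pixel twice).
    seen: dict[tuple[tuple[int, int], int], int] = {}
    cur, back = start, 4
    chain: list[tuple[int, int]] = []
    while True:
        key = (cur, back)
        if key in seen:
            chain = chain[seen[key]:]
            break
        seen[key] = len(chain)
        chain.append(cur)
        nxt = None
        for k in range(1, 9):  # clockwise scan starting just past backtrack
            d = (back + k) % 8
            nr, nc = cur[0] + FREEMAN_STEPS[d][0], cur[1] + FREEMAN_STEPS[d][1]
            if pad[nr, nc]:
                nxt = (nr, nc)
                step_dir = d
                break
        if nxt is None:  # start pixel isolated within this mask; defensive
            break
        cur, back = nxt, (step_dir + 4) % 8

    unpadded = [(r - 1, c - 1) for r, c in chain]
    codes = []
    for i, (r, c) in enumerate(unpadded):
        r2, c2 = unpadded[(i + 1) % len(unpadded)]
        codes.append(_STEP_TO_CODE[(r2 - r, c2 - c)])
    return unpadded, codes


def field_mask(image, threshold_frac: float = 0.5) -> FieldMask:
    """Threshold the image into a radiation-field mask and trace its edge.

    The threshold is ``threshold_frac`` times the robust maximum (99th
    percentile); pixels exactly at the threshold are included.  Only the
    largest 8-connected component is kept.

    Raises
    ------
    NoFieldDetected
        If no pixel reaches the threshold.
    """
    if isinstance(image, PortalImage):
        image = image.pixels
    img = np.asarray(image, dtype=float)
    robust_max = float(np.percentile(img, 99.0))
    if robust_max <= 0:
        raise NoFieldDetected("image has no positive signal")
    thr = threshold_frac * robust_max
    mask = img >= thr
    if not mask.any():
        raise NoFieldDetected(f"no pixels at or above threshold {thr:.4g}")
    labels = measure.label(mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == int(np.argmax(counts))
    chain, codes = trace_boundary(mask)
    return FieldMask(mask=mask, boundary_chain=chain, chain_codes=codes,
                     threshold_used=thr)


def _on_edge_pixels(vertices: np.ndarray, grid_shape, eps: float = 1e-9) -> np.ndarray:
    """Boolean mask of pixel centres lying exactly on a polygon edge."""
    ny, nx = grid_shape
    out = np.zeros((ny, nx), dtype=bool)
    v = vertices
    for i in range(len(v) - 1):
        (x1, y1), (x2, y2) = v[i], v[i + 1]
        lo_x, hi_x = sorted((x1, x2))
        lo_y, hi_y = sorted((y1, y2))
        cs = np.arange(max(0, int(np.ceil(lo_x - eps))),
                       min(nx - 1, int(np.floor(hi_x + eps))) + 1)
        rs = np.arange(max(0, int(np.ceil(lo_y - eps))),
                       min(ny - 1, int(np.floor(hi_y + eps))) + 1)
        if cs.size == 0 or rs.size == 0:
            continue
        C, R = np.meshgrid(cs, rs)
        # collinearity + within segment bbox
        cross = (x2 - x1) * (R - y1) - (y2 - y1) * (C - x1)
        seg_len = np.hypot(x2 - x1, y2 - y1)
        if seg_len < eps:
            continue
        on = np.abs(cross) / seg_len <= eps
        out[R[on], C[on]] = True
    return out


def fill_polygon(vertices, grid_shape) -> RoiPolygon:
    """Fill a polygon on a pixel grid (even-odd scanline, centre inclusion).

    ``vertices`` are (x_px, y_px) pixel coordinates (x = column, y = row);
    the polygon is closed automatically.  A pixel belongs to the ROI when
    its centre is inside under the even-odd rule or lies exactly on an
    edge.  Zero-area (collinear) polygons yield the degenerate on-edge fill
    with ``degenerate=True``; self-intersecting polygons are rejected.
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
        raise ValueError("need at least 3 (x, y) vertices")
    if not np.allclose(v[0], v[-1]):
        v = np.vstack([v, v[0]])
    ny, nx = grid_shape

    area2 = float(np.sum(v[:-1, 0] * v[1:, 1] - v[1:, 0] * v[:-1, 1]))
    if abs(area2) < 1e-12:
        # zero signed area: either all vertices collinear (degenerate, fill
        # reduces to the on-edge pixels) or the ring folds back on itself
        d0 = v[1] - v[0]
        cross = (v[:-1, 0] - v[0, 0]) * d0[1] - (v[:-1, 1] - v[0, 1]) * d0[0]
        if np.all(np.abs(cross) < 1e-9):
            return RoiPolygon(vertices=v,
                              filled_mask=_on_edge_pixels(v, grid_shape),
                              degenerate=True)
        raise ValueError("polygon is self-intersecting (not simple)")

    poly = _ShapelyPolygon(v)
    if not poly.is_valid:
        raise ValueError("polygon is self-intersecting (not simple)")

    filled = np.zeros((ny, nx), dtype=bool)
    xs1, ys1 = v[:-1, 0], v[:-1, 1]
    xs2, ys2 = v[1:, 0], v[1:, 1]
    for j in range(ny):
        yj = float(j)
        ymin = np.minimum(ys1, ys2)
        ymax = np.maximum(ys1, ys2)
        hit = (ymin <= yj) & (yj < ymax)  # half-open rule handles vertices
        if not hit.any():
            continue
        xh = xs1[hit] + (yj - ys1[hit]) * (xs2[hit] - xs1[hit]) / (ys2[hit] - ys1[hit])
        xh = np.sort(xh)
        for a, b in zip(xh[0::2], xh[1::2]):
            c0 = max(0, int(np.ceil(a - 1e-9)))
            c1 = min(nx - 1, int(np.floor(b + 1e-9)))
            if c1 >= c0:
                filled[j, c0:c1 + 1] = True
    filled |= _on_edge_pixels(v, grid_shape)
    return RoiPolygon(vertices=v, filled_mask=filled, degenerate=False)


def roi_from_outline_cm(outline_cm, pixel_pitch: float, grid_shape) -> RoiPolygon:
    """Project a phantom outline given in cm into pixel coordinates and fill.

    The cm coordinate system is centred on the grid centre (as produced by
    the simulator); x maps to columns, y to rows.
    """
    outline_cm = np.asarray(outline_cm, dtype=float)
    ny, nx = grid_shape
    col = outline_cm[:, 0] / pixel_pitch + (nx - 1) / 2.0
    row = outline_cm[:, 1] / pixel_pitch + (ny - 1) / 2.0
    return fill_polygon(np.column_stack([col, row]), grid_shape)
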