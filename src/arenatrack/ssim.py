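"""Incremental SSIM difference images, thresholding, and per-ROI detections.

The structural similarity index (SSIM) compares two images through local
windowed statistics: means mu_x, mu_y, second moments mu_xx, mu_yy, and the
cross moment mu_xy.  Here one of the images is always the static background,
so its statistics (mu_y, mu_yy) are computed once and cached in an
:class:`SsimContext`; each incoming frame then costs only three box filters
(mu_x, mu_xx, mu_xy).  The caching is a pure speedup — the result is
identical to recomputing all five statistics per frame.

The per-pixel similarity

    S = (2 mu_x mu_y + C1)(2 sigma_xy + C2)
        / ((mu_x^2 + mu_y^2 + C1)(sigma_x^2 + sigma_y^2 + C2))

is mapped to a dissimilarity ("difference image") D = clip((1 - S)/2, 0, 1),
so identical regions score 0 and maximally dissimilar ones 1.  Thresholding D
and extracting connected components inside each ROI yields at most one animal
detection per arena.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.draw import polygon2mask

from .roi import PolygonRoi, RoiSet


class SsimError(ValueError):
    pass


@dataclass(frozen=True)
class SsimParams:
    """SSIM window size and stabilization constants.

    Defaults follow the common convention for 8-bit images: a 7x7 uniform
    window, K1=0.01, K2=0.03, dynamic range L=255, giving C1=(K1 L)^2 and
    C2=(K2 L)^2.
    """

    win_size: int = 7
    k1: float = 0.01
    k2: float = 0.03
    data_range: float = 255.0

    def __post_init__(self) -> None:
        if self.win_size < 3 or self.win_size % 2 == 0:
            raise SsimError(f"win_size must be odd and >= 3, got {self.win_size}")
        if self.k1 <= 0 or self.k2 <= 0 or self.data_range <= 0:
            raise SsimError("K1, K2 and data_range must be > 0")

    @property
    def c1(self) -> float:
        return (self.k1 * self.data_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.data_range) ** 2


def _box(img: np.ndarray, win: int) -> np.ndarray:
    # reflective padding keeps the map at full frame shape
    return ndimage.uniform_filter(img, size=win, mode="reflect")


@dataclass
class SsimContext:
    """Cached background statistics for incremental SSIM."""

    params: SsimParams
    background: np.ndarray  # float64 copy of the background image
    mu_y: np.ndarray
    mu_yy: np.ndarray

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.background.shape

    def variance_y(self) -> np.ndarray:
        return self.mu_yy - self.mu_y**2


def build_context(background: np.ndarray, params: SsimParams = SsimParams()) -> SsimContext:
    """Precompute the background's local mean and second moment."""
    bg = np.asarray(background, dtype=np.float64)
    if bg.ndim != 2:
        raise SsimError("background must be a 2-D grayscale image")
    if params.win_size > min(bg.shape):
        raise SsimError(
            f"win_size {params.win_size} exceeds image dimension {min(bg.shape)}"
        )
    mu_y = _box(bg, params.win_size)
    mu_yy = _box(bg * bg, params.win_size)
    return SsimContext(params, bg, mu_y, mu_yy)


@dataclass
class DifferenceImage:
    """Per-pixel dissimilarity in [0, 1]; high values mark the moving animal."""

    values: np.ndarray
    frame_index: int = 0


def ssim_difference(
    frame: np.ndarray, ctx: SsimContext, frame_index: int = 0
) -> DifferenceImage:
    """SSIM dissimilarity of ``frame`` against the cached background.

    Only mu_x, mu_xx and mu_xy are computed here; mu_y and mu_yy come from
    the context.
    """
    x = np.asarray(frame, dtype=np.float64)
    if x.shape != ctx.frame_shape:
        raise SsimError(f"frame shape {x.shape} != context shape {ctx.frame_shape}")
    win = ctx.params.win_size
    c1, c2 = ctx.params.c1, ctx.params.c2
    mu_x = _box(x, win)
    mu_xx = _box(x * x, win)
    mu_xy = _box(x * ctx.background, win)
    var_x = mu_xx - mu_x**2
    var_y = ctx.mu_yy - ctx.mu_y**2
    cov = mu_xy - mu_x * ctx.mu_y
    s = ((2 * mu_x * ctx.mu_y + c1) * (2 * cov + c2)) / (
        (mu_x**2 + ctx.mu_y**2 + c1) * (var_x + var_y + c2)
    )
    return DifferenceImage(np.clip((1.0 - s) / 2.0, 0.0, 1.0), frame_index)


@dataclass
class Detection:
    roi_id: str
    centroid: tuple[float, float]  # (x, y) px
    area: float  # px^2
    frame_index: int
    confident: bool = True


class RasterizedRois:
    """Per-ROI boolean masks and bounding slices, rasterized once.

    Rasterizing polygons is the slow part of per-frame segmentation, so it is
    hoisted out of the loop.
    """

    def __init__(self, roi_set: RoiSet, frame_shape: tuple[int, int]):
        self.roi_set = roi_set
        self.frame_shape = frame_shape
        self.masks: dict[str, tuple[tuple[slice, slice], np.ndarray]] = {}
        h, w = frame_shape
        for roi in roi_set:
            x0, y0, x1, y1 = roi.bounds
            r0 = max(int(np.floor(y0)), 0)
            r1 = min(int(np.ceil(y1)) + 1, h)
            c0 = max(int(np.floor(x0)), 0)
            c1 = min(int(np.ceil(x1)) + 1, w)
            sl = (slice(r0, r1), slice(c0, c1))
            local = roi.vertices[:, ::-1] - np.array([r0, c0])  # (row, col)
            mask = polygon2mask((r1 - r0, c1 - c0), local)
            self.masks[roi.id] = (sl, mask)

    def mask_area(self, roi_id: str) -> int:
        return int(self.masks[roi_id][1].sum())


def segment(
    diff: DifferenceImage,
    roi_set: RoiSet,
    threshold: float = 0.35,
    min_area: float = 4.0,
    max_area: Optional[float] = None,
    max_area_frac: float = 0.25,
    rasters: Optional[RasterizedRois] = None,
) -> list[Detection]:
    """Threshold the difference image and extract one detection per ROI.

    Within each ROI independently, connected components of ``diff >=
    threshold`` with area in [min_area, max_area] are candidate animals; the
    largest passer becomes that ROI's (single) confident Detection, with an
    intensity-weighted centroid on the difference values.  ROIs with no
    passing component yield no detection.  ``max_area`` defaults to
    ``max_area_frac`` of each ROI's pixel area.
    """
    if not 0.0 < threshold < 1.0:
        raise SsimError("threshold must lie in (0, 1)")
    vals = diff.values
    if rasters is None or rasters.roi_set is not roi_set:
        rasters = RasterizedRois(roi_set, vals.shape)
    binary = vals >= threshold
    detections: list[Detection] = []
    for roi in roi_set:
        sl, mask = rasters.masks[roi.id]
        sub = binary[sl] & mask
        if not sub.any():
            continue
        labels, n = ndimage.label(sub)
        if n == 0:
            continue
        areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        cap = max_area if max_area is not None else max_area_frac * rasters.mask_area(roi.id)
        passing = [
            (a, i + 1) for i, a in enumerate(areas) if min_area <= a <= cap
        ]
        if not passing:
            continue
        area, lab = max(passing)
        comp = labels == lab
        weights = vals[sl] * comp
        total = weights.sum()
        rows, cols = np.nonzero(comp)
        cy = (rows * weights[rows, cols]).sum() / total
        cx = (cols * weights[rows, cols]).sum() / total
        detections.append(
            Detection(
                roi.id,
                (cx + sl[1].start, cy + sl[0].start),
                float(area),
                diff.frame_index,
            )
        )
    return detections


def dpix(
    frame: np.ndarray,
    prev_frame: np.ndarray,
    roi: Optional[PolygonRoi] = None,
    intensity_threshold: int = 10,
    mask: Optional[np.ndarray] = None,
) -> int:
    """Delta-pixel count: pixels inside the ROI whose intensity changed by
    strictly more than ``intensity_threshold`` between consecutive frames.

    ``mask`` (full-frame boolean) may be passed instead of rasterizing
    ``roi`` per call.
    """
    frame = np.asarray(frame)
    prev_frame = np.asarray(prev_frame)
    if frame.shape != prev_frame.shape:
        raise SsimError("consecutive frames must have identical shapes")
    delta = np.abs(frame.astype(np.int16) - prev_frame.astype(np.int16))
    changed = delta > intensity_threshold
    if mask is not None:
        changed = changed & mask
    elif roi is not None:
        m = polygon2mask(frame.shape, roi.vertices[:, ::-1])
        changed = changed & m
    return int(changed.sum())
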