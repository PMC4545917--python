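"""Ductal segmentation: from a raw field to wall/lumen geometry in a ROI.

The pipeline mirrors the standard duct workup for proflavine-stained
confocal fields: adaptive Wiener denoising, contrast-limited adaptive
histogram equalization, intensity thresholding (per-site, user-chosen in
the original interactive workflow; 107 is the cohort mean), removal of
objects below the nuclear size ceiling (500 px) so isolated nuclei outside
duct walls drop out, clipping to a polygon ROI around the duct, and finally
hole filling and lumen extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Polygon
from skimage import exposure

from .calibration import CalibratedImage
from .io import PolygonROI

__all__ = [
    "DuctSegParams",
    "DuctGeometry",
    "DuctSegmentationError",
    "wiener_denoise",
    "clahe",
    "binarize",
    "remove_small_objects",
    "clip_to_roi",
    "extract_duct_geometry",
    "segment_duct",
]

_STRUCT4 = ndimage.generate_binary_structure(2, 1)
_STRUCT8 = np.ones((3, 3), dtype=bool)


class DuctSegmentationError(ValueError):
    """No usable duct wall found within the ROI."""


@dataclass(frozen=True)
class DuctSegParams:
    wiener_window: int = 5
    clahe_tiles: tuple[int, int] = (8, 8)
    clahe_clip: float = 0.01
    threshold: int = 107          # cohort-mean binarization threshold
    min_object_area: int = 500    # nuclear size ceiling, px
    min_lumen_area: int = 35      # speckle-hole floor, px

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= 255:
            raise ValueError("threshold must lie in [0, 255]")
        if self.wiener_window < 3 or self.wiener_window % 2 == 0:
            raise ValueError("wiener_window must be odd and >= 3")
        if self.min_object_area < 1 or self.min_lumen_area < 1:
            raise ValueError("areas must be >= 1")


@dataclass
class DuctGeometry:
    """Wall/lumen geometry of one duct, in pixel units.

    ``filled_mask`` is the wall with enclosed holes filled; ``lumen_labels``
    labels the holes of at least ``min_lumen_area`` px; boundaries are the
    8-connected contour pixel sets of the filled region (outer) and of the
    lumens (inner), as (N, 2) row/col arrays.
    """

    wall_mask: np.ndarray
    filled_mask: np.ndarray
    lumen_labels: np.ndarray
    outer_boundary: np.ndarray = field(default=None)  # type: ignore[assignment]
    inner_boundary: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.outer_boundary is None:
            self.outer_boundary = _contour_pixels(self.filled_mask)
        if self.inner_boundary is None:
            self.inner_boundary = _contour_pixels(self.lumen_labels > 0)

    @property
    def n_lumens(self) -> int:
        return int(self.lumen_labels.max())


def _contour_pixels(mask: np.ndarray) -> np.ndarray:
    """Mask pixels with a 4-neighbor (or raster edge) outside the mask.

    4-adjacency to the background yields the thin, 8-connected contour
    curve; using the full 8-neighborhood would double the contour on
    diagonals and bias boundary-to-boundary distances.
    """
    mask = np.asarray(mask, dtype=bool)
    interior = ndimage.binary_erosion(mask, structure=_STRUCT4, border_value=0)
    return np.argwhere(mask & ~interior)


def wiener_denoise(image: CalibratedImage, window: int = 5) -> CalibratedImage:
    """Adaptive local Wiener estimate on a ``window x window`` neighborhood.

    Each pixel is shrunk toward its local mean in proportion to the local
    excess variance over the image-wide noise floor (the mean of the local
    variances); output is clipped back to [0, 255].
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if min(image.shape) < window:
        raise ValueError("window larger than image")
    x = image.pixels.astype(float)
    mu = ndimage.uniform_filter(x, window, mode="reflect")
    var = np.maximum(ndimage.uniform_filter(x * x, window, mode="reflect") - mu * mu, 0.0)
    noise = var.mean()
    denom = np.maximum(var, noise)
    gain = np.divide(
        np.maximum(var - noise, 0.0), denom,
        out=np.zeros_like(var), where=denom > 0,
    )
    out = mu + gain * (x - mu)
    out = np.clip(np.round(out), 0, 255).astype(np.uint8)
    return CalibratedImage(out, image.calibration, image.site_id)


def clahe(
    image: CalibratedImage,
    tiles: tuple[int, int] = (8, 8),
    clip: float = 0.01,
) -> CalibratedImage:
    """Contrast-limited adaptive histogram equalization on the 0-255 scale."""
    H, W = image.shape
    kernel = (max(H // tiles[0], 1), max(W // tiles[1], 1))
    if np.ptp(image.pixels) == 0:
        return CalibratedImage(image.pixels.copy(), image.calibration, image.site_id)
    eq = exposure.equalize_adapthist(
        image.pixels, kernel_size=kernel, clip_limit=clip, nbins=256
    )
    out = np.clip(np.round(eq * 255.0), 0, 255).astype(np.uint8)
    return CalibratedImage(out, image.calibration, image.site_id)


def binarize(image: CalibratedImage, threshold: int) -> np.ndarray:
    """Foreground where intensity >= threshold."""
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    return image.pixels >= threshold


def remove_small_objects(mask: np.ndarray, min_object_area: int) -> np.ndarray:
    """Delete 8-connected components with area strictly below the cutoff."""
    mask = np.asarray(mask, dtype=bool)
    lab, n = ndimage.label(mask, structure=_STRUCT8)
    if n == 0:
        return mask.copy()
    keep = np.bincount(lab.ravel(), minlength=n + 1) >= min_object_area
    keep[0] = False
    return keep[lab]


def roi_raster_mask(roi: PolygonROI, shape: tuple[int, int]) -> np.ndarray:
    """Pixels whose centers fall inside or on the ROI polygon."""
    poly = Polygon(roi.vertices)
    if not poly.is_valid or poly.area == 0:
        raise ValueError("degenerate ROI polygon")
    H, W = shape
    minx, miny, maxx, maxy = poly.bounds
    c0, c1 = max(int(np.floor(minx)), 0), min(int(np.ceil(maxx)) + 1, W)
    r0, r1 = max(int(np.floor(miny)), 0), min(int(np.ceil(maxy)) + 1, H)
    out = np.zeros(shape, dtype=bool)
    if c0 >= c1 or r0 >= r1:
        return out
    cc, rr = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    inside = shapely.intersects_xy(poly, cc.ravel(), rr.ravel())
    out[r0:r1, c0:c1] = inside.reshape(rr.shape)
    return out


def clip_to_roi(mask: np.ndarray, roi: PolygonROI) -> np.ndarray:
    """Zero all mask pixels whose centers fall outside the ROI polygon."""
    return np.asarray(mask, dtype=bool) & roi_raster_mask(roi, mask.shape)


def extract_duct_geometry(
    wall_mask: np.ndarray,
    roi: PolygonROI,
    min_lumen_area: int = 35,
) -> DuctGeometry:
    """Fill enclosed holes of the wall and label the lumens.

    Holes are background components (4-connected) enclosed by the wall
    within the ROI-clipped raster: background touching the ROI border (or
    the raster edge) is exterior.  Holes of at least ``min_lumen_area`` px
    become lumens; smaller speckle holes are filled but not counted.
    """
    wall = np.asarray(wall_mask, dtype=bool)
    region = roi_raster_mask(roi, wall.shape)
    wall = wall & region
    if not wall.any():
        raise DuctSegmentationError("no duct wall within ROI")

    background = region & ~wall
    lab_bg, _ = ndimage.label(background, structure=_STRUCT4)
    exterior = ~region
    touch_ext = ndimage.binary_dilation(exterior, structure=_STRUCT4) & background
    border = np.zeros_like(wall)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    touch_ext |= border & background
    exterior_labels = np.unique(lab_bg[touch_ext])
    is_hole = np.ones(lab_bg.max() + 1, dtype=bool)
    is_hole[0] = False
    is_hole[exterior_labels] = False

    holes = is_hole[lab_bg]
    filled = wall | holes

    areas = np.bincount(lab_bg.ravel(), minlength=lab_bg.max() + 1)
    keep = is_hole & (areas >= min_lumen_area)
    lumen_mask = keep[lab_bg]
    lumen_labels, _ = ndimage.label(lumen_mask, structure=_STRUCT4)
    return DuctGeometry(
        wall_mask=wall,
        filled_mask=filled,
        lumen_labels=lumen_labels.astype(np.int32),
    )


def segment_duct(
    image: CalibratedImage,
    params: DuctSegParams | None = None,
    roi: PolygonROI | None = None,
) -> DuctGeometry:
    """Full ductal segmentation of one field within a polygon ROI."""
    params = params or DuctSegParams()
    if roi is None:
        H, W = image.shape
        roi = PolygonROI(((0, 0), (W - 1, 0), (W - 1, H - 1), (0, H - 1)))
    den = wiener_denoise(image, params.wiener_window)
    eq = clahe(den, params.clahe_tiles, params.clahe_clip)
    mask = binarize(eq, params.threshold)
    mask = remove_small_objects(mask, params.min_object_area)
    mask = clip_to_roi(mask, roi)
    if not mask.any():
        raise DuctSegmentationError("no duct wall after filtering")
    return extract_duct_geometry(mask, roi, params.min_lumen_area)
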