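"""Ductal morphometry: the 19 ductal features of one segmented duct.

Wall width is sampled at every pixel of the outer boundary as the Euclidean
distance to the nearest inner (lumen) boundary pixel, via a distance
transform.  Ellipse fits are moment ellipses; axes are reported as full
lengths.  When a duct has several lumens the lumen areas are summed while
lumen shape descriptors (axes, eccentricity, solidity, ellipse area) are
measured on the largest lumen.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .calibration import PixelCalibration
from .ductseg import DuctGeometry
from .moments import EllipseFit, fit_region_ellipse, solidity
from .nuclear import _SUMMARY_FIELDS, summarize

__all__ = [
    "DUCT_FEATURE_NAMES",
    "count_lumens",
    "wall_width_profile",
    "fit_region_ellipse",
    "solidity",
    "duct_feature_vector",
]

DUCT_FEATURE_NAMES: tuple[str, ...] = (
    *(f"{s}_wall_width" for s in _SUMMARY_FIELDS),
    "n_lumens",
    "wall_area",
    "lumen_area",
    "outer_ellipse_area",
    "lumen_ellipse_area",
    "duct_major",
    "duct_minor",
    "lumen_major",
    "lumen_minor",
    "duct_solidity",
    "lumen_solidity",
    "duct_eccentricity",
    "lumen_eccentricity",
)


def count_lumens(geometry: DuctGeometry) -> int:
    """Number of segmented lumens (enclosed holes above the speckle floor)."""
    return geometry.n_lumens


def wall_width_profile(
    geometry: DuctGeometry, calib: PixelCalibration
) -> np.ndarray:
    """Wall width (um) at every outer-boundary pixel.

    Width is the Euclidean distance to the nearest inner-boundary pixel of
    any lumen; undefined (error) when the duct has no lumen.
    """
    if geometry.n_lumens == 0:
        raise ValueError("wall width undefined without a lumen")
    inner = np.zeros(geometry.wall_mask.shape, dtype=bool)
    inner[geometry.inner_boundary[:, 0], geometry.inner_boundary[:, 1]] = True
    dist = ndimage.distance_transform_edt(~inner)
    outer = geometry.outer_boundary
    return dist[outer[:, 0], outer[:, 1]] * calib.pitch_um


def _largest_lumen_mask(geometry: DuctGeometry) -> np.ndarray:
    areas = np.bincount(geometry.lumen_labels.ravel())
    areas[0] = 0
    return geometry.lumen_labels == int(np.argmax(areas))


def duct_feature_vector(
    geometry: DuctGeometry, calib: PixelCalibration
) -> dict[str, float]:
    """The 19 ductal features, in physical units.

    Lumen-derived entries are NaN when the duct has no lumen (``n_lumens``
    is still reported, as 0).
    """
    p = calib.pitch_um
    p2 = calib.pixel_area_um2
    out: dict[str, float] = {}

    n_lumens = geometry.n_lumens
    if n_lumens > 0:
        out.update(summarize(wall_width_profile(geometry, calib)).as_dict("wall_width"))
    else:
        out.update({f"{s}_wall_width": float("nan") for s in _SUMMARY_FIELDS})
    out["n_lumens"] = float(n_lumens)
    out["wall_area"] = float(np.count_nonzero(geometry.wall_mask)) * p2
    out["lumen_area"] = float(np.count_nonzero(geometry.lumen_labels)) * p2

    duct_fit: EllipseFit = fit_region_ellipse(geometry.filled_mask)
    out["outer_ellipse_area"] = duct_fit.ellipse_area * p2
    out["duct_major"] = duct_fit.major_axis * p
    out["duct_minor"] = duct_fit.minor_axis * p
    out["duct_eccentricity"] = duct_fit.eccentricity
    out["duct_solidity"] = solidity(geometry.filled_mask)

    if n_lumens > 0:
        lumen = _largest_lumen_mask(geometry)
        lumen_fit = fit_region_ellipse(lumen)
        out["lumen_ellipse_area"] = lumen_fit.ellipse_area * p2
        out["lumen_major"] = lumen_fit.major_axis * p
        out["lumen_minor"] = lumen_fit.minor_axis * p
        out["lumen_eccentricity"] = lumen_fit.eccentricity
        out["lumen_solidity"] = solidity(lumen)
    else:
        for k in (
            "lumen_ellipse_area",
            "lumen_major",
            "lumen_minor",
            "lumen_eccentricity",
            "lumen_solidity",
        ):
            out[k] = float("nan")
    return {k: out[k] for k in DUCT_FEATURE_NAMES}
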