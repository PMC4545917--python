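"""Region shape descriptors from pixel second moments.

Axis lengths use the moment-ellipse convention in which every pixel
contributes as a unit square (a +1/12 term on the diagonal of the central
second-moment matrix), so a single pixel has axis length 4*sqrt(1/12) ~
1.155 and a 1 x k run of pixels behaves like a continuous segment of
length k.  Solidity uses the exact convex-hull polygon of the pixel
squares' corners, so convex rasters (rectangles) score exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np
from scipy.spatial import ConvexHull, QhullError


@dataclass(frozen=True)
class EllipseFit:
    """Moment ellipse of a pixel region (axes are full lengths, px)."""

    major_axis: float
    minor_axis: float
    eccentricity: float
    ellipse_area: float
    centroid: tuple[float, float]
    orientation: float  # radians, major axis vs row direction

    @classmethod
    def from_coords(cls, coords: np.ndarray) -> "EllipseFit":
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 2 or coords.shape[0] == 0:
            raise ValueError("ellipse fit requires a non-empty (N, 2) pixel set")
        n = coords.shape[0]
        c = coords.mean(axis=0)
        d = coords - c
        cov = d.T @ d / n + np.eye(2) / 12.0
        evals, evecs = np.linalg.eigh(cov)  # ascending
        minor = 4.0 * math.sqrt(max(evals[0], 0.0))
        major = 4.0 * math.sqrt(max(evals[1], 0.0))
        ecc = math.sqrt(1.0 - (minor / major) ** 2) if major > 0 else 0.0
        v = evecs[:, 1]
        return cls(
            major_axis=major,
            minor_axis=minor,
            eccentricity=ecc,
            ellipse_area=math.pi * major * minor / 4.0,
            centroid=(float(c[0]), float(c[1])),
            orientation=float(math.atan2(v[1], v[0])),
        )

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "EllipseFit":
        return cls.from_coords(np.argwhere(np.asarray(mask, dtype=bool)))


def fit_region_ellipse(mask: np.ndarray) -> EllipseFit:
    """Moment ellipse sharing the region's normalized second central moments."""
    return EllipseFit.from_mask(mask)


def solidity(mask: np.ndarray) -> float:
    """Region area divided by the exact convex-hull area of its pixel squares."""
    coords = np.argwhere(np.asarray(mask, dtype=bool))
    if coords.shape[0] == 0:
        raise ValueError("solidity of an empty region is undefined")
    offsets = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
    corners = (coords[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
    try:
        hull_area = ConvexHull(corners).volume  # 2-D "volume" is the area
    except QhullError as exc:  # degenerate (collinear) input cannot occur
        raise ValueError(f"convex hull failed: {exc}") from exc
    return float(coords.shape[0] / hull_area)
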