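"""Nuclear morphometry: per-nucleus geometry and the 14 nuclear features.

From a labeled nucleus mask the module measures nuclear density (nuclei per
mm^2), area fraction, the inter-nuclear distance vector (IND: distance from
each nucleus centroid to its nearest other centroid, um) and the nuclear
diameter vector (moment-ellipse major axis per nucleus, um), and summarises
the two vectors with six statistics each: mean, median, mode, interquartile
range, standard deviation and range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .calibration import CalibratedImage, PixelCalibration
from .mser import MSERParams, detect_mser, regions_to_label_mask

__all__ = [
    "NucleusLabelMask",
    "SummaryStats",
    "NUCLEAR_FEATURE_NAMES",
    "nuclear_density",
    "area_fraction",
    "min_internuclear_distances",
    "nuclear_diameters",
    "summarize",
    "nuclear_feature_vector",
    "segment_nuclei",
]

_SUMMARY_FIELDS = ("mean", "median", "mode", "iqr", "std", "range")

NUCLEAR_FEATURE_NAMES: tuple[str, ...] = (
    "nuclear_density",
    "area_fraction",
    *(f"{s}_ind" for s in _SUMMARY_FIELDS),
    *(f"{s}_diameter" for s in _SUMMARY_FIELDS),
)


@dataclass
class NucleusLabelMask:
    """Labeled nucleus raster with cached per-label geometry (pixel units)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("label mask must be 2-D")
        self.labels = lab.astype(np.int64)

    @property
    def n_nuclei(self) -> int:
        return int(self.labels.max())

    @property
    def centroids_px(self) -> np.ndarray:
        """(n, 2) array of (row, col) centroids."""
        n = self.n_nuclei
        if n == 0:
            return np.empty((0, 2))
        return np.asarray(
            ndimage.center_of_mass(
                np.ones_like(self.labels), self.labels, index=range(1, n + 1)
            )
        )

    @property
    def areas_px(self) -> np.ndarray:
        return np.bincount(self.labels.ravel(), minlength=self.n_nuclei + 1)[1:]

    @property
    def major_axes_px(self) -> np.ndarray:
        """Moment-ellipse major-axis length per label (unit-square pixels)."""
        lab = self.labels.ravel()
        n = self.n_nuclei
        if n == 0:
            return np.empty(0)
        H, W = self.labels.shape
        rr = (np.arange(lab.size) // W).astype(float)
        cc = (np.arange(lab.size) % W).astype(float)
        cnt = np.bincount(lab, minlength=n + 1)[1:].astype(float)
        sr = np.bincount(lab, weights=rr, minlength=n + 1)[1:]
        sc = np.bincount(lab, weights=cc, minlength=n + 1)[1:]
        srr = np.bincount(lab, weights=rr * rr, minlength=n + 1)[1:]
        scc = np.bincount(lab, weights=cc * cc, minlength=n + 1)[1:]
        src = np.bincount(lab, weights=rr * cc, minlength=n + 1)[1:]
        mrr = srr / cnt - (sr / cnt) ** 2 + 1.0 / 12.0
        mcc = scc / cnt - (sc / cnt) ** 2 + 1.0 / 12.0
        mrc = src / cnt - (sr / cnt) * (sc / cnt)
        lam = 0.5 * (mrr + mcc) + np.sqrt(0.25 * (mrr - mcc) ** 2 + mrc**2)
        return 4.0 * np.sqrt(np.maximum(lam, 0.0))


@dataclass(frozen=True)
class SummaryStats:
    """Six summary statistics of a measurement vector (vector's units)."""

    mean: float
    median: float
    mode: float
    iqr: float
    std: float
    range: float

    def as_dict(self, suffix: str) -> dict[str, float]:
        return {f"{f}_{suffix}": getattr(self, f) for f in _SUMMARY_FIELDS}


def summarize(values: np.ndarray) -> SummaryStats:
    """Summarise a vector: sample std (n-1), linear-interpolation quartiles,
    mode as the most occupied 1.0-unit bin centred on integers (ties take
    the smallest bin centre)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarise an empty vector")
    q1, q3 = np.percentile(v, [25, 75])
    bins = np.floor(v + 0.5).astype(np.int64)
    uniq, cnt = np.unique(bins, return_counts=True)
    mode = float(uniq[np.argmax(cnt)])  # np.unique sorts: ties -> smallest
    return SummaryStats(
        mean=float(v.mean()),
        median=float(np.median(v)),
        mode=mode,
        iqr=float(q3 - q1),
        std=float(v.std(ddof=1)) if v.size > 1 else 0.0,
        range=float(v.max() - v.min()),
    )


def nuclear_density(mask: NucleusLabelMask, calib: PixelCalibration) -> float:
    """Number of nuclei per mm^2 of imaged area."""
    area_mm2 = mask.labels.size * calib.pixel_area_um2 / 1.0e6
    if area_mm2 == 0:
        raise ValueError("zero-area image")
    return mask.n_nuclei / area_mm2


def area_fraction(mask: NucleusLabelMask) -> float:
    """Total nuclear pixels divided by total pixels."""
    return float(np.count_nonzero(mask.labels) / mask.labels.size)


def min_internuclear_distances(
    mask: NucleusLabelMask, calib: PixelCalibration
) -> np.ndarray:
    """Distance (um) from each nucleus centroid to the nearest other centroid."""
    cents = mask.centroids_px
    if cents.shape[0] < 2:
        raise ValueError("inter-nuclear distance undefined for < 2 nuclei")
    d, _ = cKDTree(cents).query(cents, k=2)
    return d[:, 1] * calib.pitch_um


def nuclear_diameters(mask: NucleusLabelMask, calib: PixelCalibration) -> np.ndarray:
    """Moment-ellipse major-axis length (um) per nucleus."""
    if mask.n_nuclei == 0:
        raise ValueError("no nuclei in mask")
    return mask.major_axes_px * calib.pitch_um


def segment_nuclei(
    image: CalibratedImage, params: MSERParams | None = None
) -> NucleusLabelMask:
    """MSER detection followed by union/relabeling into a nucleus mask."""
    regions = detect_mser(image, params)
    return NucleusLabelMask(regions_to_label_mask(regions, image.shape))


def nuclear_feature_vector(
    image: CalibratedImage,
    mser_params: MSERParams | None = None,
    mask: NucleusLabelMask | None = None,
) -> dict[str, float]:
    """The 14 nuclear features of one site.

    IND summaries are NaN when fewer than two nuclei are present; diameter
    summaries are NaN when no nucleus is present.  A precomputed ``mask``
    may be passed to skip re-segmentation.
    """
    if mask is None:
        mask = segment_nuclei(image, mser_params)
    calib = image.calibration
    out: dict[str, float] = {
        "nuclear_density": nuclear_density(mask, calib),
        "area_fraction": area_fraction(mask),
    }
    nan = float("nan")
    if mask.n_nuclei >= 2:
        out.update(summarize(min_internuclear_distances(mask, calib)).as_dict("ind"))
    else:
        out.update({f"{s}_ind": nan for s in _SUMMARY_FIELDS})
    if mask.n_nuclei >= 1:
        out.update(summarize(nuclear_diameters(mask, calib)).as_dict("diameter"))
    else:
        out.update({f"{s}_diameter": nan for s in _SUMMARY_FIELDS})
    return out
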