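"""File I/O: images, label masks, polygon ROIs, feature tables, site metadata.

Formats
-------
* images: grayscale TIFF or PNG, 8-bit (deeper images are rejected unless
  ``rescale=True``);
* label masks: 16-bit TIFF;
* ROIs: JSON ``{"polygons": [[[x, y], ...], ...]}`` with 0-based pixel
  coordinates;
* feature tables / site metadata: CSV with canonical column names;
* config: YAML.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml
from shapely.geometry import LinearRing

from .calibration import CalibratedImage, PixelCalibration

__all__ = [
    "DIAGNOSES",
    "DUCT_DIAGNOSES",
    "MALIGNANT_DIAGNOSES",
    "class_label_for",
    "PolygonROI",
    "SiteRecord",
    "ParseError",
    "read_image",
    "write_image",
    "read_label_mask",
    "write_label_mask",
    "read_roi",
    "write_roi",
    "read_feature_table",
    "write_feature_table",
    "read_site_table",
    "write_site_table",
    "load_config",
]

#: the eight histologic phenotypes handled by the pipeline
DIAGNOSES: tuple[str, ...] = (
    "adipose",
    "fibrous",
    "lobules",
    "normal_duct",
    "hyperplastic_duct",
    "dcis",
    "idc",
    "ilc",
)
DUCT_DIAGNOSES: frozenset[str] = frozenset({"normal_duct", "hyperplastic_duct", "dcis"})
MALIGNANT_DIAGNOSES: frozenset[str] = frozenset({"dcis", "idc", "ilc"})


class ParseError(ValueError):
    """Raised when an input file violates the expected schema."""


def class_label_for(diagnosis: str) -> str:
    if diagnosis not in DIAGNOSES:
        raise ParseError(f"unknown diagnosis {diagnosis!r}; expected one of {DIAGNOSES}")
    return "malignant" if diagnosis in MALIGNANT_DIAGNOSES else "benign"


@dataclass(frozen=True)
class PolygonROI:
    """Simple polygon in 0-based (x, y) pixel coordinates, implicitly closed."""

    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ParseError(
                f"polygon ROI needs >= 3 vertices, got {len(self.vertices)}"
            )
        ring = LinearRing(self.vertices)
        if not ring.is_simple or ring.length == 0:
            raise ParseError("polygon ROI must be simple (non-self-intersecting)")

    @property
    def xy(self) -> np.ndarray:
        return np.asarray(self.vertices, dtype=float)


@dataclass(frozen=True)
class SiteRecord:
    """Metadata for one imaged site."""

    site_id: str
    patient_id: str
    diagnosis: str
    duct_threshold: Optional[int] = None

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSES:
            raise ParseError(
                f"site {self.site_id}: unknown diagnosis {self.diagnosis!r}"
            )
        is_duct = self.diagnosis in DUCT_DIAGNOSES
        if is_duct and self.duct_threshold is None:
            raise ParseError(
                f"site {self.site_id}: duct_threshold required for duct diagnosis"
            )
        if not is_duct and self.duct_threshold is not None:
            raise ParseError(
                f"site {self.site_id}: duct_threshold given for non-duct diagnosis"
            )
        if self.duct_threshold is not None and not 0 <= self.duct_threshold <= 255:
            raise ParseError(
                f"site {self.site_id}: duct_threshold {self.duct_threshold} not in [0, 255]"
            )

    @property
    def is_duct_site(self) -> bool:
        return self.diagnosis in DUCT_DIAGNOSES

    @property
    def class_label(self) -> str:
        return class_label_for(self.diagnosis)


# ---------------------------------------------------------------------------
# images and masks
# ---------------------------------------------------------------------------

def read_image(
    path: str | Path,
    calibration: PixelCalibration | None = None,
    site_id: str = "",
    rescale: bool = False,
) -> CalibratedImage:
    """Read a grayscale TIFF/PNG as an 8-bit calibrated image.

    Images deeper than 8 bit raise unless ``rescale`` is set, in which case
    they are linearly rescaled onto [0, 255].
    """
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        if arr.shape[2] in (3, 4) and np.ptp(arr[..., :3], axis=2).max() == 0:
            arr = arr[..., 0]  # gray stored as RGB
        else:
            raise ParseError(f"{path}: expected a grayscale image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        if not rescale:
            raise ParseError(
                f"{path}: image is {arr.dtype}, not 8-bit; pass rescale=True to convert"
            )
        lo, hi = float(arr.min()), float(arr.max())
        scale = 255.0 / (hi - lo) if hi > lo else 0.0
        arr = np.round((arr.astype(float) - lo) * scale).astype(np.uint8)
    return CalibratedImage(arr, calibration or PixelCalibration(), site_id=site_id)


def write_image(path: str | Path, image: CalibratedImage) -> None:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, image.pixels)
    else:
        iio.imwrite(path, image.pixels)


def write_label_mask(path: str | Path, mask: np.ndarray) -> None:
    """Store an integer label raster as 16-bit TIFF."""
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() > np.iinfo(np.uint16).max:
        raise ValueError("label mask does not fit a 16-bit raster")
    tifffile.imwrite(Path(path), mask.astype(np.uint16))


def read_label_mask(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(Path(path))
    if arr.ndim != 2:
        raise ParseError(f"{path}: label mask must be 2-D, got shape {arr.shape}")
    return arr.astype(np.int32)


# ---------------------------------------------------------------------------
# ROIs
# ---------------------------------------------------------------------------

def read_roi(path: str | Path) -> list[PolygonROI]:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: invalid JSON ({exc})") from exc
    if not isinstance(doc, dict) or "polygons" not in doc:
        raise ParseError(f"{path}: missing required key 'polygons'")
    rois = []
    for i, poly in enumerate(doc["polygons"]):
        try:
            rois.append(PolygonROI(tuple((float(x), float(y)) for x, y in poly)))
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: polygon #{i}: {exc}") from exc
    return rois


def write_roi(path: str | Path, rois: Sequence[PolygonROI]) -> None:
    doc = {"polygons": [[[float(x), float(y)] for x, y in r.vertices] for r in rois]}
    with open(path, "w") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def _canonical_feature_columns() -> list[str]:
    from .classify import ALL_FEATURE_NAMES

    return ["site_id", "diagnosis", "class_label", *ALL_FEATURE_NAMES]


def write_feature_table(path: str | Path, table: pd.DataFrame) -> None:
    cols = _canonical_feature_columns()
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ParseError(f"feature table missing columns: {missing}")
    table.loc[:, cols].to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    cols = _canonical_feature_columns()
    unknown = [c for c in table.columns if c not in cols]
    if unknown:
        raise ParseError(f"{path}: unknown feature-table columns: {unknown}")
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ParseError(f"{path}: feature table missing columns: {missing}")
    return table[cols]


def write_site_table(path: str | Path, sites: Iterable[SiteRecord]) -> None:
    rows = [
        {
            "site_id": s.site_id,
            "patient_id": s.patient_id,
            "diagnosis": s.diagnosis,
            "duct_threshold": s.duct_threshold,
        }
        for s in sites
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_site_table(path: str | Path) -> list[SiteRecord]:
    table = pd.read_csv(path)
    required = {"site_id", "patient_id", "diagnosis"}
    missing = required - set(table.columns)
    if missing:
        raise ParseError(f"{path}: site table missing columns: {sorted(missing)}")
    records = []
    for _, row in table.iterrows():
        thr = row.get("duct_threshold")
        thr = None if thr is None or pd.isna(thr) else int(thr)
        records.append(
            SiteRecord(
                site_id=str(row["site_id"]),
                patient_id=str(row["patient_id"]),
                diagnosis=str(row["diagnosis"]),
                duct_threshold=thr,
            )
        )
    return records


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ParseError(f"{path}: config must be a YAML mapping")
    return doc
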