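"""End-to-end feature extraction: images -> 33-parameter site table."""

from __future__ import annotations

from dataclasses import replace
from typing import Optional, Sequence

import pandas as pd

from .calibration import CalibratedImage
from .classify import ALL_FEATURE_NAMES
from .ductmorph import DUCT_FEATURE_NAMES, duct_feature_vector
from .ductseg import DuctSegParams, DuctSegmentationError, segment_duct
from .io import PolygonROI
from .mser import MSERParams
from .nuclear import nuclear_feature_vector
from .phantoms import SyntheticSite

__all__ = [
    "extract_site_features",
    "cohort_feature_table",
    "prepare_training_table",
]


def extract_site_features(
    image: CalibratedImage,
    diagnosis: str,
    roi: Optional[PolygonROI] = None,
    duct_threshold: Optional[int] = None,
    mser_params: Optional[MSERParams] = None,
    duct_params: Optional[DuctSegParams] = None,
) -> dict:
    """One site's metadata plus its 33 features.

    Ductal features are measured only when a ROI is given (duct sites);
    elsewhere they are NaN.  A failed duct segmentation also yields NaN
    ductal features rather than aborting the cohort run.
    """
    from .io import class_label_for

    row: dict = {
        "site_id": image.site_id,
        "diagnosis": diagnosis,
        "class_label": class_label_for(diagnosis),
    }
    row.update(nuclear_feature_vector(image, mser_params))
    if roi is not None:
        params = duct_params or DuctSegParams()
        if duct_threshold is not None:
            params = replace(params, threshold=int(duct_threshold))
        try:
            geometry = segment_duct(image, params, roi)
            row.update(duct_feature_vector(geometry, image.calibration))
        except DuctSegmentationError:
            row.update({k: float("nan") for k in DUCT_FEATURE_NAMES})
    else:
        row.update({k: float("nan") for k in DUCT_FEATURE_NAMES})
    return row


def cohort_feature_table(
    sites: Sequence[SyntheticSite],
    mser_params: Optional[MSERParams] = None,
    duct_params: Optional[DuctSegParams] = None,
) -> pd.DataFrame:
    """Extract the feature table of a synthetic cohort."""
    rows = [
        extract_site_features(
            s.image,
            s.diagnosis,
            roi=s.roi,
            duct_threshold=s.spec.duct_threshold,
            mser_params=mser_params,
            duct_params=duct_params,
        )
        for s in sites
    ]
    cols = ["site_id", "diagnosis", "class_label", *ALL_FEATURE_NAMES]
    return pd.DataFrame(rows)[cols]


def prepare_training_table(table: pd.DataFrame) -> pd.DataFrame:
    """Classifier-ready copy: missing lumen counts become 0 (sites without
    a segmented duct have no lumens); other missing values stay missing."""
    out = table.copy()
    out["n_lumens"] = out["n_lumens"].fillna(0.0)
    return out
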