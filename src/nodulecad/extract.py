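"""Assembly of the full 42-dimensional feature vector per ROI.

`extract_features` produces one :class:`FeatureVector`; `feature_table`
stacks many ROIs into the canonical ``roi_id,label,fs1..ft16`` DataFrame.
:class:`RoiFeatureExtractor` wraps the same computation as a stateless
scikit-learn transformer so extraction composes with pipelines.
"""

from __future__ import annotations

from typing import Iterable, List, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .roi import FEATURE_NAMES, FeatureVector, RoiVolume
from .shape import shape_feature_block
from .texture import intensity_texture_block


def extract_features(roi: RoiVolume, glcm_levels: int = 16) -> FeatureVector:
    """Compute the 42-slot feature vector (fs1..fs18, fi1..fi8, ft1..ft16)."""
    values = np.concatenate(
        [shape_feature_block(roi), intensity_texture_block(roi, glcm_levels=glcm_levels)]
    )
    return FeatureVector(values=values, roi_id=roi.id, label=roi.decision)


def feature_table(rois: Iterable[RoiVolume], glcm_levels: int = 16) -> pd.DataFrame:
    """Extract features for many ROIs into the canonical feature DataFrame."""
    vectors = [extract_features(roi, glcm_levels=glcm_levels) for roi in rois]
    records = []
    for v in vectors:
        rec = {"roi_id": v.roi_id, "label": v.label}
        rec.update(v.as_dict())
        records.append(rec)
    return pd.DataFrame(records, columns=["roi_id", "label", *FEATURE_NAMES])


class RoiFeatureExtractor(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer: list of :class:`RoiVolume` -> (n, 42) array.

    Stateless; ``fit`` only validates input.  ``transform`` returns a float
    array in the fixed schema order; ``get_feature_names_out`` exposes the
    slot names.
    """

    def __init__(self, glcm_levels: int = 16):
        self.glcm_levels = glcm_levels

    def fit(self, X: Sequence[RoiVolume], y=None):
        for roi in X:
            if not isinstance(roi, RoiVolume):
                raise TypeError("RoiFeatureExtractor expects RoiVolume inputs")
        self.n_features_in_ = 1
        return self

    def transform(self, X: Sequence[RoiVolume]) -> np.ndarray:
        rows: List[np.ndarray] = [
            extract_features(roi, glcm_levels=self.glcm_levels).values for roi in X
        ]
        return np.vstack(rows)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)
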