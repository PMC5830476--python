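"""Univariate feature screening and threshold-based selection.

Each binary feature (a drug-target annotation or an assay readout) is
evaluated as a standalone predictor of every ADE: its AUC-ROC when used
directly as the score, and the balanced accuracy of the
predict-positive-iff-feature-present rule.  A feature is selected when it
exceeds the block's threshold (strictly) on either metric for at least
one ADE — 0.6 for annotation blocks, 0.65 for assay readout blocks.

Note: the screen is computed on the full compound set, with no holdout;
selected-feature AUCs are screening statistics, not unbiased performance
estimates.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .evaluation import auc_roc, balanced_accuracy
from .matrices import ADELabelMatrix, FeatureMatrix

__all__ = [
    "UnivariateRecord",
    "univariate_eval",
    "screen_block",
    "select_features",
    "top_contributors",
    "DTA_THRESHOLD",
    "READOUT_THRESHOLD",
]

DTA_THRESHOLD = 0.6
READOUT_THRESHOLD = 0.65


@dataclasses.dataclass
class UnivariateRecord:
    feature_id: str
    ade_id: str
    auc: float
    ba: float
    constant: bool = False

    def passes(self, threshold: float) -> bool:
        return self.auc > threshold or self.ba > threshold


def univariate_eval(
    feature_col: np.ndarray, labels: ADELabelMatrix, feature_id: str
) -> list[UnivariateRecord]:
    """Evaluate one binary feature against every ADE column.

    A constant feature cannot rank compounds: AUC and BA are recorded as
    0.5 with the ``constant`` flag set.
    """
    x = np.asarray(feature_col, dtype=float)
    if np.isnan(x).any():
        raise ValueError("univariate screen requires a feature without missing values")
    x = x.astype(int)
    records = []
    constant = len(np.unique(x)) < 2
    for ade_id in labels.ade_ids:
        y = labels.labels(ade_id)
        if constant:
            records.append(UnivariateRecord(feature_id, ade_id, 0.5, 0.5, constant=True))
            continue
        records.append(
            UnivariateRecord(
                feature_id,
                ade_id,
                auc=auc_roc(x, y),
                ba=balanced_accuracy(x, y),
            )
        )
    return records


def screen_block(
    features: FeatureMatrix, labels: ADELabelMatrix
) -> list[UnivariateRecord]:
    """Univariate screen of every feature in a block."""
    records: list[UnivariateRecord] = []
    for fid in features.feature_ids:
        records.extend(
            univariate_eval(features.data[fid].to_numpy(), labels, fid)
        )
    return records


def select_features(
    records: list[UnivariateRecord], threshold: float
) -> set[str]:
    """Features passing the threshold (strict >, AUC or BA) for ≥1 ADE."""
    if not records:
        raise ValueError("no univariate records to select from")
    return {r.feature_id for r in records if r.passes(threshold)}


def top_contributors(records: list[UnivariateRecord]) -> pd.DataFrame:
    """Per-ADE most predictive feature by AUC (convenience report)."""
    df = records_to_frame(records)
    idx = df.groupby("ade_id")["auc"].idxmax()
    return df.loc[idx, ["ade_id", "feature_id", "auc", "ba"]].reset_index(drop=True)


def records_to_frame(records: list[UnivariateRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in records],
            "ade_id": [r.ade_id for r in records],
            "auc": [r.auc for r in records],
            "ba": [r.ba for r in records],
        }
    )
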