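"""Weighted Feature Significance (WFS) scoring.

WFS is a two-step scoring algorithm for predicting whether a drug causes a
given adverse effect (ADE) from its binary feature profile.

Step 1 builds a *comprehensive feature fingerprint* for the ADE: for every
feature present in at least one training drug with the ADE, a one-sided
Fisher's exact test measures how enriched the feature is among ADE-positive
drugs relative to ADE-negative drugs.  Rows with a missing feature value
are omitted from the 2×2 table.  A feature that is *less* frequent among
ADE-positive drugs gets p = 1 (depletion carries no evidence for the ADE).

Step 2 scores a drug with feature set C against the fingerprint M:

    WFS = sum_{i in M∩C} log(p_i)
          / ( min_{i in M} log(p_i) × (α·N_{C−M} + N_{M∩C}) )

where N_{M∩C} counts the drug's fingerprint features, N_{C−M} counts its
features absent from the fingerprint (each penalised by the weighting
factor α, fixed at 1 here), and the minimum log p normalises against the
single most significant feature of the fingerprint.  Scores lie in [0, 1]
when C ⊆ M and α = 1; a high score indicates strong ADE potential.  The
ratio is invariant to the logarithm base; natural logs are used.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .matrices import FeatureMatrix

__all__ = [
    "FeatureFingerprint",
    "WFSModel",
    "DrugFeatureSet",
    "fisher_enrichment_p",
    "build_fingerprint",
    "wfs_score",
    "score_matrix",
]


@dataclasses.dataclass
class FeatureFingerprint:
    """Per-ADE map from feature id to Fisher enrichment p-value.

    The key set is M: the features present (value 1) in at least one
    ADE-positive training compound.  All p-values lie in (0, 1].
    """

    ade_id: str
    p_values: dict[str, float]

    def __post_init__(self) -> None:
        for fid, p in self.p_values.items():
            if not (0.0 < p <= 1.0):
                raise ValueError(f"p-value for {fid!r} outside (0, 1]: {p}")

    def __len__(self) -> int:
        return len(self.p_values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature_id": list(self.p_values), "p_value": list(self.p_values.values())}
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, ade_id: str) -> "FeatureFingerprint":
        df = pd.read_csv(path)
        return cls(ade_id, dict(zip(df["feature_id"].astype(str), df["p_value"])))


@dataclasses.dataclass
class DrugFeatureSet:
    """The set C of features present in one drug."""

    present_features: frozenset[str]

    @classmethod
    def from_row(cls, row: pd.Series) -> "DrugFeatureSet":
        present = frozenset(str(f) for f, v in row.items() if v == 1)
        return cls(present)


@dataclasses.dataclass
class WFSModel:
    """A fingerprint plus the weighting factor α (default 1).

    ``min_over`` selects the index set of the min(log p) normaliser:
    ``"M"`` (default) uses the whole fingerprint, so a drug carrying only
    weak features cannot reach the maximal score; ``"M∩C"`` restricts to
    the drug's own fingerprint features (sensitivity variant).
    """

    fingerprint: FeatureFingerprint
    alpha: float = 1.0
    min_over: Literal["M", "M∩C"] = "M"

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if len(self.fingerprint) == 0:
            raise ValueError("fingerprint is empty")

    @property
    def min_log_p(self) -> float:
        return min(np.log(p) for p in self.fingerprint.p_values.values())


def fisher_enrichment_p(
    feature_col: np.ndarray, ade_labels: np.ndarray
) -> float:
    """One-sided Fisher enrichment p-value of a feature for an ADE.

    Rows where the feature value is missing (NaN) are dropped.  Among the
    remaining rows, if the feature is strictly less frequent in the
    ADE-positive set than in the ADE-negative set the p-value is set to 1;
    otherwise the one-sided (greater) Fisher exact p of the 2×2 table
    {ADE±} × {feature 1/0} is returned.
    """
    feature_col = np.asarray(feature_col, dtype=float)
    ade_labels = np.asarray(ade_labels, dtype=int)
    if feature_col.shape != ade_labels.shape:
        raise ValueError("feature and label vectors differ in length")
    keep = ~np.isnan(feature_col)
    x = feature_col[keep].astype(int)
    y = ade_labels[keep]
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        warnings.warn(
            "one label class has no non-missing feature values; p undefined, returning 1",
            stacklevel=2,
        )
        return 1.0
    k_pos = int(x[y == 1].sum())
    k_neg = int(x[y == 0].sum())
    if k_pos / n_pos < k_neg / n_neg:
        return 1.0
    # one-sided Fisher (greater) == hypergeometric upper tail
    n_total = n_pos + n_neg
    k_total = k_pos + k_neg
    return float(hypergeom.sf(k_pos - 1, n_total, k_total, n_pos))


def _fingerprint_pvalues(
    values: np.ndarray, labels: np.ndarray
) -> np.ndarray:
    """Vectorised enrichment p-values for every column of ``values``.

    Column j gets NaN if it is never 1 in an ADE-positive row (feature not
    in M).  Missing feature values are excluded column-wise.
    """
    labels = labels.astype(bool)
    present = values == 1.0
    observed = ~np.isnan(values)
    n_pos = (observed & labels[:, None]).sum(axis=0)
    n_neg = (observed & ~labels[:, None]).sum(axis=0)
    k_pos = (present & labels[:, None]).sum(axis=0)
    k_neg = (present & ~labels[:, None]).sum(axis=0)

    p = np.ones(values.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        f_pos = np.where(n_pos > 0, k_pos / np.maximum(n_pos, 1), np.nan)
        f_neg = np.where(n_neg > 0, k_neg / np.maximum(n_neg, 1), np.nan)
    testable = (n_pos > 0) & (n_neg > 0) & (f_pos >= f_neg)
    if testable.any():
        p[testable] = hypergeom.sf(
            k_pos[testable] - 1,
            n_pos[testable] + n_neg[testable],
            k_pos[testable] + k_neg[testable],
            n_pos[testable],
        )
    p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
    p[k_pos == 0] = np.nan  # not in M
    return p


def build_fingerprint(
    features: FeatureMatrix, ade_labels: np.ndarray, ade_id: str
) -> FeatureFingerprint:
    """Build the comprehensive feature fingerprint on training compounds.

    M is the set of features with value 1 in at least one ADE-positive
    training compound; each gets its Fisher enrichment p-value.
    """
    ade_labels = np.asarray(ade_labels, dtype=int)
    if ade_labels.shape[0] != features.shape[0]:
        raise ValueError("label vector length does not match compound count")
    if ade_labels.sum() == 0:
        raise ValueError(f"no ADE-positive training compounds for {ade_id!r}")
    values = features.values()
    p = _fingerprint_pvalues(values, ade_labels)
    in_m = ~np.isnan(p)
    p_values = dict(zip(np.asarray(features.feature_ids)[in_m], p[in_m]))
    return FeatureFingerprint(ade_id, p_values)


def wfs_score(model: WFSModel, drug: DrugFeatureSet) -> float:
    """Score one drug against a WFS model; degenerate cases return 0."""
    fp = model.fingerprint.p_values
    shared = drug.present_features & fp.keys()
    n_outside = len(drug.present_features) - len(shared)
    numerator = sum(np.log(fp[f]) for f in shared)
    if model.min_over == "M":
        min_log_p = min(np.log(p) for p in fp.values())
    else:
        min_log_p = min((np.log(fp[f]) for f in shared), default=0.0)
    denominator = min_log_p * (model.alpha * n_outside + len(shared))
    if numerator == 0.0 or denominator == 0.0:
        return 0.0
    return float(numerator / denominator)


def score_matrix(model: WFSModel, features: FeatureMatrix) -> pd.Series:
    """WFS-score every compound of a feature matrix.

    Missing feature values are treated as "not present" (they cannot add
    to C).  Feature ids unknown to the model's universe are tolerated only
    as absences; a fingerprint feature absent from the matrix is an error.
    """
    fp = model.fingerprint.p_values
    missing_cols = set(fp) - set(features.feature_ids)
    if missing_cols:
        raise KeyError(f"fingerprint features absent from matrix: {sorted(missing_cols)[:5]}")
    values = features.values()
    present = values == 1.0

    cols = np.asarray(features.feature_ids)
    in_m = np.isin(cols, list(fp))
    log_p = np.zeros(len(cols))
    log_p[in_m] = np.log([fp[c] for c in cols[in_m]])

    n_in = (present & in_m[None, :]).sum(axis=1)
    n_out = (present & ~in_m[None, :]).sum(axis=1)
    numerator = present[:, in_m] @ log_p[in_m]
    if model.min_over == "M":
        min_log_p = np.full(values.shape[0], min(np.log(p) for p in fp.values()))
    else:
        with np.errstate(invalid="ignore"):
            masked = np.where(present[:, in_m], log_p[in_m][None, :], np.inf)
            min_log_p = np.where(n_in > 0, masked.min(axis=1), 0.0)
    denominator = min_log_p * (model.alpha * n_out + n_in)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where((numerator == 0) | (denominator == 0), 0.0, numerator / denominator)
    return pd.Series(scores, index=features.compound_ids, name=model.fingerprint.ade_id)
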