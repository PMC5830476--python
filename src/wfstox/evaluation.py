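"""Repeated-holdout evaluation, ROC/AUC, permutation nulls and model comparison.

The evaluation protocol mirrors a repeated 50/50 holdout: compounds are
randomly split into two halves, a WFS fingerprint is fit per ADE on the
training half, the held-out half is scored, and the AUC-ROC recorded.
The split is redrawn (default 10 times) and per-ADE AUCs averaged; a
model set is summarised by the grand mean over ADEs and the count of ADEs
whose mean AUC exceeds 0.75.

Statistical significance is assessed by permutation: label permutation
(shuffle each ADE column independently, refit, re-evaluate — the grand
mean collapses to 0.5 for a random classifier) and feature-block
permutation (shuffle the rows of one block against compound ids, severing
the compound–annotation linkage while preserving column marginals).
"""

from __future__ import annotations

import dataclasses
import logging
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .matrices import ADELabelMatrix, FeatureMatrix
from .wfs import WFSModel, build_fingerprint, score_matrix

__all__ = [
    "SplitPlan",
    "EvaluationResult",
    "ModelSetSummary",
    "auc_roc",
    "balanced_accuracy",
    "run_repeated_holdout",
    "permutation_null",
    "permute_feature_block",
    "compare_model_sets",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class SplitPlan:
    """Repeated 50/50 train/test partitions of a compound list."""

    n_compounds: int
    n_splits: int = 10
    split_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.split_fraction < 1.0):
            raise ValueError("split_fraction must be in (0, 1)")
        rng = np.random.default_rng(self.seed)
        n_train = int(round(self.n_compounds * self.split_fraction))
        self._splits: list[tuple[np.ndarray, np.ndarray]] = []
        for _ in range(self.n_splits):
            perm = rng.permutation(self.n_compounds)
            self._splits.append((np.sort(perm[:n_train]), np.sort(perm[n_train:])))
        self._rng = rng

    def split(self, index: int) -> tuple[np.ndarray, np.ndarray]:
        """Train/test row indices of split ``index`` (0-based)."""
        return self._splits[index]

    def redraw(self) -> tuple[np.ndarray, np.ndarray]:
        """An extra split from the plan's stream (degenerate-split rescue)."""
        n_train = int(round(self.n_compounds * self.split_fraction))
        perm = self._rng.permutation(self.n_compounds)
        return np.sort(perm[:n_train]), np.sort(perm[n_train:])


@dataclasses.dataclass
class EvaluationResult:
    """AUC (and optional balanced accuracy) of one ADE on one split."""

    ade_id: str
    split_index: int
    auc_roc: float
    n_test_pos: int
    n_test_neg: int
    balanced_accuracy: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc_roc <= 1.0):
            raise ValueError("auc_roc outside [0, 1]")
        if self.n_test_pos < 1 or self.n_test_neg < 1:
            raise ValueError("AUC recorded for a one-class test set")


@dataclasses.dataclass
class ModelSetSummary:
    """Per-ADE mean AUCs of one model set plus Table-style aggregates."""

    model_label: str
    per_ade_auc: pd.Series
    auc_threshold: float = 0.75

    @property
    def grand_mean_auc(self) -> float:
        return float(self.per_ade_auc.mean())

    @property
    def best_auc(self) -> float:
        return float(self.per_ade_auc.max())

    @property
    def n_above_threshold(self) -> int:
        return int((self.per_ade_auc > self.auc_threshold).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": [self.model_label],
                "best_auc": [self.best_auc],
                "mean_auc": [self.grand_mean_auc],
                f"ades_above_{self.auc_threshold}": [self.n_above_threshold],
            }
        )


def auc_roc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve.

    Equals the probability that a random positive outscores a random
    negative, with ties counted 0.5 (Mann-Whitney convention).  0.5 is a
    random classifier, 1 a perfect one.
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def balanced_accuracy(predictions: np.ndarray, labels: np.ndarray) -> float:
    """(sensitivity + specificity) / 2 of binary predictions."""
    predictions = np.asarray(predictions, dtype=int)
    labels = np.asarray(labels, dtype=int)
    n_pos = (labels == 1).sum()
    n_neg = (labels == 0).sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("balanced accuracy undefined: labels contain a single class")
    sens = (predictions[labels == 1] == 1).sum() / n_pos
    spec = (predictions[labels == 0] == 0).sum() / n_neg
    return float((sens + spec) / 2.0)


def _evaluate_ade_split(
    features: FeatureMatrix,
    labels: np.ndarray,
    ade_id: str,
    split_index: int,
    train: np.ndarray,
    test: np.ndarray,
    alpha: float,
) -> EvaluationResult:
    fp = build_fingerprint(_rows(features, train), labels[train], ade_id)
    y = labels[test]
    if len(fp) == 0:
        # positives carry no features: no evidence, every score 0 (AUC 0.5)
        scores = np.zeros(len(test))
    else:
        model = WFSModel(fp, alpha=alpha)
        scores = score_matrix(model, _rows(features, test)).to_numpy()
    return EvaluationResult(
        ade_id=ade_id,
        split_index=split_index + 1,
        auc_roc=auc_roc(scores, y),
        n_test_pos=int((y == 1).sum()),
        n_test_neg=int((y == 0).sum()),
    )


def _rows(features: FeatureMatrix, idx: np.ndarray) -> FeatureMatrix:
    fm = FeatureMatrix.__new__(FeatureMatrix)
    fm.data = features.data.iloc[idx]
    fm.block_label = features.block_label
    return fm


def run_repeated_holdout(
    features: FeatureMatrix,
    labels: ADELabelMatrix,
    plan: SplitPlan,
    alpha: float = 1.0,
    model_label: str | None = None,
    max_redraws: int = 100,
) -> tuple[list[EvaluationResult], ModelSetSummary]:
    """Fit-and-score every ADE on every split of the plan.

    For each (ADE, split): fingerprint on the training half, WFS scores on
    the test half, AUC recorded.  A split that leaves one class empty in
    train or test for an ADE is redrawn for that ADE (up to
    ``max_redraws``); if no usable split is found the (ADE, split) cell is
    skipped with a warning.
    """
    if features.shape[0] != len(labels.compound_ids):
        raise ValueError("features and labels are not aligned")
    if plan.n_compounds != features.shape[0]:
        raise ValueError("split plan sized for a different compound count")
    results: list[EvaluationResult] = []
    for ade_id in labels.ade_ids:
        y = labels.labels(ade_id)
        for s in range(plan.n_splits):
            train, test = plan.split(s)
            tries = 0
            while (
                len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2
            ) and tries < max_redraws:
                train, test = plan.redraw()
                tries += 1
            if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
                logger.warning(
                    "skipping ADE %s split %d: one-class after %d redraws",
                    ade_id, s + 1, max_redraws,
                )
                continue
            if tries:
                logger.info("ADE %s split %d redrawn %d times", ade_id, s + 1, tries)
            results.append(
                _evaluate_ade_split(features, y, ade_id, s, train, test, alpha)
            )
    per_ade = (
        pd.DataFrame(
            {"ade_id": [r.ade_id for r in results], "auc": [r.auc_roc for r in results]}
        )
        .groupby("ade_id")["auc"]
        .mean()
        .reindex(labels.ade_ids)
        .dropna()
    )
    summary = ModelSetSummary(model_label or features.block_label, per_ade)
    return results, summary


def permutation_null(
    features: FeatureMatrix,
    labels: ADELabelMatrix,
    plan: SplitPlan,
    n_perm: int,
    observed_mean: float | None = None,
    seed: int = 0,
    alpha: float = 1.0,
) -> tuple[np.ndarray, float | None]:
    """Label-permutation null distribution of the grand mean AUC.

    Each replicate independently permutes every ADE label column across
    compounds, reruns the repeated holdout, and records the grand mean
    AUC.  If ``observed_mean`` is given, the one-sided empirical p-value
    (1 + #{null ≥ observed}) / (n_perm + 1) is returned alongside.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    null_means = np.empty(n_perm)
    n = len(labels.compound_ids)
    for r in range(n_perm):
        shuffled = labels.data.copy()
        for ade_id in labels.ade_ids:
            shuffled[ade_id] = shuffled[ade_id].to_numpy()[rng.permutation(n)]
        perm_labels = ADELabelMatrix(shuffled)
        _, summary = run_repeated_holdout(
            features, perm_labels, plan, alpha=alpha, model_label="null"
        )
        null_means[r] = summary.grand_mean_auc
    p = None
    if observed_mean is not None:
        p = (1.0 + float((null_means >= observed_mean).sum())) / (n_perm + 1.0)
    return null_means, p


def permute_feature_block(features: FeatureMatrix, seed: int) -> FeatureMatrix:
    """Shuffle the rows of a block against its compound ids.

    Severs the compound↔annotation linkage while preserving every column
    marginal exactly; used to show that combined-model gains vanish when
    the added block is randomised.
    """
    if np.isnan(features.values()).any():
        raise ValueError("block permutation requires a block without missing values")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(features.shape[0])
    shuffled = pd.DataFrame(
        features.values()[perm], index=features.compound_ids, columns=features.feature_ids
    )
    return FeatureMatrix(shuffled, features.block_label)


def compare_model_sets(summaries: Sequence[ModelSetSummary]) -> pd.DataFrame:
    """One-way ANOVA across model sets with Bonferroni post hoc t-tests.

    Observations are per-ADE mean AUCs; all summaries must cover the same
    ADE list.  Returns a tidy frame: one ``anova`` row with the global F
    and p, then one row per pair with the Bonferroni-adjusted p (raw p
    multiplied by the number of pairs, capped at 1).
    """
    if len(summaries) < 2:
        raise ValueError("need at least two model sets to compare")
    ade_lists = [list(s.per_ade_auc.index) for s in summaries]
    if any(sorted(a) != sorted(ade_lists[0]) for a in ade_lists[1:]):
        raise ValueError("model sets cover different ADE lists")
    groups = [s.per_ade_auc.to_numpy() for s in summaries]
    f_stat, anova_p = stats.f_oneway(*groups)
    rows = [
        {
            "comparison": "anova",
            "statistic": float(f_stat),
            "p_raw": float(anova_p),
            "p_adjusted": float(anova_p),
        }
    ]
    pairs = list(combinations(range(len(summaries)), 2))
    for i, j in pairs:
        if np.array_equal(groups[i], groups[j]):
            t, p_raw = 0.0, 1.0  # identical sets: no evidence of difference
        else:
            t, p_raw = stats.ttest_ind(groups[i], groups[j])
        rows.append(
            {
                "comparison": f"{summaries[i].model_label} vs {summaries[j].model_label}",
                "statistic": float(t),
                "p_raw": float(p_raw),
                "p_adjusted": min(1.0, float(p_raw) * len(pairs)),
            }
        )
    return pd.DataFrame(rows)
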