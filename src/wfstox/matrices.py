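"""Core matrix containers and I/O.

The pipeline works on wide binary matrices: compounds in rows, features
(assay readouts, drug-target annotations, structure-fingerprint bits,
animal-toxicity endpoints) or adverse-effect labels in columns.  Assay and
animal blocks may contain missing values (a compound not tested in an
assay); annotation and structure blocks are strictly 0/1.

All containers wrap a :class:`pandas.DataFrame` with float values, using
``NaN`` as the missing sentinel.  CSV/TSV round-trips preserve missingness
(empty cell or ``NA`` on read, empty cell on write).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "ADELabelMatrix",
    "MatrixValidationError",
    "read_feature_matrix",
    "read_ade_labels",
    "write_matrix",
    "filter_ades",
    "align_compounds",
]

#: block labels that must not contain missing values
_NO_MISSING_BLOCKS = frozenset({"dta", "structure"})


class MatrixValidationError(ValueError):
    """Raised when a matrix violates its structural contract."""


def _check_unique(ids: Iterable[str], what: str) -> None:
    ids = list(ids)
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise MatrixValidationError(f"duplicate {what}: {dups[:5]}")


def _check_binary(df: pd.DataFrame, allow_missing: bool, context: str) -> None:
    values = df.to_numpy(dtype=float)
    bad = ~(np.isnan(values) | (values == 0.0) | (values == 1.0))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise MatrixValidationError(
            f"{context}: value {values[r, c]!r} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r} is not 0/1/missing"
        )
    if not allow_missing and np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise MatrixValidationError(
            f"{context}: missing value at row {df.index[r]!r}, column "
            f"{df.columns[c]!r} not allowed in this block"
        )


@dataclasses.dataclass
class FeatureMatrix:
    """Compounds × binary features, with optional missing values.

    Parameters
    ----------
    data
        DataFrame indexed by compound id with feature ids as columns.
        Values are 0.0, 1.0 or NaN (missing).
    block_label
        Free-text name of the data type: ``assay``, ``dta``, ``structure``
        or ``animal``.  ``dta`` and ``structure`` blocks reject missing
        values.
    """

    data: pd.DataFrame
    block_label: str = "assay"

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        _check_unique(self.data.index, "compound ids")
        _check_unique(self.data.columns, "feature ids")
        allow_missing = self.block_label not in _NO_MISSING_BLOCKS
        _check_binary(self.data, allow_missing, f"{self.block_label} block")

    @property
    def compound_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        """Dense float array with NaN for missing."""
        return self.data.to_numpy(dtype=float)

    def subset(self, compound_ids: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(self.data.loc[list(compound_ids)], self.block_label)

    def concat(self, other: "FeatureMatrix", block_label: str | None = None) -> "FeatureMatrix":
        """Column-wise concatenation over an identical compound index."""
        if list(self.data.index) != list(other.data.index):
            raise MatrixValidationError("concat requires identical compound order")
        overlap = set(self.feature_ids) & set(other.feature_ids)
        if overlap:
            raise MatrixValidationError(f"overlapping feature ids: {sorted(overlap)[:5]}")
        label = block_label or f"{self.block_label}+{other.block_label}"
        merged = pd.concat([self.data, other.data], axis=1)
        # concat blocks may mix missing policies; validate as missing-capable
        fm = FeatureMatrix.__new__(FeatureMatrix)
        fm.data = merged.astype(float)
        fm.block_label = label
        _check_unique(fm.data.index, "compound ids")
        _check_unique(fm.data.columns, "feature ids")
        _check_binary(fm.data, True, f"{label} block")
        return fm


@dataclasses.dataclass
class ADELabelMatrix:
    """Compounds × adverse drug effects, strictly binary (no missing)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        _check_unique(self.data.index, "compound ids")
        _check_unique(self.data.columns, "ADE ids")
        _check_binary(self.data, False, "ADE labels")
        self.data = self.data.astype(int)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def ade_ids(self) -> list[str]:
        return list(self.data.columns)

    def labels(self, ade_id: str) -> np.ndarray:
        return self.data[ade_id].to_numpy(dtype=int)

    def positive_counts(self) -> pd.Series:
        return self.data.sum(axis=0)

    def subset(self, compound_ids: Sequence[str]) -> "ADELabelMatrix":
        return ADELabelMatrix(self.data.loc[list(compound_ids)])


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def _read_wide(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    header = pd.read_csv(path, sep=_sep_for(path), header=None, nrows=1, dtype=str)
    _check_unique(header.iloc[0, 1:], f"feature ids in {path.name}")
    df = pd.read_csv(
        path,
        sep=_sep_for(path),
        index_col=0,
        dtype=str,
        keep_default_na=False,
        na_values=["", "NA"],
    )
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    try:
        return df.astype(float)
    except ValueError as exc:
        raise MatrixValidationError(f"{path}: non-numeric cell ({exc})") from exc


def read_feature_matrix(path: str | Path, block_label: str = "assay") -> FeatureMatrix:
    """Read a wide CSV/TSV (first column compound id, header feature ids).

    Empty cells and ``NA`` parse as missing.  Delimiter is inferred from
    the extension (``.tsv``/``.tab`` → tab, otherwise comma).
    """
    return FeatureMatrix(_read_wide(path), block_label)


def read_ade_labels(path: str | Path) -> ADELabelMatrix:
    """Read a wide CSV/TSV of 0/1 adverse-effect labels."""
    return ADELabelMatrix(_read_wide(path))


def write_matrix(matrix: FeatureMatrix | ADELabelMatrix, path: str | Path) -> None:
    """Write a matrix to CSV/TSV; missing values become empty cells."""
    path = Path(path)
    df = matrix.data
    if df.to_numpy().dtype.kind == "f" and not np.isnan(df.to_numpy()).any():
        df = df.astype(int)
    elif df.to_numpy().dtype.kind == "f":
        # keep 0/1 printed without decimals where present
        df = df.map(lambda v: "" if pd.isna(v) else str(int(v)))
    df.to_csv(path, sep=_sep_for(path), index_label="compound_id")


def filter_ades(labels: ADELabelMatrix, min_drugs: int) -> ADELabelMatrix:
    """Drop ADE columns with fewer than ``min_drugs`` positive compounds.

    The threshold is inclusive: an ADE with exactly ``min_drugs`` positives
    is kept ("fewer than" is strict).  The compound set is unchanged.
    """
    if min_drugs < 1:
        raise ValueError("min_drugs must be >= 1")
    counts = labels.positive_counts()
    keep = counts[counts >= min_drugs].index
    if len(keep) == 0:
        raise MatrixValidationError(
            f"all {len(counts)} ADEs have fewer than {min_drugs} positive "
            "compounds; lower the threshold"
        )
    return ADELabelMatrix(labels.data[list(keep)])


def align_compounds(
    blocks: Sequence[FeatureMatrix], labels: ADELabelMatrix
) -> tuple[list[FeatureMatrix], ADELabelMatrix, dict[str, int]]:
    """Restrict all matrices to the shared compound ids, in one row order.

    Returns the aligned blocks, aligned labels, and a per-input count of
    dropped compounds.  Row order follows the label matrix's order
    restricted to the intersection, so the operation is idempotent.
    """
    common = set(labels.compound_ids)
    for block in blocks:
        common &= set(block.compound_ids)
    if not common:
        raise MatrixValidationError("no compound ids shared by all inputs")
    order = [c for c in labels.compound_ids if c in common]
    dropped = {"labels": len(labels.compound_ids) - len(order)}
    aligned_blocks = []
    for i, block in enumerate(blocks):
        dropped[f"block_{i}_{block.block_label}"] = len(block.compound_ids) - len(order)
        aligned_blocks.append(block.subset(order))
    return aligned_blocks, labels.subset(order), dropped
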