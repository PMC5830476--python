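"""Activity calling and assay-reproducibility QC.

Quantitative HTS assays summarise each concentration-response curve by a
signed *curve rank*: positive for activation, negative for inhibition,
larger magnitude meaning higher-confidence activity.  A compound is
called active when |curve rank| > 0.5 (strict), inactive otherwise.

Reproducibility of an assay is graded from triplicate screens of the same
library (three copies, different well layouts).  Per compound the three
calls fall into: active match (all three active, same direction),
inactive match (all three inactive), mismatch (both directions present),
or inconclusive (any other pattern).  The score is

    score = 2·%active match + %inactive match − %inconclusive − 2·%mismatch

graded A (≥90), B (80–90), C (70–80), D (<70).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CALL_STATES",
    "TriplicateCallTable",
    "ReproducibilityRecord",
    "call_activity",
    "triplicate_rates",
    "reproducibility_score",
    "qc_report",
]

CALL_STATES = ("activation", "inhibition", "inactive", "inconclusive")


@dataclasses.dataclass
class TriplicateCallTable:
    """Exactly three activity calls per (compound, assay).

    ``calls`` is a long DataFrame with columns compound_id, assay_id,
    replicate (1..3), call (one of :data:`CALL_STATES`).
    """

    calls: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"compound_id", "assay_id", "replicate", "call"}
        if not required <= set(self.calls.columns):
            raise ValueError(f"call table needs columns {sorted(required)}")
        bad = set(self.calls["call"]) - set(CALL_STATES)
        if bad:
            raise ValueError(f"unknown call states: {sorted(bad)}")
        counts = self.calls.groupby(["compound_id", "assay_id"]).size()
        if (counts != 3).any():
            offender = counts[counts != 3].index[0]
            raise ValueError(f"{offender}: expected 3 replicates, got {counts[offender]}")

    @property
    def assay_ids(self) -> list[str]:
        return sorted(self.calls["assay_id"].unique())

    def write_csv(self, path: str | Path) -> None:
        self.calls.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "TriplicateCallTable":
        return cls(pd.read_csv(path, dtype={"compound_id": str, "assay_id": str}))


@dataclasses.dataclass
class ReproducibilityRecord:
    assay_id: str
    pct_active_match: float
    pct_inactive_match: float
    pct_inconclusive: float
    pct_mismatch: float
    score: float
    grade: str

    def __post_init__(self) -> None:
        total = (
            self.pct_active_match
            + self.pct_inactive_match
            + self.pct_inconclusive
            + self.pct_mismatch
        )
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"rates sum to {total}, not 100")


def call_activity(curve_rank: float) -> tuple[int, int]:
    """Binary activity call plus direction from a signed curve rank.

    Returns ``(call, direction)``: call is 1 iff |curve_rank| > 0.5
    (strict), direction is the sign (+1 activation, −1 inhibition, 0 for
    inactive).
    """
    if not np.isfinite(curve_rank):
        raise ValueError(f"curve rank must be finite, got {curve_rank}")
    active = int(abs(curve_rank) > 0.5)
    direction = int(np.sign(curve_rank)) if active else 0
    return active, direction


def triplicate_rates(
    table: TriplicateCallTable, assay_id: str
) -> tuple[float, float, float, float]:
    """Active-match / inactive-match / inconclusive / mismatch percentages."""
    sub = table.calls[table.calls["assay_id"] == assay_id]
    if sub.empty:
        raise KeyError(f"no calls for assay {assay_id!r}")
    n = a = i = m = inc = 0
    for _, grp in sub.groupby("compound_id"):
        calls = list(grp["call"])
        n += 1
        has_act = "activation" in calls
        has_inh = "inhibition" in calls
        if has_act and has_inh:
            m += 1
        elif all(c == "inactive" for c in calls):
            i += 1
        elif all(c == "activation" for c in calls) or all(c == "inhibition" for c in calls):
            a += 1
        else:
            inc += 1
    return tuple(100.0 * x / n for x in (a, i, inc, m))  # type: ignore[return-value]


def reproducibility_score(
    rates: tuple[float, float, float, float]
) -> tuple[float, str]:
    """Score and letter grade from the four match-rate percentages."""
    active, inactive, inconclusive, mismatch = rates
    if any(r < 0 for r in rates) or abs(sum(rates) - 100.0) > 1e-9:
        raise ValueError(f"rates must be non-negative and sum to 100, got {rates}")
    score = 2.0 * active + inactive - inconclusive - 2.0 * mismatch
    if score >= 90:
        grade = "A"
    elif score >= 80:
        grade = "B"
    elif score >= 70:
        grade = "C"
    else:
        grade = "D"
    return score, grade


def qc_report(table: TriplicateCallTable) -> pd.DataFrame:
    """Reproducibility records for every assay, as a tidy frame."""
    rows = []
    for assay_id in table.assay_ids:
        rates = triplicate_rates(table, assay_id)
        score, grade = reproducibility_score(rates)
        rec = ReproducibilityRecord(assay_id, *rates, score=score, grade=grade)
        rows.append(dataclasses.asdict(rec))
    return pd.DataFrame(rows)
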