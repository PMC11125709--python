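"""Staged quality-control filters on trials and feature values.

Exclusions happen in a fixed order:

1. **protocol** — subjects flagged as unable to complete the seated trial
   (a boolean on the subject record; not detected algorithmically);
2. **implausible** — any trial with any feature value strictly greater than
   10^6 (technically impossible magnitudes);
3. **iqr_distance** — per feature column, values farther than k·IQR
   (default k = 0.9) outside the interquartile interval [Q1, Q3] are
   excluded; a trial is dropped if any analysis-relevant feature falls
   outside its fence.

Quartiles use linear interpolation (numpy's default, "type 7"); the fence
rule is invariant under affine transformation of the values and both filters
are idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import SubjectRecord


@dataclass
class ExclusionReport:
    stage: str  # one of {"protocol", "implausible", "iqr_distance"}
    excluded_ids: list[str]
    rule_params: dict = field(default_factory=dict)
    n_before: int = 0
    n_after: int = 0

    def __post_init__(self) -> None:
        assert self.n_after == self.n_before - len(self.excluded_ids)

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "excluded_ids": list(self.excluded_ids),
            "rule_params": dict(self.rule_params),
            "n_before": self.n_before,
            "n_after": self.n_after,
        }


def filter_protocol(
    records: Sequence[SubjectRecord],
) -> tuple[list[SubjectRecord], ExclusionReport]:
    """Drop subjects whose protocol flag marks the trial invalid."""
    kept = [r for r in records if r.protocol_ok]
    excluded = [r.subject_id for r in records if not r.protocol_ok]
    return kept, ExclusionReport(
        stage="protocol",
        excluded_ids=excluded,
        rule_params={},
        n_before=len(records),
        n_after=len(kept),
    )


def filter_implausible(
    features: pd.DataFrame,
    threshold: float = 1e6,
    columns: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop trials with any feature value strictly greater than ``threshold``.

    ``features`` is one row per trial with a ``subject_id`` column; a value
    exactly at the threshold is kept ("greater than" is strict).
    """
    cols = list(columns) if columns is not None else [
        c for c in features.columns if c != "subject_id"
    ]
    bad = (features[cols] > threshold).any(axis=1)
    kept = features.loc[~bad]
    return kept, ExclusionReport(
        stage="implausible",
        excluded_ids=features.loc[bad, "subject_id"].tolist(),
        rule_params={"threshold": threshold, "columns": cols},
        n_before=len(features),
        n_after=len(kept),
    )


def iqr_fences(values: np.ndarray, k: float = 0.9) -> tuple[float, float]:
    """[Q1 - k·IQR, Q3 + k·IQR] with type-7 (linear interpolation) quartiles."""
    q1, q3 = np.quantile(values, [0.25, 0.75])
    iqr = q3 - q1
    return float(q1 - k * iqr), float(q3 + k * iqr)


def filter_iqr_distance(
    values: Sequence[float], k: float = 0.9
) -> tuple[np.ndarray, ExclusionReport]:
    """Keep values within k·IQR of the interquartile interval.

    Returns (kept indices, report).  With IQR = 0 (all values equal within
    the quartiles) the interval collapses and only exact matches survive —
    for constant data nothing is excluded.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        raise ValueError("IQR fence needs at least 4 values")
    lo, hi = iqr_fences(arr, k)
    kept_idx = np.flatnonzero((arr >= lo) & (arr <= hi))
    excluded = [str(i) for i in np.flatnonzero((arr < lo) | (arr > hi))]
    return kept_idx, ExclusionReport(
        stage="iqr_distance",
        excluded_ids=excluded,
        rule_params={"k": k, "fence_low": lo, "fence_high": hi},
        n_before=arr.size,
        n_after=kept_idx.size,
    )


def filter_feature_table_iqr(
    features: pd.DataFrame,
    columns: Sequence[str],
    k: float = 0.9,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the IQR fence per feature column; drop a trial if any listed
    feature falls outside its column's fence."""
    keep_mask = np.ones(len(features), dtype=bool)
    fences = {}
    for col in columns:
        vals = features[col].to_numpy(dtype=float)
        lo, hi = iqr_fences(vals, k)
        fences[col] = (lo, hi)
        keep_mask &= (vals >= lo) & (vals <= hi)
    kept = features.loc[keep_mask]
    return kept, ExclusionReport(
        stage="iqr_distance",
        excluded_ids=features.loc[~keep_mask, "subject_id"].tolist(),
        rule_params={"k": k, "fences": {c: list(f) for c, f in fences.items()}},
        n_before=len(features),
        n_after=len(kept),
    )
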