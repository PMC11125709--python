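"""CSV readers/writers for trial recordings, cohort tables and CoP tracks.

No standard on-disk format exists for raw balance-board data, so the package
uses plain CSV: one row per sample, columns ``time_s`` (optional), ``f_tl``,
``f_tr``, ``f_bl``, ``f_br`` in newtons.  Cohort tables are one row per
subject.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .core import CHANNEL_NAMES, CoPTrack, ForceRecording, SubjectRecord, pain_label_from_korff

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """The file does not follow the expected column layout."""


class DataError(ValueError):
    """The file parses but its contents are unusable."""


#: tolerated relative mismatch between file rows and configured duration
_DURATION_RTOL = 0.01


def read_recording(
    path: str | Path,
    config: PipelineConfig,
    subject_id: str | None = None,
    max_nan_gap: int = 10,
) -> ForceRecording:
    """Read one trial's four-channel force recording from CSV.

    Short NaN gaps (up to ``max_nan_gap`` consecutive samples per channel)
    are linearly interpolated; longer runs raise :class:`DataError`.  If the
    file holds more rows than ``config`` expects the recording is truncated
    with a warning; too few rows (beyond 1% tolerance) is an error.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in CHANNEL_NAMES if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing force columns {missing}")

    n_expected = config.n_samples
    n_rows = len(df)
    if n_rows < n_expected * (1 - _DURATION_RTOL):
        raise DataError(
            f"{path.name}: {n_rows} rows < expected {n_expected} "
            f"({config.trial_duration_s} s at {config.sampling_rate_hz} Hz)"
        )
    if n_rows > n_expected * (1 + _DURATION_RTOL):
        warnings.warn(
            f"{path.name}: {n_rows} rows exceed configured duration; "
            f"truncating to {n_expected}",
            stacklevel=2,
        )
        df = df.iloc[:n_expected]

    channels = np.empty((4, len(df)))
    for i, name in enumerate(CHANNEL_NAMES):
        col = df[name].to_numpy(dtype=float)
        col = _fill_nan_gaps(col, max_nan_gap, f"{path.name}:{name}")
        channels[i] = col

    return ForceRecording(
        channels=channels,
        rate_hz=config.sampling_rate_hz,
        board_half_length_cm=config.board_half_length_cm,
        board_half_width_cm=config.board_half_width_cm,
        subject_id=subject_id if subject_id is not None else path.stem,
    )


def _fill_nan_gaps(x: np.ndarray, max_gap: int, label: str) -> np.ndarray:
    bad = ~np.isfinite(x)
    if not bad.any():
        return x
    # longest run of consecutive NaNs
    runs = np.diff(np.flatnonzero(np.diff(np.r_[0, bad.view(np.int8), 0])))[::2]
    longest = int(runs.max()) if runs.size else 0
    if longest > max_gap or bad.all():
        raise DataError(f"{label}: NaN run of {longest} samples exceeds gap limit {max_gap}")
    idx = np.arange(x.size)
    out = x.copy()
    out[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    return out


def write_recording(rec: ForceRecording, path: str | Path, include_time: bool = True) -> None:
    """Write a recording as CSV (inverse of :func:`read_recording`)."""
    data = {}
    if include_time:
        data["time_s"] = np.arange(rec.n_samples) / rec.rate_hz
    for name, chan in zip(CHANNEL_NAMES, rec.channels):
        data[name] = chan
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")


_COHORT_COLUMNS = [
    "subject_id", "sex", "age_years", "height_cm", "weight_kg", "shoe_size_eu",
]


def read_cohort(path: str | Path, korff_threshold: int = 1) -> list[SubjectRecord]:
    """Read a cohort table (one row per subject) into validated records.

    Each row needs either a ``pain`` column ("LowBackPain"/"Healthy") or a
    ``korff_grade`` column from which the label is derived.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in _COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cohort table missing columns {missing}")
    if "pain" not in df.columns and "korff_grade" not in df.columns:
        raise FormatError("cohort table needs a 'pain' or 'korff_grade' column")
    dupes = df["subject_id"][df["subject_id"].duplicated()].tolist()
    if dupes:
        raise DataError(f"duplicate subject ids: {dupes}")

    records = []
    for _, row in df.iterrows():
        korff = None
        if "korff_grade" in df.columns and pd.notna(row.get("korff_grade")):
            korff = int(row["korff_grade"])
        if "pain" in df.columns and pd.notna(row.get("pain")):
            pain = str(row["pain"])
        elif korff is not None:
            pain = pain_label_from_korff(korff, korff_threshold)
        else:
            raise DataError(f"subject {row['subject_id']}: no pain label or Korff grade")
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                sex=str(row["sex"]),
                age_years=float(row["age_years"]),
                height_cm=float(row["height_cm"]),
                weight_kg=float(row["weight_kg"]),
                shoe_size_eu=float(row["shoe_size_eu"]),
                pain=pain,
                korff_grade=korff,
                protocol_ok=bool(row["protocol_ok"]) if "protocol_ok" in df.columns else True,
            )
        )
    return records


def write_cohort(records: list[SubjectRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "subject_id": r.subject_id,
                "sex": r.sex,
                "age_years": r.age_years,
                "height_cm": r.height_cm,
                "weight_kg": r.weight_kg,
                "shoe_size_eu": r.shoe_size_eu,
                "pain": r.pain,
                "korff_grade": r.korff_grade if r.korff_grade is not None else "",
                "protocol_ok": r.protocol_ok,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_cop_track(track: CoPTrack, path: str | Path) -> None:
    t = np.arange(track.n_samples) / track.rate_hz
    pd.DataFrame({"t": t, "x_cm": track.x_ml_cm, "y_cm": track.y_ap_cm}).to_csv(
        path, index=False, float_format="%.9g"
    )
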