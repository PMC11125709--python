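"""Core data containers for seated-posturography trials.

Conventions used throughout the package:

* coordinates: ``x`` is mediolateral (right positive), ``y`` is
  anteroposterior (anterior positive), origin at the board centre, in cm;
* force channels are ordered top-left, top-right, bottom-left, bottom-right
  ("top" = anterior edge of the board), in newtons;
* sampling rates in Hz, durations in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

#: gravitational acceleration used to convert mass to weight force [m/s^2]
GRAVITY_M_S2 = 9.81

#: channel names in storage order
CHANNEL_NAMES = ("f_tl", "f_tr", "f_bl", "f_br")


@dataclass
class ForceRecording:
    """One trial's raw four-load-cell force time series.

    ``channels`` has shape ``(4, n_samples)`` in the order TL, TR, BL, BR.
    Board half-dimensions describe the rectangle spanned by the four load
    cells; the CoP formula scales the normalised force asymmetry by them.
    """

    channels: np.ndarray
    rate_hz: float
    board_half_length_cm: float
    board_half_width_cm: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 2 or self.channels.shape[0] != 4:
            raise ValueError(
                f"channels must have shape (4, n); got {self.channels.shape}"
            )
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.board_half_length_cm <= 0 or self.board_half_width_cm <= 0:
            raise ValueError("board half-dimensions must be positive")

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    @property
    def total_force(self) -> np.ndarray:
        """Per-sample sum of the four channels [N]."""
        return self.channels.sum(axis=0)


@dataclass
class CoPTrack:
    """Planar centre-of-pressure trajectory at a fixed sampling rate."""

    x_ml_cm: np.ndarray
    y_ap_cm: np.ndarray
    rate_hz: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.x_ml_cm = np.asarray(self.x_ml_cm, dtype=float)
        self.y_ap_cm = np.asarray(self.y_ap_cm, dtype=float)
        if self.x_ml_cm.shape != self.y_ap_cm.shape or self.x_ml_cm.ndim != 1:
            raise ValueError("x and y must be equal-length 1-D arrays")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.x_ml_cm.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def as_array(self) -> np.ndarray:
        """Stack to shape ``(n, 2)`` with columns (x_ml, y_ap)."""
        return np.column_stack([self.x_ml_cm, self.y_ap_cm])


@dataclass
class SubjectRecord:
    """Anthropometry and pain label for one subject.

    ``pain`` is the binary study label; when a Korff chronic-pain grade is
    available the label is derived from it (grade >= threshold ->
    "LowBackPain", configurable, default threshold 1).
    """

    subject_id: str
    sex: str
    age_years: float
    height_cm: float
    weight_kg: float
    shoe_size_eu: float
    pain: str
    korff_grade: int | None = None
    protocol_ok: bool = True

    VALID_SEX = frozenset({"M", "F"})
    VALID_PAIN = frozenset({"LowBackPain", "Healthy"})

    def __post_init__(self) -> None:
        if self.sex not in self.VALID_SEX:
            raise ValueError(f"sex must be one of {sorted(self.VALID_SEX)}; got {self.sex!r}")
        if self.pain not in self.VALID_PAIN:
            raise ValueError(
                f"pain must be one of {sorted(self.VALID_PAIN)}; got {self.pain!r}"
            )


def pain_label_from_korff(grade: int, threshold: int = 1) -> str:
    """Binary pain label from a Korff chronic-pain grade (0-4)."""
    if not 0 <= grade <= 4:
        raise ValueError(f"Korff grade must be in 0..4; got {grade}")
    return "LowBackPain" if grade >= threshold else "Healthy"


@dataclass
class Spectrum:
    """One-sided power spectral density of a CoP axis (or their sum)."""

    freqs_hz: np.ndarray
    density: np.ndarray
    axis: str = "resultant"  # one of {"ML", "AP", "resultant"}

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.freqs_hz.shape != self.density.shape:
            raise ValueError("freqs and density must have equal shapes")
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise ValueError("freqs_hz must be strictly increasing")
        if np.any(self.density < -1e-15):
            raise ValueError("density must be nonnegative")


@dataclass
class FeatureVector:
    """Per-trial scalar features entering the statistical analysis."""

    subject_id: str
    track_length_cm: float
    band_area: Mapping[tuple[float, float], float] = field(default_factory=dict)
    mean_max_accel_cm_s2: float = float("nan")
    ellipticity: float = float("nan")

    def to_dict(self) -> dict[str, float]:
        """Flatten to a column-name -> value mapping for table assembly."""
        out: dict[str, float] = {
            "subject_id": self.subject_id,  # type: ignore[dict-item]
            "track_length_cm": self.track_length_cm,
            "mean_max_accel_cm_s2": self.mean_max_accel_cm_s2,
            "ellipticity": self.ellipticity,
        }
        for (lo, hi), area in self.band_area.items():
            out[band_column_name(lo, hi)] = area
        return out


def band_column_name(low_hz: float, high_hz: float) -> str:
    """Stable column name for a frequency band, e.g. ``band_0p001_10``."""

    def fmt(v: float) -> str:
        s = f"{v:g}".replace(".", "p").replace("-", "m")
        return s

    return f"band_{fmt(low_hz)}_{fmt(high_hz)}"
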