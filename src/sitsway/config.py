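"""Pipeline configuration.

A single :class:`PipelineConfig` travels through the whole pipeline:
acquisition geometry, filter design, PSD estimator, band set, benchmark
protocol and master RNG seed.  Defaults mirror the acquisition protocol the
package targets: four-channel balance-board recordings at 1 kHz for 60 s,
third-order zero-phase Butterworth low-pass, periodogram PSD integrated over
eight frequency windows between the lowest resolvable frequency and 10 Hz.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

#: the eight analysis bands (low_hz, high_hz); 0.001 Hz is in practice the
#: lowest resolvable frequency of the trial (band edges are clipped to the
#: first positive PSD bin at integration time).
DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (0.001, 10.0),
    (0.001, 8.0),
    (0.001, 6.0),
    (0.001, 4.0),
    (0.001, 1.0),
    (1.0, 8.0),
    (1.0, 4.0),
    (4.0, 8.0),
)

#: nominal Wii-type balance-board load-cell rectangle (cm)
DEFAULT_BOARD_HALF_LENGTH_CM = 15.8
DEFAULT_BOARD_HALF_WIDTH_CM = 25.5


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters in one place.

    ``filter_cutoff_hz`` may be a number (fixed cohort-wide cutoff) or the
    string ``"auto"`` to select it by residual analysis on the cohort.
    """

    sampling_rate_hz: float = 1000.0
    trial_duration_s: float = 60.0
    filter_order: int = 3
    filter_cutoff_hz: float | str = "auto"
    filter_cutoff_max_hz: float = 20.0
    psd_method: str = "periodogram"  # or "welch"
    welch_nperseg_s: float = 20.0
    band_set: tuple[tuple[float, float], ...] = DEFAULT_BANDS
    board_half_length_cm: float = DEFAULT_BOARD_HALF_LENGTH_CM
    board_half_width_cm: float = DEFAULT_BOARD_HALF_WIDTH_CM
    korff_pain_threshold: int = 1
    implausible_threshold: float = 1e6
    iqr_fence_k: float = 0.9
    split_fraction: float = 0.7
    n_repeats: int = 10
    stratified_split: bool = False
    nn_hidden: int = 3
    rf_n_trees: int = 500
    classifier_features: tuple[str, ...] = (
        "track_length_cm",
        "band_0p001_10",
        "band_0p001_4",
    )
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.trial_duration_s <= 0:
            raise ValueError("trial_duration_s must be positive")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        if isinstance(self.filter_cutoff_hz, str):
            if self.filter_cutoff_hz != "auto":
                raise ValueError("filter_cutoff_hz must be a number or 'auto'")
        elif not 0 < self.filter_cutoff_hz < self.sampling_rate_hz / 2:
            raise ValueError("filter_cutoff_hz must lie in (0, Nyquist)")
        if self.psd_method not in {"periodogram", "welch"}:
            raise ValueError("psd_method must be 'periodogram' or 'welch'")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        self.band_set = tuple((float(lo), float(hi)) for lo, hi in self.band_set)
        if not self.band_set:
            raise ValueError("band_set must not be empty")
        nyq = self.sampling_rate_hz / 2
        for lo, hi in self.band_set:
            if not 0 < lo < hi <= nyq:
                raise ValueError(
                    f"band ({lo}, {hi}) violates 0 < low < high <= Nyquist ({nyq})"
                )

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate_hz * self.trial_duration_s))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band_set"] = [list(b) for b in self.band_set]
        d["classifier_features"] = list(self.classifier_features)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "band_set" in d:
            d["band_set"] = tuple(tuple(b) for b in d["band_set"])
        if "classifier_features" in d:
            d["classifier_features"] = tuple(d["classifier_features"])
        return cls(**d)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
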