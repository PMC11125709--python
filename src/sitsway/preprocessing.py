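"""Raw force channels -> filtered CoP trajectories.

The processing order follows the acquisition pipeline: the four load-cell
channels are low-pass filtered first (zero-phase third-order Butterworth by
default), then combined into the planar centre of pressure

    x_ml = half_width  * ((TR + BR) - (TL + BL)) / total
    y_ap = half_length * ((TL + TR) - (BL + BR)) / total

per sample, in cm.  A single cohort-wide cutoff frequency is either fixed in
the config or chosen by residual analysis: for each candidate cutoff the RMS
residual between raw and filtered signal is computed; in the noise-dominated
high-cutoff region that residual decays linearly, so extrapolating a line
back to 0 Hz estimates the noise floor, and the selected cutoff is the
smallest one whose residual has fallen to that floor.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .config import PipelineConfig
from .core import CoPTrack, ForceRecording

log = logging.getLogger(__name__)


def butterworth_lowpass(
    series: np.ndarray, rate_hz: float, cutoff_hz: float, order: int = 3
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    The design magnitude response is the single-pass Butterworth one
    (-3 dB at the cutoff); applying it forward and backward squares the
    magnitude and cancels the phase, so the output has no lag.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    nyq = rate_hz / 2
    if not 0 < cutoff_hz < nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyq} Hz)")
    sos = sps.butter(order, cutoff_hz, btype="low", fs=rate_hz, output="sos")
    x = np.asarray(series, dtype=float)
    return sps.sosfiltfilt(sos, x)


def filter_recording(rec: ForceRecording, cutoff_hz: float, order: int = 3) -> ForceRecording:
    """Apply the low-pass to all four force channels."""
    filtered = np.stack(
        [butterworth_lowpass(ch, rec.rate_hz, cutoff_hz, order) for ch in rec.channels]
    )
    return ForceRecording(
        channels=filtered,
        rate_hz=rec.rate_hz,
        board_half_length_cm=rec.board_half_length_cm,
        board_half_width_cm=rec.board_half_width_cm,
        subject_id=rec.subject_id,
    )


def compute_cop(rec: ForceRecording) -> CoPTrack:
    """Centre of pressure from the four corner forces, in cm.

    Requires a loaded board: the channel sum must be positive at every
    sample.  The formula is scale-invariant in the forces (doubling all
    channels leaves the CoP unchanged).
    """
    total = rec.total_force
    bad = np.flatnonzero(total <= 0)
    if bad.size:
        raise ValueError(
            f"non-positive total load at sample {bad[0]} "
            f"(total={total[bad[0]]:.3g} N); board must be loaded throughout"
        )
    tl, tr, bl, br = rec.channels
    x = rec.board_half_width_cm * ((tr + br) - (tl + bl)) / total
    y = rec.board_half_length_cm * ((tl + tr) - (bl + br)) / total
    return CoPTrack(x_ml_cm=x, y_ap_cm=y, rate_hz=rec.rate_hz, subject_id=rec.subject_id)


def _residual_rms(x: np.ndarray, rate_hz: float, cutoff_hz: float, order: int) -> float:
    return float(np.sqrt(np.mean((x - butterworth_lowpass(x, rate_hz, cutoff_hz, order)) ** 2)))


def select_cutoff(
    recordings: Sequence[ForceRecording],
    config: PipelineConfig,
    candidate_grid_hz: Sequence[float] | None = None,
) -> float:
    """Cohort-wide low-pass cutoff.

    Returns the fixed config value when one is set; otherwise runs residual
    analysis per recording (on the raw, unfiltered CoP signal) and returns
    the cohort median of the per-recording selections.  Degenerate signals
    (constant, or no signal/noise knee) fall back to the configured maximum
    with a warning.
    """
    if not recordings:
        raise ValueError("select_cutoff needs at least one recording")
    if not isinstance(config.filter_cutoff_hz, str):
        return float(config.filter_cutoff_hz)

    fmax = min(config.filter_cutoff_max_hz, 0.45 * config.sampling_rate_hz)
    if candidate_grid_hz is None:
        candidate_grid_hz = np.arange(1.0, fmax + 1e-9, 0.5)
    grid = np.asarray(candidate_grid_hz, dtype=float)

    chosen = []
    for rec in recordings:
        track = compute_cop(rec)
        # residual analysis on both axes, combined RMS
        sel = _select_cutoff_single(
            np.column_stack([track.x_ml_cm, track.y_ap_cm]),
            rec.rate_hz,
            grid,
            config.filter_order,
            fmax,
        )
        chosen.append(sel)
    return float(np.median(chosen))


def _select_cutoff_single(
    xy: np.ndarray, rate_hz: float, grid: np.ndarray, order: int, fmax: float
) -> float:
    resid = np.empty(grid.size)
    for i, fc in enumerate(grid):
        r2 = [
            _residual_rms(xy[:, j], rate_hz, fc, order) ** 2 for j in range(xy.shape[1])
        ]
        resid[i] = np.sqrt(np.mean(r2))
    if resid[-1] <= 0 or np.ptp(resid) < 1e-12 * max(resid.max(), 1e-30):
        warnings.warn(
            "degenerate (constant or noiseless) signal; falling back to maximum cutoff",
            stacklevel=2,
        )
        return float(fmax)
    # fit the linear noise tail over the upper half of the grid
    tail = grid >= grid[grid.size // 2]
    slope, intercept = np.polyfit(grid[tail], resid[tail], 1)
    if intercept <= 0:
        warnings.warn(
            "no signal/noise knee found (noise floor extrapolates to <= 0); "
            "falling back to maximum cutoff",
            stacklevel=2,
        )
        return float(fmax)
    # no knee: for (near-)white noise the whole residual curve already lies
    # on the extrapolated noise line, so low cutoffs remove no signal
    predicted_low = intercept + slope * grid[0]
    if resid[0] <= 1.05 * predicted_low:
        warnings.warn(
            "broadband noise without a signal/noise knee; using maximum cutoff",
            stacklevel=2,
        )
        return float(fmax)
    # smallest cutoff whose residual has fallen to the extrapolated 0 Hz
    # noise floor (the classic residual-analysis criterion)
    below = np.flatnonzero(resid <= intercept)
    if below.size == 0:
        warnings.warn("residuals never reach the noise floor; using maximum cutoff", stacklevel=2)
        return float(fmax)
    return float(grid[below[0]])


def preprocess_recording(
    rec: ForceRecording, cutoff_hz: float, config: PipelineConfig
) -> CoPTrack:
    """Filter the force channels, then compute the CoP track."""
    return compute_cop(filter_recording(rec, cutoff_hz, config.filter_order))
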