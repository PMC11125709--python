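"""Per-trial scalar features of a CoP trajectory.

Features mirror the quantities a seated-posturography analysis compares
between groups:

* **track length** — total path length of the CoP over the trial (cm);
* **band-power areas** — the PSD of each axis is estimated (periodogram by
  default, Welch optional), the ML and AP densities are summed into a
  "resultant" spectrum, and the density is integrated (trapezoid) over a set
  of frequency windows; areas are in cm² since densities are cm²/Hz;
* **mean max acceleration per movement cycle** — movement cycles are
  delimited by upward zero crossings of the anteroposterior velocity; within
  each cycle the maximum resultant acceleration magnitude is taken and the
  per-cycle maxima are averaged (cm/s²);
* **ellipticity** — ratio of principal-axis standard deviations of the
  centred (x, y) point cloud; 1 for a circular sway pattern, > 1 for an
  elongated (elliptical) one.

Band edges below the first positive frequency bin (e.g. a nominal 0.001 Hz
lower edge on a 60 s trial whose resolution is 1/60 Hz) are clipped to the
first bin with a warning: such an edge means "from the lowest resolvable
frequency".
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .config import PipelineConfig
from .core import CoPTrack, FeatureVector, Spectrum

#: ellipticity returned for exactly collinear clouds when capping is enabled
ELLIPTICITY_CAP = 1e6


def track_length(track: CoPTrack) -> float:
    """Total CoP path length: sum of Euclidean step lengths, in cm."""
    if track.n_samples < 2:
        raise ValueError("track length needs at least 2 samples")
    dx = np.diff(track.x_ml_cm)
    dy = np.diff(track.y_ap_cm)
    return float(np.sum(np.hypot(dx, dy)))


def psd(
    track: CoPTrack, config: PipelineConfig | None = None
) -> dict[str, Spectrum]:
    """One-sided PSD of each axis and their sum ("resultant").

    The default estimator is the mean-detrended rectangular-window
    periodogram, for which the integral of the density over [0, Nyquist]
    equals the signal variance (Parseval).  ``psd_method='welch'`` trades
    that exactness for reduced estimator variance.
    """
    if config is None:
        config = PipelineConfig()
    x, y = track.x_ml_cm, track.y_ap_cm
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("track contains non-finite samples")

    if config.psd_method == "periodogram":
        fx, px = sps.periodogram(x, fs=track.rate_hz, window="boxcar", detrend="constant")
        fy, py = sps.periodogram(y, fs=track.rate_hz, window="boxcar", detrend="constant")
    else:
        nperseg = min(int(config.welch_nperseg_s * track.rate_hz), track.n_samples)
        fx, px = sps.welch(x, fs=track.rate_hz, nperseg=nperseg, detrend="constant")
        fy, py = sps.welch(y, fs=track.rate_hz, nperseg=nperseg, detrend="constant")

    return {
        "ML": Spectrum(fx, px, axis="ML"),
        "AP": Spectrum(fy, py, axis="AP"),
        "resultant": Spectrum(fx, px + py, axis="resultant"),
    }


def band_area(spec: Spectrum, low_hz: float, high_hz: float) -> float:
    """Integral of the density over [low_hz, high_hz) (cm²).

    Integration is at bin resolution: every frequency bin whose centre falls
    in the half-open band contributes its full density x bin-width (the
    upper band edge bin goes to the adjacent band; the Nyquist bin is
    included when the band reaches it).  This makes areas of adjacent bands
    exactly additive and the full-support area exactly equal to the signal
    variance for the rectangular-window periodogram (Parseval).

    Edges outside the spectral support are clipped (with a warning) to the
    first positive frequency bin and to the highest bin respectively; an
    empty intersection is an error.
    """
    if not low_hz < high_hz:
        raise ValueError(f"band ({low_hz}, {high_hz}): low must be < high")
    f, p = spec.freqs_hz, spec.density
    f_min = f[1] if f[0] == 0 and f.size > 1 else f[0]
    f_max = f[-1]
    lo, hi = low_hz, high_hz
    if lo < f_min:
        if hi <= f_min:
            raise ValueError(
                f"band ({low_hz}, {high_hz}) lies entirely below the spectral "
                f"support starting at {f_min:.4g} Hz"
            )
        warnings.warn(
            f"band edge {low_hz} Hz below spectral resolution; clipped to "
            f"{f_min:.4g} Hz",
            stacklevel=2,
        )
        lo = f_min
    if hi > f_max:
        if lo >= f_max:
            raise ValueError(
                f"band ({low_hz}, {high_hz}) lies entirely above the spectral "
                f"support ending at {f_max:.4g} Hz"
            )
        warnings.warn(
            f"band edge {high_hz} Hz above Nyquist; clipped to {f_max:.4g} Hz",
            stacklevel=2,
        )
        hi = f_max

    df = f[1] - f[0]
    mask = (f >= lo) & (f < hi)
    if hi >= f_max:  # band reaches the top of the support: include Nyquist
        mask |= f == f_max
    return float(np.sum(p[mask]) * df)


def _movement_cycles(v_ap: np.ndarray) -> list[tuple[int, int]]:
    """Index spans between consecutive upward zero crossings of AP velocity."""
    s = np.signbit(v_ap)
    up = np.flatnonzero(s[:-1] & ~s[1:]) + 1
    return [(a, b) for a, b in zip(up[:-1], up[1:])]


def mean_max_accel(track: CoPTrack) -> float:
    """Mean over movement cycles of each cycle's maximum acceleration (cm/s²).

    Velocity and acceleration come from second-order central differences of
    the (already filtered) track; the acceleration magnitude is the
    resultant over both axes.  A track with no complete AP-velocity cycle
    (e.g. a constant track) is an error.
    """
    if track.n_samples < 3:
        raise ValueError("acceleration needs at least 3 samples")
    dt = 1.0 / track.rate_hz
    vx = np.gradient(track.x_ml_cm, dt)
    vy = np.gradient(track.y_ap_cm, dt)
    ax = np.gradient(vx, dt)
    ay = np.gradient(vy, dt)
    accel = np.hypot(ax, ay)
    cycles = _movement_cycles(vy)
    if not cycles:
        raise ValueError("no complete movement cycle (AP velocity never oscillates)")
    return float(np.mean([accel[a:b].max() for a, b in cycles]))


def ellipticity(track: CoPTrack, cap: float | None = ELLIPTICITY_CAP) -> float:
    """Principal-axis elongation of the sway cloud: sqrt(lambda1 / lambda2).

    Eigenvalues of the 2x2 covariance of the centred (x, y) points; >= 1 by
    construction.  Degenerate clouds (zero variance on an axis) either raise
    or return ``cap`` when one is given.
    """
    if track.n_samples < 10:
        raise ValueError("ellipticity needs at least 10 samples")
    pts = track.as_array()
    pts = pts - pts.mean(axis=0)
    cov = pts.T @ pts / (pts.shape[0] - 1)
    if np.trace(cov) <= 0:
        raise ValueError("zero variance on both axes; ellipticity undefined")
    lam = np.linalg.eigvalsh(cov)  # ascending
    if lam[0] <= np.finfo(float).eps * lam[1]:
        if cap is None:
            raise ValueError("collinear track: ellipticity diverges")
        return float(cap)
    return float(np.sqrt(lam[1] / lam[0]))


def extract_features(
    track: CoPTrack, config: PipelineConfig | None = None
) -> FeatureVector:
    """All per-trial features used by the downstream statistics."""
    if config is None:
        config = PipelineConfig()
    spectra = psd(track, config)
    res = spectra["resultant"]
    with warnings.catch_warnings():
        # sub-resolution lower band edges are expected for nominal 0.001 Hz
        warnings.simplefilter("ignore")
        areas = {band: band_area(res, *band) for band in config.band_set}
    return FeatureVector(
        subject_id=track.subject_id,
        track_length_cm=track_length(track),
        band_area=areas,
        mean_max_accel_cm_s2=mean_max_accel(track),
        ellipticity=ellipticity(track),
    )
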