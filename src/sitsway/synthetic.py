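"""Synthetic two-cohort seated-sway generator.

Seated sway is modelled as a sum of narrowband stochastic oscillators — one
per anatomical pendulum (hip axis ~1.5-3 Hz, sacroiliac region ~1 Hz,
thoracic spine ~0.7-0.9 Hz) — plus a low-frequency postural drift and white
measurement noise.  Each oscillator is a constant-amplitude sinusoid whose
phase diffuses slowly, giving a Lorentzian line of the requested bandwidth
while keeping the expected power at exactly amplitude²/2.  The
anteroposterior axis is an independent realisation with amplitudes scaled by
the ellipticity, so pain-group tracks come out elongated while healthy
tracks stay near-circular.

Group defaults are calibrated so that cohort summaries reproduce the
direction and order of magnitude of the contrasts the analysis is built to
detect: pain subjects show roughly four-fold higher 0.001-10 Hz band power
(slow, large-amplitude sway) but a *shorter* CoP track (less fast corrective
activity) than healthy subjects.

Tracks are converted back to four-channel force recordings by inverting the
CoP formula with a bilinear load distribution, so synthetic data enters the
pipeline at the raw stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .config import DEFAULT_BOARD_HALF_LENGTH_CM, DEFAULT_BOARD_HALF_WIDTH_CM
from .core import GRAVITY_M_S2, CoPTrack, ForceRecording, SubjectRecord


@dataclass
class SwayModelParams:
    """Parameters of one subject's sway model.

    ``component_bands`` holds (center_freq_hz, amplitude_cm, bandwidth_hz)
    triples for the mediolateral axis; the anteroposterior axis uses the
    same components with amplitudes multiplied by ``ellipticity`` (>= 1).
    """

    component_bands: tuple[tuple[float, float, float], ...]
    ellipticity: float = 1.0
    drift_amplitude_cm: float = 0.0
    noise_sd_cm: float = 0.0
    subject_mass_kg: float = 75.8
    board_half_length_cm: float = DEFAULT_BOARD_HALF_LENGTH_CM
    board_half_width_cm: float = DEFAULT_BOARD_HALF_WIDTH_CM

    def validate(self, rate_hz: float) -> None:
        arr = np.asarray(
            [v for band in self.component_bands for v in band]
            + [
                self.ellipticity,
                self.drift_amplitude_cm,
                self.noise_sd_cm,
                self.subject_mass_kg,
            ],
            dtype=float,
        )
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite sway model parameter")
        if self.ellipticity < 1:
            raise ValueError("ellipticity must be >= 1 (AP/ML amplitude ratio)")
        if self.drift_amplitude_cm < 0 or self.noise_sd_cm < 0:
            raise ValueError("drift amplitude and noise SD must be >= 0")
        if self.subject_mass_kg <= 0:
            raise ValueError("subject mass must be positive")
        for f0, amp, bw in self.component_bands:
            if not 0 < f0 < rate_hz / 2:
                raise ValueError(f"component frequency {f0} Hz outside (0, Nyquist)")
            if amp < 0 or bw < 0:
                raise ValueError("component amplitude and bandwidth must be >= 0")


# -- group defaults -----------------------------------------------------------
#
# Healthy: moderate amplitudes spread across the pendulum bands, with enough
# content above 1 Hz to keep the path long; near-circular (ellipticity 1.1).
# Pain: a large slow component dominates (high band power); the corrective
# activity carries less power but sits at higher frequency — acceleration
# scales as omega^2 * amplitude while path length scales as omega * amplitude,
# so pain tracks come out shorter yet with higher peak accelerations —
# and the pattern is elliptical (2.0).

HEALTHY_PARAMS = SwayModelParams(
    component_bands=(
        (0.3, 0.042, 0.08),    # visual/vestibular slow sway
        (0.8, 0.055, 0.12),    # thoracic spine pendulum
        (1.0, 0.068, 0.15),    # sacroiliac pendulum
        (1.8, 0.0963, 0.35),   # hip-axis pendulum
        (2.4, 0.0591, 0.45),   # corrective muscle activity
    ),
    ellipticity=1.1,
    drift_amplitude_cm=0.03,
    noise_sd_cm=0.01,
)

PAIN_PARAMS = SwayModelParams(
    component_bands=(
        (0.25, 0.233, 0.06),   # dominant slow drift-like sway
        (0.7, 0.055, 0.10),
        (1.0, 0.030, 0.15),
        (2.8, 0.0293, 0.45),   # hip-axis pendulum, shifted up
        (4.0, 0.0136, 0.55),   # fast, low-power proprioceptive corrections
    ),
    ellipticity=2.0,
    drift_amplitude_cm=0.05,
    noise_sd_cm=0.01,
)

#: lognormal sigma of the per-subject amplitude multiplier for slow
#: (< 1 Hz) components: band power is dominated by slow sway, whose
#: between-subject spread in seated cohorts is large (power CV ~ 1)
DEFAULT_AMP_SIGMA = 0.42

#: lognormal sigma for fast (>= 1 Hz) components: corrective activity —
#: which dominates the CoP path length — varies much less between subjects
DEFAULT_FAST_AMP_SIGMA = 0.15

#: boundary between "slow" and "fast" components for the spread model [Hz]
SLOW_FAST_BOUNDARY_HZ = 1.0


@dataclass
class AnthropometryModel:
    """Per-sex Gaussian anthropometry (means/SDs of a mixed adult cohort)."""

    age_mean: float = 40.0
    age_sd: float = 17.0
    height_mean: dict = field(default_factory=lambda: {"M": 180.9, "F": 160.3})
    height_sd: dict = field(default_factory=lambda: {"M": 7.7, "F": 8.0})
    weight_mean: dict = field(default_factory=lambda: {"M": 83.9, "F": 66.1})
    weight_sd: dict = field(default_factory=lambda: {"M": 13.7, "F": 11.9})
    shoe_mean: dict = field(default_factory=lambda: {"M": 42.5, "F": 38.9})
    shoe_sd: dict = field(default_factory=lambda: {"M": 2.0, "F": 1.5})
    male_fraction: float = 0.52

    def draw(self, rng: np.random.Generator) -> dict:
        sex = "M" if rng.random() < self.male_fraction else "F"
        return {
            "sex": sex,
            "age_years": float(np.clip(rng.normal(self.age_mean, self.age_sd), 18, 60)),
            "height_cm": float(rng.normal(self.height_mean[sex], self.height_sd[sex])),
            "weight_kg": float(
                np.clip(rng.normal(self.weight_mean[sex], self.weight_sd[sex]), 40, 150)
            ),
            "shoe_size_eu": float(rng.normal(self.shoe_mean[sex], self.shoe_sd[sex])),
        }


@dataclass
class CohortSpec:
    """Specification of a labelled two-group synthetic cohort."""

    n_per_group: int = 30
    healthy_params: SwayModelParams = field(default_factory=lambda: HEALTHY_PARAMS)
    pain_params: SwayModelParams = field(default_factory=lambda: PAIN_PARAMS)
    amp_sigma: float = DEFAULT_AMP_SIGMA
    fast_amp_sigma: float = DEFAULT_FAST_AMP_SIGMA
    ellipticity_sd: float = 0.15
    anthropometry: AnthropometryModel = field(default_factory=AnthropometryModel)
    duration_s: float = 60.0
    rate_hz: float = 1000.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")


def _oscillator_bank(
    n: int,
    dt: float,
    bands: Sequence[tuple[float, float, float]],
    rng: np.random.Generator,
) -> np.ndarray:
    """Sum of constant-amplitude sinusoids with diffusing phases.

    Per component, phase-increment variance 2*pi*bw*dt per sample yields a
    Lorentzian spectral line of full width ~bw around the centre frequency;
    expected power is amp²/2 independent of bw (a pure tone when bw = 0).
    """
    k = len(bands)
    f0 = np.array([b[0] for b in bands])
    amp = np.array([b[1] for b in bands])[:, None]
    bw = np.array([b[2] for b in bands])
    t = np.arange(n) * (2.0 * np.pi * dt)
    phase = np.multiply.outer(f0, t)
    phase += rng.uniform(0.0, 2.0 * np.pi, (k, 1))
    wander = np.flatnonzero(bw > 0)
    if wander.size:
        steps = rng.normal(0.0, 1.0, (wander.size, n))
        steps *= np.sqrt(2.0 * np.pi * bw[wander] * dt)[:, None]
        np.cumsum(steps, axis=1, out=steps)
        phase[wander] += steps
    np.cos(phase, out=phase)
    phase *= amp
    return phase.sum(axis=0)


def _smooth_drift(n: int, dt: float, amplitude_cm: float, rng: np.random.Generator) -> np.ndarray:
    """Slow postural drift: integrated noise scaled to the requested RMS."""
    if amplitude_cm == 0:
        return np.zeros(n)
    walk = np.cumsum(rng.normal(0.0, 1.0, n))
    walk -= walk.mean()
    rms = np.sqrt(np.mean(walk**2))
    if rms == 0:
        return np.zeros(n)
    return amplitude_cm * walk / rms


def simulate_cop_track(
    params: SwayModelParams,
    duration_s: float,
    rate_hz: float,
    seed: int | np.random.Generator,
    subject_id: str = "",
) -> CoPTrack:
    """Simulate one seated-sway CoP trajectory.

    The ML axis sums the narrowband components, drift and noise; the AP axis
    is an independent realisation with component amplitudes scaled by
    ``params.ellipticity``.
    """
    params.validate(rate_hz)
    n = int(round(duration_s * rate_hz))
    if n < 2:
        raise ValueError("need at least 2 samples (duration_s * rate_hz >= 2)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dt = 1.0 / rate_hz

    def one_axis(scale: float) -> np.ndarray:
        bands = [(f0, scale * amp, bw) for f0, amp, bw in params.component_bands]
        out = _oscillator_bank(n, dt, bands, rng) if bands else np.zeros(n)
        out += _smooth_drift(n, dt, params.drift_amplitude_cm, rng)
        if params.noise_sd_cm > 0:
            out += rng.normal(0.0, params.noise_sd_cm, n)
        return out

    x = one_axis(1.0)
    y = one_axis(params.ellipticity)
    return CoPTrack(x_ml_cm=x, y_ap_cm=y, rate_hz=rate_hz, subject_id=subject_id)


def inverse_cop_to_forces(
    track: CoPTrack,
    mass_kg: float,
    board_half_length_cm: float = DEFAULT_BOARD_HALF_LENGTH_CM,
    board_half_width_cm: float = DEFAULT_BOARD_HALF_WIDTH_CM,
) -> ForceRecording:
    """Four corner forces whose CoP reproduces ``track`` exactly.

    Uses the bilinear load distribution

        TL = F/4 (1-u)(1+v), TR = F/4 (1+u)(1+v),
        BL = F/4 (1-u)(1-v), BR = F/4 (1+u)(1-v),

    with u = x/half_width, v = y/half_length and F the weight force, which
    satisfies the CoP formula identically and keeps the channel sum equal to
    the subject's weight at every sample.
    """
    if mass_kg <= 0:
        raise ValueError("mass must be positive")
    u = track.x_ml_cm / board_half_width_cm
    v = track.y_ap_cm / board_half_length_cm
    if np.any(np.abs(u) >= 1) or np.any(np.abs(v) >= 1):
        raise ValueError("track exceeds board half-dimensions")
    f_total = mass_kg * GRAVITY_M_S2
    q = f_total / 4.0
    channels = np.stack(
        [
            q * (1 - u) * (1 + v),  # TL
            q * (1 + u) * (1 + v),  # TR
            q * (1 - u) * (1 - v),  # BL
            q * (1 + u) * (1 - v),  # BR
        ]
    )
    return ForceRecording(
        channels=channels,
        rate_hz=track.rate_hz,
        board_half_length_cm=board_half_length_cm,
        board_half_width_cm=board_half_width_cm,
        subject_id=track.subject_id,
    )


def _perturb(
    base: SwayModelParams, spec: CohortSpec, mass_kg: float, rng: np.random.Generator
) -> SwayModelParams:
    """Per-subject parameter draw around the group baseline.

    Slow (< 1 Hz) and fast (>= 1 Hz) components get independent lognormal
    amplitude multipliers, so band power varies widely between subjects
    while path length (velocity-dominated, hence fast-component-dominated)
    stays comparatively stable — the variance structure seated cohorts show.
    """
    slow_mult = float(np.exp(rng.normal(0.0, spec.amp_sigma)))
    fast_mult = float(np.exp(rng.normal(0.0, spec.fast_amp_sigma)))
    bands = tuple(
        (f0, amp * (slow_mult if f0 < SLOW_FAST_BOUNDARY_HZ else fast_mult), bw)
        for f0, amp, bw in base.component_bands
    )
    ell = max(1.0, base.ellipticity + rng.normal(0.0, spec.ellipticity_sd))
    return replace(base, component_bands=bands, ellipticity=ell, subject_mass_kg=mass_kg)


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[SubjectRecord], list[ForceRecording]]:
    """Generate a labelled two-group cohort of raw force recordings.

    Deterministic in ``spec.rng_seed``: per-subject seeds are spawned from
    the master seed, so subject k's signal does not depend on cohort size.
    Returns (subject records, one recording per subject).
    """
    master = np.random.SeedSequence(spec.rng_seed)
    subject_seeds = master.spawn(2 * spec.n_per_group)
    records: list[SubjectRecord] = []
    recordings: list[ForceRecording] = []
    for i, seed_seq in enumerate(subject_seeds):
        is_pain = i >= spec.n_per_group
        group = "LowBackPain" if is_pain else "Healthy"
        rng = np.random.default_rng(seed_seq)
        anthro = spec.anthropometry.draw(rng)
        params = _perturb(
            spec.pain_params if is_pain else spec.healthy_params,
            spec,
            anthro["weight_kg"],
            rng,
        )
        sid = f"{'P' if is_pain else 'H'}{(i % spec.n_per_group) + 1:03d}"
        track = simulate_cop_track(params, spec.duration_s, spec.rate_hz, rng, subject_id=sid)
        rec = inverse_cop_to_forces(
            track,
            params.subject_mass_kg,
            params.board_half_length_cm,
            params.board_half_width_cm,
        )
        korff = int(rng.integers(1, 5)) if is_pain else 0
        records.append(
            SubjectRecord(
                subject_id=sid,
                pain=group,
                korff_grade=korff,
                **anthro,
            )
        )
        recordings.append(rec)
    return records, recordings
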