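"""Synthetic dipole-model ECG records with ground-truth beat annotations.

The generator stands in for multichannel clinical recordings: a single
time-varying cardiac dipole H(t) = (X, Y, Z) is synthesised as sums of
Gaussian angular bumps (one per wave P/Q/R/S/T per axis) on a per-beat
phase ramp, then projected through fixed lead-field vectors onto electrode
sites.  Named leads (Standard 12, EASI trio, the P8-P7 / V2-B8 / P8-B8
montage) are formed from the electrode potentials with the textbook lead
algebra, so Einthoven and augmented-lead identities hold exactly and every
noiseless channel is an exact rank-3 linear function of the dipole -- the
premise of linear lead reconstruction made literal.

The lead-field constants are fixture values chosen for realistic relative
morphologies (positive R in I/II/V4-V6, rS pattern in V1, negative aVR);
they are NOT physiologically calibrated against any torso model.

Beat phase is 0 at the R peak; within each RR interval the P wave of the
following beat is centred near 75 % of the interval, inside the 57.5-92 %
segmentation window.  Optional premature-ventricular-contraction beats have
no P wave, a widened QRS, a taller R and a compensatory pause.  Additive
disturbances are white Gaussian noise and a sinusoidal baseline wander.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError
from .io import (
    EASI_LEAD_DEFS,
    EcgRecord,
    LIMB_LEAD_DEFS,
    PROPOSED_LEAD_DEFS,
    derive_leads,
    precordial_lead_defs,
)

__all__ = [
    "WaveParams",
    "DipoleParams",
    "NoiseConfig",
    "BeatAnnotation",
    "LEAD_FIELD_ELECTRODES",
    "simulate_dipole",
    "project_leads",
    "add_noise",
    "make_synthetic_record",
    "SYNTHETIC_LEAD_NAMES",
    "PRESETS",
]

WAVE_ORDER = ("P", "Q", "R", "S", "T")


@dataclass(frozen=True)
class WaveParams:
    """One Gaussian bump: amplitudes per axis (mV), width and centre (rad)."""

    amplitudes: tuple[float, float, float]
    width: float
    center: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigError("wave width must be positive")
        if not (-np.pi < self.center <= 2 * np.pi):
            raise ConfigError("wave centre must lie in (-pi, 2*pi]")


#: Default wave table. Beat phase runs 0..2*pi with the R peak at 0; the
#: P bump at 0.75 of the cycle precedes the *next* beat's QRS.
_DEFAULT_WAVES: dict[str, WaveParams] = {
    "P": WaveParams((0.10, 0.06, 0.03), 0.22, 2 * np.pi * 0.75),
    "Q": WaveParams((-0.10, -0.06, 0.06), 0.07, 2 * np.pi - 0.26),
    "R": WaveParams((1.20, 0.90, -0.50), 0.08, 0.0),
    "S": WaveParams((-0.30, -0.15, 0.20), 0.08, 0.26),
    "T": WaveParams((0.40, 0.25, -0.12), 0.45, 1.70),
}


@dataclass(frozen=True)
class DipoleParams:
    """Dipole trajectory parameters: wave table, rate, HRV and ectopy."""

    waves: dict[str, WaveParams] = field(
        default_factory=lambda: dict(_DEFAULT_WAVES))
    heart_rate_bpm: float = 60.0
    hrv_fraction: float = 0.05      # fractional std of the RR interval
    pvc_probability: float = 0.0    # per-beat probability of a PVC beat

    # PVC morphology factors (fixture constants)
    pvc_qrs_width_factor: float = 2.5
    pvc_r_amp_factor: float = 1.3
    pvc_pause_factor: float = 1.5

    def __post_init__(self) -> None:
        if self.heart_rate_bpm <= 0:
            raise ConfigError("heart rate must be positive")
        if not (0 <= self.pvc_probability <= 1):
            raise ConfigError("pvc_probability must lie in [0, 1]")
        if self.hrv_fraction < 0:
            raise ConfigError("hrv_fraction must be non-negative")
        if set(self.waves) != set(WAVE_ORDER):
            raise ConfigError(f"waves must define exactly {WAVE_ORDER}")


@dataclass(frozen=True)
class NoiseConfig:
    """Additive disturbances matching ambulatory recording conditions."""

    white_noise_uv: float = 5.0
    baseline_amp_uv: float = 30.0
    baseline_freq_hz: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.white_noise_uv < 0 or self.baseline_amp_uv < 0:
            raise ConfigError("noise amplitudes must be non-negative")
        if self.baseline_freq_hz <= 0:
            raise ConfigError("baseline frequency must be positive")


@dataclass(frozen=True)
class BeatAnnotation:
    """Ground truth for one beat: R-peak sample index and beat type."""

    r_sample: int
    beat_type: str  # 'normal' or 'pvc'


#: Electrode lead-field vectors: dipole (X, Y, Z) -> electrode potential.
LEAD_FIELD_ELECTRODES: dict[str, tuple[float, float, float]] = {
    "RA": (-0.35, -0.15, 0.05),
    "LA": (0.35, -0.10, 0.00),
    "LL": (0.10, 0.55, -0.05),
    # chest electrodes = WCT + precordial lead vector
    "V1": (-0.2667, 0.05, 0.60),
    "V2": (-0.1667, 0.10, 0.75),
    "V3": (0.2333, 0.25, 0.35),
    "V4": (0.4833, 0.35, 0.25),
    "V5": (0.6833, 0.30, 0.05),
    "V6": (0.6333, 0.25, -0.10),
    # EASI montage
    "E": (0.10, -0.10, 0.50),
    "A": (0.60, 0.05, -0.15),
    "S": (-0.10, -0.60, 0.15),
    "I": (-0.50, 0.05, -0.05),
    # alternative parasternal/back montage
    "P7": (-0.20, 0.10, 0.40),
    "P8": (0.25, 0.15, 0.45),
    "B8": (-0.35, 0.00, -0.55),
}

SYNTHETIC_LEAD_NAMES: list[str] = [
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
    "ES", "AS", "AI", "P8-P7", "V2-B8", "P8-B8",
]


def simulate_dipole(
    params: DipoleParams, duration_s: float, sampling_rate: float, seed: int,
) -> tuple[np.ndarray, list[BeatAnnotation]]:
    """Simulate the 3xN dipole trajectory plus beat annotations.

    The first R peak falls half an RR interval into the record; beat phase
    ramps linearly 0..2*pi between consecutive R peaks.
    """
    fs = float(sampling_rate)
    n = int(round(duration_s * fs))
    rr_mean = 60.0 / params.heart_rate_bpm * fs
    if n < 2 * rr_mean:
        raise ConfigError("duration must cover at least two beats")
    rng = np.random.default_rng(seed)

    # beat boundaries (R-peak times, float samples); start one virtual beat
    # before the record so phase is defined from sample 0
    starts = [0.5 * rr_mean - rr_mean]
    is_pvc = [False]
    while starts[-1] < n:
        pvc = bool(rng.random() < params.pvc_probability)
        rr = rr_mean * (1.0 + params.hrv_fraction * rng.standard_normal())
        rr = max(rr, 0.3 * rr_mean)
        if is_pvc[-1]:
            rr *= params.pvc_pause_factor  # compensatory pause after a PVC
        starts.append(starts[-1] + rr)
        is_pvc.append(pvc)
    starts_a = np.asarray(starts)
    n_beats = len(starts) - 1  # intervals between consecutive R peaks

    t = np.arange(n, dtype=float)
    beat_idx = np.clip(np.searchsorted(starts_a, t, side="right") - 1,
                       0, n_beats - 1)
    rr_per_beat = np.diff(starts_a)
    phase = 2 * np.pi * (t - starts_a[beat_idx]) / rr_per_beat[beat_idx]

    pvc_flags = np.asarray(is_pvc)
    # bumps in the second half of an interval (P, Q, the left R shoulder)
    # belong to the beat whose R peak ends the interval
    owner = np.clip(beat_idx + (phase > np.pi), 0, len(pvc_flags) - 1)
    traj = np.zeros((3, n))
    for wname in WAVE_ORDER:
        w = params.waves[wname]
        amp_f = np.ones(len(pvc_flags))
        width_f = np.ones(len(pvc_flags))
        if wname == "P":
            amp_f[pvc_flags] = 0.0  # PVC beats lack a preceding P wave
        elif wname in ("Q", "R", "S"):
            width_f[pvc_flags] = params.pvc_qrs_width_factor
            if wname == "R":
                amp_f[pvc_flags] = params.pvc_r_amp_factor
        dphi = np.mod(phase - w.center + np.pi, 2 * np.pi) - np.pi
        widths = w.width * width_f[owner]
        bump = amp_f[owner] * np.exp(-0.5 * (dphi / widths) ** 2)
        for ax in range(3):
            traj[ax] += w.amplitudes[ax] * bump

    annotations = [
        BeatAnnotation(int(round(s)), "pvc" if pvc else "normal")
        for s, pvc in zip(starts[1:], is_pvc[1:])
        if 0 <= round(s) < n
    ]
    return traj, annotations


def project_leads(trajectory: np.ndarray, lead_field: dict | list,
                  sampling_rate: float = 1000.0,
                  record_id: str = "synthetic") -> EcgRecord:
    """Project a 3xN dipole trajectory through lead-field rows.

    ``lead_field`` maps channel names to 3-vectors (dict or list of
    (name, vector) pairs); each output channel is the dot product of its
    vector with the dipole, sample-wise.
    """
    traj = np.atleast_2d(np.asarray(trajectory, dtype=float))
    if traj.shape[0] != 3:
        raise ConfigError("trajectory must have 3 rows (X, Y, Z)")
    items = list(lead_field.items()) if isinstance(lead_field, dict) \
        else list(lead_field)
    names = [name for name, _ in items]
    weights = np.array([vec for _, vec in items], dtype=float)
    if weights.shape[1] != 3:
        raise ConfigError("lead-field rows must be 3-vectors")
    return EcgRecord(sampling_rate, names, weights @ traj, record_id)


def add_noise(record: EcgRecord, cfg: NoiseConfig) -> EcgRecord:
    """Add white Gaussian noise and sinusoidal baseline wander per channel."""
    rng = np.random.default_rng(cfg.seed)
    n_ch, n = record.signals.shape
    out = record.signals.copy()
    if cfg.white_noise_uv > 0:
        out += cfg.white_noise_uv / 1000.0 * rng.standard_normal((n_ch, n))
    if cfg.baseline_amp_uv > 0:
        t = np.arange(n) / record.sampling_rate
        phases = rng.uniform(0, 2 * np.pi, size=n_ch)
        out += cfg.baseline_amp_uv / 1000.0 * np.sin(
            2 * np.pi * cfg.baseline_freq_hz * t[None, :] + phases[:, None])
    return record.with_signals(out)


def _nonlinear_distort(v: np.ndarray, sat_mv: float = 0.5) -> np.ndarray:
    """Mild saturating (tanh) compression of large amplitudes."""
    return sat_mv * np.tanh(v / sat_mv)


PRESETS: dict[str, DipoleParams] = {
    "normal": DipoleParams(),
    "pvc": DipoleParams(pvc_probability=0.1),
    # same dipole as "normal"; the distortion is applied to the derived
    # precordial channels in make_synthetic_record
    "nonlinear": DipoleParams(),
}


def make_synthetic_record(
    profile: str = "normal",
    duration_s: float = 120.0,
    sampling_rate: float = 1000.0,
    noise: NoiseConfig | None = None,
    seed: int = 0,
) -> tuple[EcgRecord, list[BeatAnnotation]]:
    """Full synthetic record with 12 standard, EASI and proposed leads.

    Parameters
    ----------
    profile : {'normal', 'pvc', 'nonlinear'}
        'pvc' injects PVC-morphology beats with probability 0.1;
        'nonlinear' applies a mild saturating distortion to the precordial
        channels (so linear reconstruction is no longer exact).
    noise : NoiseConfig or None
        ``None`` applies the default ambulatory noise model (5 uV white +
        30 uV baseline wander at 0.25 Hz); pass amplitudes of 0 for a
        noiseless record.

    The dipole is scaled so the noiseless lead-II R peak is 1.0 mV.  Limb
    and augmented leads satisfy the Einthoven identities exactly before
    noise.  Returns ``(record, beat annotations)``.
    """
    if profile not in PRESETS:
        raise ConfigError(
            f"unknown preset {profile!r}; available: {sorted(PRESETS)}"
        )
    params = PRESETS[profile]
    noise = NoiseConfig(seed=seed + 1) if noise is None else noise

    traj, annotations = simulate_dipole(params, duration_s, sampling_rate,
                                        seed)
    electrodes = project_leads(traj, LEAD_FIELD_ELECTRODES, sampling_rate,
                               record_id=f"synthetic-{profile}-{seed}")
    defs = (LIMB_LEAD_DEFS + precordial_lead_defs()
            + EASI_LEAD_DEFS + PROPOSED_LEAD_DEFS)
    leads = derive_leads(electrodes, defs)

    # calibrate the R amplitude on lead II to 1.0 mV
    peak = float(np.max(leads.channel("II")))
    if peak > 0:
        leads = leads.with_signals(leads.signals / peak)

    if profile == "nonlinear":
        sig = leads.signals.copy()
        for name in ("V1", "V2", "V3", "V4", "V5", "V6"):
            k = leads.channels.index(name)
            sig[k] = _nonlinear_distort(sig[k])
        leads = leads.with_signals(sig)

    return add_noise(leads, noise), annotations
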