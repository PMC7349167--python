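"""Synthetic DEAP-shaped EEG datasets with plantable class effects.

The generator emulates the preprocessed-DEAP layout — 32 subjects x 40
trials x 32 channels x 63 s at 128 Hz, band-limited to 4-45 Hz, with a 3-s
pre-trial baseline and per-trial valence/arousal ratings on the 1-9 scale —
so every pipeline stage and both classifiers can be exercised without the
licensed download.

Each channel is zero-phase band-pass-filtered white noise.  Two optional
class-dependent components provide controllable separability:

* ``frontal_beta_arousal`` — trials rated arousal >= 5 carry an extra
  beta-band (13-30 Hz) oscillation on frontal-row electrodes, with amplitude
  ``effect_size``;
* ``alpha_asymmetry_valence`` — an alpha-band (8-13 Hz) oscillation whose
  left/right amplitude asymmetry flips sign with the binarized valence.

The placements follow conventional emotion-EEG intuition but serve purely as
planted, recoverable structure — no biological fidelity is claimed.  With
``effect_size=0`` all trials are statistically identical across classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .montage import ElectrodeMontage, default_deap_montage
from .streaming import EEGTrial

__all__ = ["SynthConfig", "generate_trial", "generate_dataset"]

#: fixed band-pass design so fixtures reproduce across platforms
_FILTER_ORDER = 6


@dataclass
class SynthConfig:
    """Dataset-shape and effect parameters (defaults mirror preprocessed DEAP)."""

    n_subjects: int = 32
    n_trials_per_subject: int = 40
    n_channels: int = 32
    sampling_rate: float = 128.0
    trial_seconds: float = 63.0
    baseline_seconds: float = 3.0
    band: tuple[float, float] = (4.0, 45.0)
    effect_size: float = 1.0
    effect_style: str = "both"  # frontal_beta_arousal | alpha_asymmetry_valence | both
    noise_scale: float = 1.0
    seed: int = 0
    quadrant_mix: Optional[tuple[float, float, float, float]] = None
    subject_gain_spread: float = 0.2

    def __post_init__(self) -> None:
        if self.trial_seconds <= self.baseline_seconds:
            raise ValueError("trial_seconds must exceed baseline_seconds")
        lo, hi = self.band
        if not (0 < lo < hi < self.sampling_rate / 2):
            raise ValueError("band must satisfy 0 < low < high < Nyquist")
        if self.effect_size < 0 or self.noise_scale < 0:
            raise ValueError("effect_size and noise_scale must be >= 0")
        if self.effect_style not in (
            "frontal_beta_arousal",
            "alpha_asymmetry_valence",
            "both",
        ):
            raise ValueError(f"unknown effect_style {self.effect_style!r}")
        if self.quadrant_mix is not None:
            if len(self.quadrant_mix) != 4 or not np.isclose(sum(self.quadrant_mix), 1.0):
                raise ValueError("quadrant_mix must be 4 probabilities summing to 1")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_seconds * self.sampling_rate))


def _band_sos(cfg: SynthConfig):
    return butter(
        _FILTER_ORDER, cfg.band, btype="bandpass", fs=cfg.sampling_rate, output="sos"
    )


def _region_channels(montage: ElectrodeMontage, cfg: SynthConfig):
    """0-based frontal / left / right channel index sets from the montage grid."""
    mid_col = (montage.grid_side - 1) / 2
    frontal, left, right = [], [], []
    for p in montage.by_channel():
        if p.channel > cfg.n_channels:
            continue
        if p.row <= 1:
            frontal.append(p.channel - 1)
        if p.col < mid_col:
            left.append(p.channel - 1)
        elif p.col > mid_col:
            right.append(p.channel - 1)
    return (np.array(frontal, dtype=int), np.array(left, dtype=int),
            np.array(right, dtype=int))


def generate_trial(
    cfg: SynthConfig,
    rng: np.random.Generator,
    valence: float,
    arousal: float,
    subject_id: str = "s01",
    trial_id: str = "t01",
    subject_gain: float = 1.0,
    montage: Optional[ElectrodeMontage] = None,
) -> EEGTrial:
    """One trial of band-limited noise plus the configured class effects."""
    if not (1.0 <= valence <= 9.0 and 1.0 <= arousal <= 9.0):
        raise ValueError("ratings must lie in [1, 9]")
    montage = montage or default_deap_montage()
    n = cfg.n_samples
    t = np.arange(n) / cfg.sampling_rate
    sos = _band_sos(cfg)
    noise = rng.standard_normal((cfg.n_channels, n))
    signal = cfg.noise_scale * sosfiltfilt(sos, noise, axis=1)
    frontal, left, right = _region_channels(montage, cfg)
    if cfg.effect_style in ("frontal_beta_arousal", "both") and arousal >= 5.0:
        f_beta = rng.uniform(13.0, 30.0)
        phase = rng.uniform(0, 2 * np.pi)
        osc = np.sin(2 * np.pi * f_beta * t + phase)
        signal[frontal] += cfg.effect_size * osc
    if cfg.effect_style in ("alpha_asymmetry_valence", "both"):
        f_alpha = rng.uniform(8.0, 13.0)
        phase = rng.uniform(0, 2 * np.pi)
        osc = cfg.effect_size * np.sin(2 * np.pi * f_alpha * t + phase)
        asym = 0.5 if valence >= 5.0 else -0.5
        signal[left] += (1.0 + asym) * osc
        signal[right] += (1.0 - asym) * osc
    return EEGTrial(
        signal=subject_gain * signal,
        sampling_rate=cfg.sampling_rate,
        subject_id=subject_id,
        trial_id=trial_id,
        valence=float(valence),
        arousal=float(arousal),
        dominance=float(rng.uniform(1, 9)),
        liking=float(rng.uniform(1, 9)),
    )


def _draw_ratings(cfg: SynthConfig, rng: np.random.Generator) -> tuple[float, float]:
    if cfg.quadrant_mix is None:
        return float(rng.uniform(1, 9)), float(rng.uniform(1, 9))
    # quadrants ordered LALV, LAHV, HALV, HAHV; low ratings in [1,5), high in [5,9]
    q = rng.choice(4, p=cfg.quadrant_mix)
    arous_high, val_high = q >= 2, q % 2 == 1
    valence = rng.uniform(5, 9) if val_high else rng.uniform(1, 5 - 1e-9)
    arousal = rng.uniform(5, 9) if arous_high else rng.uniform(1, 5 - 1e-9)
    return float(valence), float(arousal)


def generate_dataset(
    cfg: SynthConfig, montage: Optional[ElectrodeMontage] = None
) -> list[EEGTrial]:
    """n_subjects x n_trials_per_subject trials with independent random ratings.

    A per-subject amplitude gain (uniform in 1 +- subject_gain_spread) mimics
    inter-subject variability; each subject draws from its own child
    generator so subsets reproduce independently of subject order.
    """
    montage = montage or default_deap_montage()
    root = np.random.default_rng(cfg.seed)
    subject_seeds = root.integers(0, 2**31 - 1, size=cfg.n_subjects)
    trials: list[EEGTrial] = []
    for s in range(cfg.n_subjects):
        rng = np.random.default_rng(subject_seeds[s])
        gain = 1.0 + cfg.subject_gain_spread * rng.uniform(-1, 1)
        for k in range(cfg.n_trials_per_subject):
            valence, arousal = _draw_ratings(cfg, rng)
            trials.append(
                generate_trial(
                    cfg,
                    rng,
                    valence,
                    arousal,
                    subject_id=f"s{s + 1:02d}",
                    trial_id=f"s{s + 1:02d}_t{k + 1:02d}",
                    subject_gain=gain,
                    montage=montage,
                )
            )
    return trials
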