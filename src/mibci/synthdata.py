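"""Synthetic two-class motor-imagery EEG and Gaussian feature fixtures.

The trial generator emulates the statistical structure the classifier
must exploit: a mu-frequency (~10 Hz) oscillation on the lateral
sensorimotor channels C3/C4 riding on broadband Gaussian noise, with
event-related desynchronization (ERD) — a fractional amplitude drop of
``erd_depth`` — on the hemisphere *contralateral* to the imagined hand
during the imagery window. Left-hand trials (label +1) attenuate C4
(right hemisphere), right-hand trials (label -1) attenuate C3. Timing
follows the standard cue paradigm: 9-s trials at 128 Hz, imagery
sustained from second 4 to second 9.

ERD is modeled as amplitude modulation of an additive random-phase
sinusoid, not a neural-mass model: enough to create the band-power
contrast the pipeline must find, with every knob explicit. Noise is white
Gaussian by default; a 1/f ("pink") option adds realism at the cost of
simple analytic checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .eeg_io import TrialSet
from .preprocess import FeatureMatrix

__all__ = ["SynthConfig", "generate_mi_trials", "generate_gaussian_features"]


@dataclass
class SynthConfig:
    """Generator parameters; defaults give a 280-trial (140 per class)
    session matching the cue-paradigm timing."""

    n_per_class: int = 140
    channels: tuple[str, ...] = ("C3", "Cz", "C4")
    fs: float = 128.0
    duration: float = 9.0
    imagery_window: tuple[float, float] = (4.0, 9.0)
    mu_freq: float = 10.0
    mu_amp: float = 10.0        # microvolts, baseline mu amplitude
    erd_depth: float = 0.8      # fractional contralateral amplitude drop
    noise_sd: float = 5.0       # microvolts, broadband
    pink_noise: bool = False
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_per_class < 1:
            problems.append(f"n_per_class must be >= 1, got {self.n_per_class}")
        if not 0 <= self.erd_depth <= 1:
            problems.append(f"erd_depth must be in [0, 1], got {self.erd_depth}")
        for name in ("fs", "duration", "mu_freq", "mu_amp"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be > 0, got {getattr(self, name)}")
        if self.noise_sd < 0:
            problems.append(f"noise_sd must be >= 0, got {self.noise_sd}")
        t0, t1 = self.imagery_window
        if not 0 <= t0 < t1 <= self.duration:
            problems.append(
                f"imagery_window {self.imagery_window} outside [0, {self.duration}]"
            )
        if not {"C3", "C4"} <= set(self.channels):
            problems.append("channels must include C3 and C4 (the lateralized pair)")
        if problems:
            raise ValueError("; ".join(problems))


def _pink(rng: np.random.Generator, shape, fs: float) -> np.ndarray:
    """1/f-amplitude Gaussian noise, unit variance, via spectral shaping."""
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1], d=1.0 / fs)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0
    out = np.fft.irfft(spec * scale, n=shape[-1], axis=-1)
    return out / out.std(axis=-1, keepdims=True)


def generate_mi_trials(cfg: SynthConfig | None = None) -> TrialSet:
    """Two-class trials with contralateral mu ERD; deterministic per seed.

    Labels come out grouped: ``n_per_class`` left-hand (+1) trials first,
    then the right-hand (-1) trials.
    """
    cfg = cfg or SynthConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    n_samples = int(round(cfg.duration * cfg.fs))
    t = np.arange(n_samples) / cfg.fs
    in_window = (t >= cfg.imagery_window[0]) & (t < cfg.imagery_window[1])
    n_trials = 2 * cfg.n_per_class
    labels = np.concatenate(
        [np.full(cfg.n_per_class, 1), np.full(cfg.n_per_class, -1)]
    )
    i_c3 = cfg.channels.index("C3")
    i_c4 = cfg.channels.index("C4")

    data = np.zeros((n_trials, len(cfg.channels), n_samples))
    for i in range(n_trials):
        # mu oscillation with independent random phase on every channel
        for ch in range(len(cfg.channels)):
            phase = rng.uniform(0, 2 * np.pi)
            amp = np.full(n_samples, cfg.mu_amp)
            # ERD on the hemisphere contralateral to the imagined hand
            erd_ch = i_c4 if labels[i] == 1 else i_c3
            if ch == erd_ch:
                amp[in_window] *= 1.0 - cfg.erd_depth
            data[i, ch] = amp * np.sin(2 * np.pi * cfg.mu_freq * t + phase)
        if cfg.noise_sd > 0:
            shape = (len(cfg.channels), n_samples)
            noise = _pink(rng, shape, cfg.fs) if cfg.pink_noise else rng.standard_normal(shape)
            data[i] += cfg.noise_sd * noise

    return TrialSet(
        data=data,
        fs=cfg.fs,
        labels=labels,
        channel_names=list(cfg.channels),
        t0=0.0,
    )


def generate_gaussian_features(
    n_per_class: int, d: int, separation: float, seed: int = 0
) -> FeatureMatrix:
    """Two spherical unit-variance Gaussian classes.

    Class means sit ``separation`` pooled SDs apart along the first
    feature axis (+1 class at +separation/2, -1 class at -separation/2).
    ``separation=0`` gives identically distributed classes (Bayes
    accuracy 0.5); ``separation=6`` leaves < 0.3% overlap (two Phi(-3)
    tails).
    """
    if n_per_class < 1 or d < 1:
        raise ValueError(f"need n_per_class >= 1 and d >= 1, got {n_per_class}, {d}")
    if separation < 0:
        raise ValueError(f"separation must be >= 0, got {separation}")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((2 * n_per_class, d))
    X[:n_per_class, 0] += separation / 2
    X[n_per_class:, 0] -= separation / 2
    y = np.concatenate([np.full(n_per_class, 1), np.full(n_per_class, -1)])
    return FeatureMatrix(X=X, y=y)
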