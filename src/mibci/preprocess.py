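"""Filtering, epoching and feature extraction for motor-imagery trials.

The discriminative physiology is event-related desynchronization (ERD): a
drop in mu-band (~8-12 Hz) amplitude over the sensorimotor cortex
contralateral to the imagined hand. The default feature set is therefore
the log band-power (log of the within-window signal variance after
band-limiting) per channel and band, the standard statistic for ERD. A
``flatten`` mode that hands the (downsampled) raw window to the classifier
is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.signal

from .eeg_io import TrialSet

__all__ = [
    "FeatureMatrix",
    "FeatureSpec",
    "Normalizer",
    "bandpass",
    "epoch",
    "extract_features",
    "zscore_fit",
    "zscore_apply",
]

#: mu (8-12 Hz) and beta (18-26 Hz) sensorimotor bands.
DEFAULT_BANDS: tuple[tuple[float, float], ...] = ((8.0, 12.0), (18.0, 26.0))
#: Imagery window: cue at second 4, imagery sustained to the end of second 9.
DEFAULT_WINDOW: tuple[float, float] = (4.0, 9.0)


@dataclass
class FeatureMatrix:
    """N samples x d features with aligned +/-1 labels."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=np.float64))
        self.y = np.asarray(self.y, dtype=np.int64).ravel()
        self.validate()

    def validate(self) -> None:
        if self.X.ndim != 2:
            raise ValueError(f"X must be 2-D, got ndim={self.X.ndim}")
        if len(self.y) != self.X.shape[0]:
            raise ValueError(
                f"y: expected {self.X.shape[0]} labels, got {len(self.y)}"
            )
        if not np.isfinite(self.X).all():
            raise ValueError("X contains non-finite entries")
        if self.y.size and not np.isin(self.y, (1, -1)).all():
            raise ValueError("y: labels must be +1 or -1")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: np.ndarray) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return FeatureMatrix(X=self.X[idx], y=self.y[idx])


@dataclass
class FeatureSpec:
    """How to turn an epoched TrialSet into a FeatureMatrix.

    mode="bandpower": one log-variance feature per (channel, band) after
    band-limiting to each ``bands`` entry within ``window``.
    mode="flatten": the raw window, decimated by ``downsample_factor``,
    flattened channel-major.
    """

    mode: str = "bandpower"
    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS
    window: tuple[float, float] = DEFAULT_WINDOW
    downsample_factor: int = 1
    filter_order: int = 5

    def validate(self, ts: TrialSet | None = None) -> None:
        if self.mode not in ("bandpower", "flatten"):
            raise ValueError(f"mode must be 'bandpower' or 'flatten', got {self.mode!r}")
        t0, t1 = self.window
        if not t0 < t1:
            raise ValueError(f"window: need t_start < t_end, got {self.window}")
        if self.mode == "bandpower" and not self.bands:
            raise ValueError("bands: empty band list in bandpower mode")
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be a positive integer")
        if ts is not None:
            for lo, hi in self.bands if self.mode == "bandpower" else ():
                if not 0 < lo < hi < ts.fs / 2:
                    raise ValueError(
                        f"band ({lo}, {hi}) Hz outside (0, fs/2) = (0, {ts.fs / 2})"
                    )


def bandpass(ts: TrialSet, lo: float, hi: float, order: int = 5) -> TrialSet:
    """Zero-phase Butterworth bandpass of every trial and channel.

    The filter is applied forward and backward (``sosfiltfilt``), so there
    is no group delay; the effective magnitude response is the squared
    Butterworth response.
    """
    nyq = ts.fs / 2
    if not 0 <= lo < hi:
        raise ValueError(f"need 0 <= lo < hi, got lo={lo}, hi={hi}")
    if hi >= nyq:
        raise ValueError(f"hi={hi} Hz must be below the Nyquist rate {nyq} Hz")
    sos = scipy.signal.butter(order, [lo, hi], btype="bandpass", fs=ts.fs, output="sos")
    # sosfiltfilt needs more samples than its edge padding
    padlen = 3 * (2 * sos.shape[0] + 1)
    if ts.n_samples <= padlen:
        raise ValueError(
            f"trials of {ts.n_samples} samples are shorter than the filter "
            f"warm-up ({padlen} samples at order {order})"
        )
    filtered = scipy.signal.sosfiltfilt(sos, ts.data, axis=-1)
    return replace(ts, data=np.ascontiguousarray(filtered))


def epoch(ts: TrialSet, t_start: float, t_end: float) -> TrialSet:
    """Cut every trial to the window [t_start, t_end) seconds.

    Sample count of the result is round((t_end - t_start) * fs); ``t0`` is
    updated to ``t_start``.
    """
    lo, hi = ts.t0, ts.t0 + ts.duration
    if not (lo <= t_start < t_end <= hi + 1e-9):
        raise ValueError(
            f"window ({t_start}, {t_end}) s outside recorded span ({lo}, {hi}) s"
        )
    i0 = int(round((t_start - ts.t0) * ts.fs))
    count = int(round((t_end - t_start) * ts.fs))
    return replace(ts, data=ts.data[:, :, i0 : i0 + count].copy(), t0=t_start)


def extract_features(ts: TrialSet, spec: FeatureSpec | None = None) -> FeatureMatrix:
    """Turn trials into a FeatureMatrix according to ``spec``.

    bandpower mode gives d = n_channels * n_bands features: the natural log
    of the within-window variance after band-limiting each band. flatten
    mode gives d = n_channels * (window samples // downsample_factor).
    """
    spec = spec or FeatureSpec()
    spec.validate(ts)
    windowed = epoch(ts, *spec.window) if spec.window != (ts.t0, ts.t0 + ts.duration) else ts

    if spec.mode == "bandpower":
        cols = []
        for lo, hi in spec.bands:
            band = bandpass(windowed, lo, hi, order=spec.filter_order)
            var = band.data.var(axis=-1)  # (trials, channels)
            cols.append(np.log(np.maximum(var, np.finfo(float).tiny)))
        # channel-major: (ch0, band0), (ch0, band1), ..., (chC, bandB)
        X = np.stack(cols, axis=-1).reshape(ts.n_trials, -1)
    else:
        dec = windowed.data[:, :, :: spec.downsample_factor]
        X = dec.reshape(ts.n_trials, -1)
    return FeatureMatrix(X=X, y=ts.labels.copy())


@dataclass
class Normalizer:
    """Per-feature centering and scaling fitted on a training set."""

    mean: np.ndarray
    scale: np.ndarray

    @property
    def d(self) -> int:
        return self.mean.shape[0]


def zscore_fit(train: FeatureMatrix) -> Normalizer:
    """Fit per-feature mean/SD on the training set.

    Features with zero variance get scale 1 (centered only), so applying
    the normalizer never divides by zero.
    """
    if train.n < 2:
        raise ValueError(f"need at least 2 training samples to fit, got {train.n}")
    mean = train.X.mean(axis=0)
    sd = train.X.std(axis=0, ddof=0)
    scale = np.where(sd > 0, sd, 1.0)
    return Normalizer(mean=mean, scale=scale)


def zscore_apply(norm: Normalizer, fm: FeatureMatrix) -> FeatureMatrix:
    """Apply training-set statistics to ``fm`` (no refitting: leakage-free)."""
    if fm.d != norm.d:
        raise ValueError(f"normalizer expects d={norm.d}, got d={fm.d}")
    return FeatureMatrix(X=(fm.X - norm.mean) / norm.scale, y=fm.y.copy())
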