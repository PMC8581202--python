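"""Trial-level EEG container and file I/O.

Two on-disk dialects are supported:

``portable``
    An HDF5 layout owned by this package: datasets ``data`` (trials x
    channels x samples, float64 microvolts), ``labels`` (int8, +1/-1) and
    ``channel_names`` (UTF-8 strings), with scalar attributes ``fs`` (Hz)
    and ``t0`` (seconds, time of sample 0 relative to trial start).

``competition_mat``
    Best-effort reader for the Graz motor-imagery trial layout distributed
    as a MATLAB v5 ``.mat`` file (3 channels C3/Cz/C4, 9-s trials sampled
    at 128 Hz, a separate integer label vector with 1 = left, 2 = right).
    The container is identified by shape, not by variable name, and mapped
    into the portable layout with ``fs`` forced to 128 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import scipy.io

__all__ = ["TrialSet", "read_trials", "write_trials"]

#: Label encoding used throughout the package: left-hand imagery -> +1,
#: right-hand imagery -> -1.
LEFT, RIGHT = 1, -1

_COMPETITION_FS = 128.0
_COMPETITION_CHANNELS = ["C3", "Cz", "C4"]


@dataclass
class TrialSet:
    """Multichannel EEG trials with per-trial class labels.

    Attributes
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz, strictly positive.
    labels : ndarray, shape (n_trials,)
        Class of each trial, +1 (left) or -1 (right).
    channel_names : list of str
        One name per channel, in data order.
    t0 : float
        Time of sample 0 relative to trial start, in seconds.
    """

    data: np.ndarray
    fs: float
    labels: np.ndarray
    channel_names: list[str] = field(default_factory=list)
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.channel_names = [str(c) for c in self.channel_names]
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be 3-D (trials x channels x samples), got ndim={self.data.ndim}"
            )
        if self.labels.ndim != 1 or len(self.labels) != self.n_trials:
            raise ValueError(
                f"labels: expected {self.n_trials} entries (one per trial), "
                f"got {self.labels.shape}"
            )
        if self.n_trials and not np.isin(self.labels, (LEFT, RIGHT)).all():
            bad = np.unique(self.labels[~np.isin(self.labels, (LEFT, RIGHT))])
            raise ValueError(f"labels: values outside {{+1, -1}}: {bad.tolist()}")
        if not self.fs > 0:
            raise ValueError(f"fs: sampling rate must be > 0, got {self.fs}")
        if len(self.channel_names) != self.n_channels:
            raise ValueError(
                f"channel_names: expected {self.n_channels} names, "
                f"got {len(self.channel_names)}"
            )

    # -- conveniences ----------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def duration(self) -> float:
        """Trial span in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Per-sample time axis in seconds relative to trial start."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def subset(self, idx: np.ndarray) -> "TrialSet":
        """A new TrialSet restricted to the given trial indices."""
        idx = np.asarray(idx)
        return replace(self, data=self.data[idx], labels=self.labels[idx])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialSet):
            return NotImplemented
        return (
            self.data.shape == other.data.shape
            and np.array_equal(self.data, other.data)
            and np.array_equal(self.labels, other.labels)
            and self.channel_names == other.channel_names
            and self.fs == other.fs
            and self.t0 == other.t0
        )


def write_trials(ts: TrialSet, path) -> None:
    """Write a TrialSet to ``path`` in the portable HDF5 dialect.

    Lossless for 64-bit floating-point data: ``read_trials(path)`` returns
    a bitwise-identical array.
    """
    ts.validate()
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ts.data, dtype=np.float64)
        f.create_dataset("labels", data=ts.labels.astype(np.int8))
        f.create_dataset(
            "channel_names",
            data=np.array(ts.channel_names, dtype=h5py.string_dtype("utf-8")),
        )
        f.attrs["fs"] = float(ts.fs)
        f.attrs["t0"] = float(ts.t0)


def read_trials(path, dialect: str = "portable") -> TrialSet:
    """Read EEG trials from ``path``.

    Parameters
    ----------
    path : path-like
        File to read.
    dialect : {"portable", "competition_mat"}
        On-disk layout; see the module docstring.
    """
    if dialect == "portable":
        return _read_portable(path)
    if dialect == "competition_mat":
        return _read_competition_mat(path)
    raise ValueError(f"unknown dialect {dialect!r}; use 'portable' or 'competition_mat'")


def _read_portable(path) -> TrialSet:
    with h5py.File(path, "r") as f:
        for name in ("data", "labels", "channel_names"):
            if name not in f:
                raise ValueError(f"portable file missing dataset {name!r}")
        data = f["data"][()]
        labels = f["labels"][()]
        names = [c.decode() if isinstance(c, bytes) else str(c) for c in f["channel_names"][()]]
        fs = float(f.attrs["fs"])
        t0 = float(f.attrs.get("t0", 0.0))
    return TrialSet(data=data, fs=fs, labels=labels, channel_names=names, t0=t0)


def _read_competition_mat(path) -> TrialSet:
    """Map the competition's .mat trial layout into the portable one.

    Identifies the first 3-D real array as the trial tensor and the first
    1-D integer vector of matching length as the labels; axes are oriented
    so the trial axis matches the label count and the channel axis is the
    shortest remaining one.
    """
    mat = scipy.io.loadmat(path, squeeze_me=True)
    arrays = {k: np.asarray(v) for k, v in mat.items() if not k.startswith("__")}

    cube = None
    for name, a in arrays.items():
        if a.ndim == 3 and np.issubdtype(a.dtype, np.number):
            cube = (name, a.astype(np.float64))
            break
    if cube is None:
        raise ValueError("competition_mat: no 3-D numeric trial array found")
    cube_name, data = cube

    vec = None
    for name, a in arrays.items():
        if name != cube_name and a.ndim == 1 and np.issubdtype(a.dtype, np.number):
            vec = (name, np.asarray(a).ravel())
            break
    if vec is None:
        raise ValueError("competition_mat: no 1-D label vector found")
    vec_name, raw_labels = vec

    n_trials = raw_labels.size
    axes = [ax for ax, n in enumerate(data.shape) if n == n_trials]
    if not axes:
        raise ValueError(
            f"competition_mat: labels ({vec_name}, n={n_trials}) match no axis of "
            f"{cube_name} with shape {data.shape}"
        )
    trial_ax = axes[0]
    rest = [ax for ax in range(3) if ax != trial_ax]
    # channel axis is the shorter of the two non-trial axes
    chan_ax, samp_ax = sorted(rest, key=lambda ax: data.shape[ax])
    data = np.transpose(data, (trial_ax, chan_ax, samp_ax))

    uniq = np.unique(raw_labels)
    if uniq.size != 2:
        raise ValueError(
            f"competition_mat: labels ({vec_name}) must have exactly two classes, got {uniq.tolist()}"
        )
    # competition coding: 1 = left, 2 = right -> +1 / -1
    labels = np.where(raw_labels == uniq[0], LEFT, RIGHT)

    n_chan = data.shape[1]
    names = _COMPETITION_CHANNELS if n_chan == 3 else [f"ch{i}" for i in range(n_chan)]
    return TrialSet(
        data=data, fs=_COMPETITION_FS, labels=labels, channel_names=names, t0=0.0
    )
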