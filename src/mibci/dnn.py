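"""From-scratch fully connected feed-forward network.

This network exists to serve as an *explicit kernel map*: its hidden
stack, trained by plain full-batch gradient descent on a mean-squared
error, is later re-used as the feature transformation phi feeding a linear
large-margin head (see :mod:`mibci.idnn`). Forward propagation is

    a^h = sigma(W^h a^{h-1} + b^h),    a^0 = x,

the per-sample loss is J = ||a^H - y||^2 / 2, and backpropagation follows
the standard recurrences

    delta^H = (a^H - y) * sigma'(z^H),
    delta^h = (W^{h+1})^T delta^{h+1} * sigma'(z^h),
    dJ/dW^h = delta^h (a^{h-1})^T,     dJ/db^h = delta^h,

with * the elementwise (Hadamard) product.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import FeatureMatrix

__all__ = [
    "DNNParams",
    "GradientSet",
    "init_params",
    "forward",
    "mse_loss",
    "backprop",
    "train_dnn",
    "pretrain_autoencoders",
]


# -- activations ---------------------------------------------------------

def _sigmoid(z):
    # split by sign for numerical stability at large |z|
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _sigmoid_prime(z):
    s = _sigmoid(z)
    return s * (1.0 - s)


ACTIVATIONS = {
    "sigmoid": (_sigmoid, _sigmoid_prime),
    "relu": (lambda z: np.maximum(z, 0.0), lambda z: (z > 0).astype(float)),
    "identity": (lambda z: z, lambda z: np.ones_like(z)),
}


@dataclass
class DNNParams:
    """Per-layer weights and biases plus the hidden activation name.

    ``layers[h] = (W, b)`` with W of shape (n_h, n_{h-1}) and b of shape
    (n_h,); adjacent shapes must chain.
    """

    layers: list[tuple[np.ndarray, np.ndarray]]
    activation: str = "sigmoid"

    def __post_init__(self) -> None:
        self.layers = [
            (np.asarray(W, dtype=np.float64), np.asarray(b, dtype=np.float64).ravel())
            for W, b in self.layers
        ]
        self.validate()

    def validate(self) -> None:
        if self.activation not in ACTIVATIONS:
            raise ValueError(
                f"activation must be one of {sorted(ACTIVATIONS)}, got {self.activation!r}"
            )
        for h, (W, b) in enumerate(self.layers):
            if W.ndim != 2 or b.shape != (W.shape[0],):
                raise ValueError(f"layer {h}: W {W.shape} and b {b.shape} inconsistent")
            if not (np.isfinite(W).all() and np.isfinite(b).all()):
                raise ValueError(f"layer {h}: non-finite parameters")
            if h > 0 and W.shape[1] != self.layers[h - 1][0].shape[0]:
                raise ValueError(
                    f"layer {h}: expects input of size {W.shape[1]} but layer "
                    f"{h - 1} outputs {self.layers[h - 1][0].shape[0]}"
                )

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def sizes(self) -> list[int]:
        """[input dim, layer 1 width, ..., layer H width]."""
        if not self.layers:
            return []
        return [self.layers[0][0].shape[1]] + [W.shape[0] for W, _ in self.layers]

    def copy(self) -> "DNNParams":
        return DNNParams(
            layers=[(W.copy(), b.copy()) for W, b in self.layers],
            activation=self.activation,
        )


@dataclass
class GradientSet:
    """Loss gradients (dW^h, db^h), shapes mirroring a DNNParams."""

    layers: list[tuple[np.ndarray, np.ndarray]]

    def scaled(self, c: float) -> "GradientSet":
        return GradientSet([(c * dW, c * db) for dW, db in self.layers])


def init_params(
    sizes: list[int], activation: str = "sigmoid", seed: int | None = 0
) -> DNNParams:
    """Seeded uniform init scaled by 1/sqrt(fan-in).

    ``sizes`` is [d_in, n_1, ..., n_H].
    """
    rng = np.random.default_rng(seed)
    layers = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        lim = 1.0 / np.sqrt(fan_in)
        layers.append(
            (
                rng.uniform(-lim, lim, size=(fan_out, fan_in)),
                rng.uniform(-lim, lim, size=fan_out),
            )
        )
    return DNNParams(layers=layers, activation=activation)


# -- forward / loss / gradients -----------------------------------------

def _forward_full(p: DNNParams, X: np.ndarray):
    """Pre-activations and activations for a batch (N x d). a[0] is X."""
    act, _ = ACTIVATIONS[p.activation]
    zs, acts = [], [X]
    a = X
    for W, b in p.layers:
        z = a @ W.T + b
        a = act(z)
        zs.append(z)
        acts.append(a)
    return zs, acts


def forward(p: DNNParams, x: np.ndarray) -> list[np.ndarray]:
    """Activations a^1..a^H for one feature vector (or an N x d batch).

    The last entry is the network output — in IDNN use, the mapped feature
    phi(x).
    """
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if p.layers and X.shape[1] != p.layers[0][0].shape[1]:
        raise ValueError(
            f"input dimension {X.shape[1]} does not match first layer "
            f"({p.layers[0][0].shape[1]})"
        )
    _, acts = _forward_full(p, X)
    out = acts[1:]
    return [a[0] for a in out] if single else out


def mse_loss(aH: np.ndarray, y: np.ndarray) -> float:
    """Half squared Euclidean distance between output and target."""
    aH = np.asarray(aH, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if aH.shape != y.shape:
        raise ValueError(f"shape mismatch: output {aH.shape} vs target {y.shape}")
    diff = aH - y
    return 0.5 * float(np.sum(diff * diff))


def backprop(p: DNNParams, x: np.ndarray, y: np.ndarray) -> GradientSet:
    """Gradients of the half-squared-error loss for one sample."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    grads, _ = _batch_gradients(p, x[None, :], y[None, :], mean=False)
    return grads


def _batch_gradients(p: DNNParams, X: np.ndarray, T: np.ndarray, mean: bool = True):
    """(GradientSet, loss) over a batch; gradients summed or averaged."""
    _, dact = ACTIVATIONS[p.activation]
    zs, acts = _forward_full(p, X)
    n = X.shape[0]
    scale = 1.0 / n if mean else 1.0

    diff = acts[-1] - T
    with np.errstate(over="ignore"):  # divergence is caught via isfinite
        loss = 0.5 * float(np.sum(diff * diff)) * scale
        delta = diff * dact(zs[-1])
    grads: list[tuple[np.ndarray, np.ndarray]] = [None] * p.n_layers
    for h in range(p.n_layers - 1, -1, -1):
        grads[h] = (scale * delta.T @ acts[h], scale * delta.sum(axis=0))
        if h > 0:
            delta = (delta @ p.layers[h][0]) * dact(zs[h - 1])
    return GradientSet(layers=grads), loss


def train_dnn(
    p: DNNParams,
    fm: FeatureMatrix | np.ndarray,
    targets: np.ndarray,
    lr: float = 0.07,
    iters: int = 2500,
    batch_size: int | None = None,
    seed: int | None = None,
) -> tuple[DNNParams, np.ndarray]:
    """Gradient-descent training on the mean of the per-sample MSE loss.

    Full-batch by default; ``batch_size`` turns on seeded mini-batching.
    Returns the updated parameters and the per-iteration training loss
    (evaluated on the full batch before each step). ``iters=0`` returns a
    copy of the initialization and an empty loss record.
    """
    if lr <= 0:
        raise ValueError(f"lr must be > 0, got {lr}")
    if iters < 0:
        raise ValueError(f"iters must be >= 0, got {iters}")
    X = fm.X if isinstance(fm, FeatureMatrix) else np.asarray(fm, dtype=np.float64)
    T = np.atleast_2d(np.asarray(targets, dtype=np.float64))
    if T.shape[0] != X.shape[0]:
        raise ValueError(f"targets: expected {X.shape[0]} rows, got {T.shape[0]}")

    p = p.copy()
    losses = np.empty(iters)
    rng = np.random.default_rng(seed)
    for it in range(iters):
        if batch_size is None:
            grads, loss = _batch_gradients(p, X, T, mean=True)
        else:
            _, loss = _batch_gradients(p, X, T, mean=True)
            idx = rng.choice(X.shape[0], size=min(batch_size, X.shape[0]), replace=False)
            grads, _ = _batch_gradients(p, X[idx], T[idx], mean=True)
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite training loss at iteration {it}")
        losses[it] = loss
        p.layers = [
            (W - lr * dW, b - lr * db)
            for (W, b), (dW, db) in zip(p.layers, grads.layers)
        ]
    return p, losses


def pretrain_autoencoders(
    sizes: list[int],
    X: np.ndarray,
    activation: str = "sigmoid",
    lr: float = 0.07,
    iters: int = 200,
    seed: int | None = 0,
) -> DNNParams:
    """Greedy layer-wise autoencoder pretraining of a hidden stack.

    Each hidden layer is initialized as the encoder of a one-hidden-layer
    autoencoder trained to reconstruct its input under the MSE loss; the
    encoded data then feeds the next layer. Off by default in the pipeline
    (no specific unsupervised scheme is mandated by the method), provided
    for users who want warm-started hidden weights.
    """
    rng = np.random.default_rng(seed)
    layers = []
    data = np.asarray(X, dtype=np.float64)
    for d_in, d_out in zip(sizes[:-1], sizes[1:]):
        ae = init_params([d_in, d_out, d_in], activation, seed=int(rng.integers(2**31)))
        ae, _ = train_dnn(ae, data, data, lr=lr, iters=iters)
        layers.append(ae.layers[0])
        enc = DNNParams(layers=[ae.layers[0]], activation=activation)
        data = forward(enc, data)[-1]
    return DNNParams(layers=layers, activation=activation)
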