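"""IDNN: a feed-forward hidden stack as explicit kernel map, with an
LM_SVM output head.

The network has an input layer and r hidden layers but *no* output layer:
classification is done by the large-margin-distribution SVM on the last
hidden activation. Training is staged:

  Stage A  pretrain the hidden stack with a temporary linear-output head
           under the MSE loss on one-hot class targets (full-batch
           gradient descent);
  Stage B  discard the temporary head, push all training inputs through
           the hidden stack to get the mapped features Phi, and fit the
           LM_SVM head on Phi;
  Stage C  (optional, ``joint_finetune``) a few further gradient steps on
           the combined LM_SVM primal, backpropagated through the map.

With ``hidden_units=()`` the map is the identity and the model reduces to
a linear LM_SVM on the (normalized) input features — the configuration
used to cross-check the whole path against the standalone solver.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import h5py
import numpy as np

from . import dnn, lmsvm
from .preprocess import FeatureMatrix, Normalizer, zscore_apply, zscore_fit

__all__ = ["IDNNConfig", "IDNNModel", "fit_idnn", "predict_idnn", "save_idnn", "load_idnn"]

#: One-hot target encoding for Stage A: column 0 <-> label +1 (left),
#: column 1 <-> label -1 (right).
_CLASS_ORDER = (1, -1)


@dataclass
class IDNNConfig:
    """Training configuration; defaults are the selected operating point
    (two hidden layers of (11, 6) units, lr 0.07, 2500 iterations,
    lambda 0.1)."""

    hidden_units: tuple[int, ...] = (11, 6)
    activation: str = "sigmoid"
    lr: float = 0.07
    iters: int = 2500
    C: float = 1.0
    lam: float = 0.1
    seed: int = 0
    normalize: bool = True
    pretrain_autoencoder: bool = False
    joint_finetune: bool = False
    finetune_iters: int = 100
    finetune_lr: float = 0.01

    def validate(self) -> None:
        problems = []
        if any(u < 1 for u in self.hidden_units):
            problems.append(f"hidden_units: every width must be >= 1, got {self.hidden_units}")
        if self.lr <= 0:
            problems.append(f"lr must be > 0, got {self.lr}")
        if self.iters < 0:
            problems.append(f"iters must be >= 0, got {self.iters}")
        if self.C <= 0:
            problems.append(f"C must be > 0, got {self.C}")
        if self.lam < 0:
            problems.append(f"lam must be >= 0, got {self.lam}")
        if self.activation not in dnn.ACTIVATIONS:
            problems.append(f"activation: unknown {self.activation!r}")
        if problems:
            raise ValueError("; ".join(problems))


@dataclass
class IDNNModel:
    """Fitted map + head + normalizer, with the config echoed for
    reproducible retraining."""

    phi: dnn.DNNParams
    head: lmsvm.LMSVMModel
    normalizer: Normalizer | None
    config: IDNNConfig
    train_accuracy: float = np.nan
    pretrain_losses: np.ndarray = field(default_factory=lambda: np.empty(0))


def _one_hot(y: np.ndarray) -> np.ndarray:
    T = np.zeros((y.size, len(_CLASS_ORDER)))
    for j, c in enumerate(_CLASS_ORDER):
        T[y == c, j] = 1.0
    return T


def _map_features(phi: dnn.DNNParams, X: np.ndarray) -> np.ndarray:
    if phi.n_layers == 0:
        return X
    return dnn.forward(phi, X)[-1]


def fit_idnn(fm: FeatureMatrix, cfg: IDNNConfig | None = None) -> IDNNModel:
    """Staged training of map and head on a labeled feature matrix."""
    cfg = cfg or IDNNConfig()
    cfg.validate()
    if np.unique(fm.y).size < 2:
        raise ValueError("training data must contain both classes")

    norm = zscore_fit(fm) if cfg.normalize else None
    work = zscore_apply(norm, fm) if norm is not None else fm
    X, y = work.X, work.y

    sizes = [work.d, *cfg.hidden_units]
    losses = np.empty(0)
    if cfg.hidden_units:
        # Stage A: temporary linear-output head, MSE on one-hot targets
        if cfg.pretrain_autoencoder:
            stack = dnn.pretrain_autoencoders(
                sizes, X, cfg.activation, lr=cfg.lr, seed=cfg.seed
            )
            head_init = dnn.init_params(
                [cfg.hidden_units[-1], len(_CLASS_ORDER)], cfg.activation, seed=cfg.seed
            )
            p = dnn.DNNParams(
                layers=stack.layers + head_init.layers, activation=cfg.activation
            )
        else:
            p = dnn.init_params(
                sizes + [len(_CLASS_ORDER)], cfg.activation, seed=cfg.seed
            )
        p, losses = dnn.train_dnn(p, X, _one_hot(y), lr=cfg.lr, iters=cfg.iters)
        # Stage B: head-swap — keep only the hidden stack
        phi = dnn.DNNParams(layers=p.layers[:-1], activation=cfg.activation)
    else:
        phi = dnn.DNNParams(layers=[], activation=cfg.activation)

    Phi = _map_features(phi, X)
    head = lmsvm.fit_lmsvm(Phi, y, C=cfg.C, lam=cfg.lam)

    if cfg.joint_finetune and cfg.hidden_units:
        phi, head = _joint_finetune(phi, head, X, y, cfg)

    model = IDNNModel(phi=phi, head=head, normalizer=norm, config=cfg)
    pred = predict_idnn(model, fm)[0]
    model.train_accuracy = float(np.mean(pred == fm.y))
    model.pretrain_losses = losses
    return model


def _joint_finetune(phi, head, X, y, cfg: IDNNConfig):
    """Stage C: subgradient steps on the LM_SVM primal through the map.

    The primal's sensitivity to the mapped feature of sample i is
    d obj / d phi_i = (-2C xi_i - lam/N) y_i w, which enters the hidden
    stack exactly like an output-layer error signal.
    """
    w, b = head.w.copy(), head.b
    n = y.size
    for _ in range(cfg.finetune_iters):
        zs, acts = dnn._forward_full(phi, X)
        Phi = acts[-1]
        f = Phi @ w + b
        xi = np.maximum(0.0, 1.0 - y * f)
        gf = -2.0 * cfg.C * xi * y - (cfg.lam / n) * y
        gw = w + Phi.T @ gf
        gb = float(np.sum(gf))
        # error signal entering the top of the hidden stack
        dact = dnn.ACTIVATIONS[cfg.activation][1]
        delta = np.outer(gf, w) * dact(zs[-1])
        new_layers = list(phi.layers)
        for h in range(phi.n_layers - 1, -1, -1):
            dW = delta.T @ acts[h] / n
            db = delta.sum(axis=0) / n
            new_layers[h] = (phi.layers[h][0] - cfg.finetune_lr * dW,
                             phi.layers[h][1] - cfg.finetune_lr * db)
            if h > 0:
                delta = (delta @ phi.layers[h][0]) * dact(zs[h - 1])
        phi = dnn.DNNParams(layers=new_layers, activation=cfg.activation)
        w = w - cfg.finetune_lr * gw / n
        b = b - cfg.finetune_lr * gb / n
    Phi = _map_features(phi, X)
    # re-solve the head at the final map so diagnostics stay exact
    head = lmsvm.fit_lmsvm(Phi, y, C=cfg.C, lam=cfg.lam)
    return phi, head


def predict_idnn(m: IDNNModel, fm: FeatureMatrix | np.ndarray):
    """(labels, scores) for a FeatureMatrix or raw N x d array.

    normalizer -> hidden stack forward -> LM_SVM decision function;
    deterministic.
    """
    X = fm.X if isinstance(fm, FeatureMatrix) else np.atleast_2d(np.asarray(fm, float))
    if m.normalizer is not None:
        if X.shape[1] != m.normalizer.d:
            raise ValueError(f"model expects d={m.normalizer.d}, got d={X.shape[1]}")
        X = (X - m.normalizer.mean) / m.normalizer.scale
    Phi = _map_features(m.phi, X)
    scores = lmsvm.decision_function(m.head, Phi)
    return np.where(scores >= 0, 1, -1), scores


# -- serialization -------------------------------------------------------

def save_idnn(m: IDNNModel, path) -> None:
    """One portable HDF5 file holding map, head, normalizer and config."""
    with h5py.File(path, "w") as f:
        g = f.create_group("phi")
        g.attrs["activation"] = m.phi.activation
        g.attrs["n_layers"] = m.phi.n_layers
        for h, (W, b) in enumerate(m.phi.layers):
            g.create_dataset(f"W{h}", data=W)
            g.create_dataset(f"b{h}", data=b)
        g = f.create_group("head")
        g.create_dataset("w", data=m.head.w)
        g.attrs["b"] = m.head.b
        g.attrs["C"] = m.head.C
        g.attrs["lam"] = m.head.lam
        if m.normalizer is not None:
            g = f.create_group("normalizer")
            g.create_dataset("mean", data=m.normalizer.mean)
            g.create_dataset("scale", data=m.normalizer.scale)
        cfg = asdict(m.config)
        cfg["hidden_units"] = list(cfg["hidden_units"])
        f.attrs["config"] = json.dumps(cfg, sort_keys=True)
        f.attrs["train_accuracy"] = m.train_accuracy


def load_idnn(path) -> IDNNModel:
    """Inverse of :func:`save_idnn`; round-trips to identical predictions."""
    with h5py.File(path, "r") as f:
        g = f["phi"]
        layers = [
            (g[f"W{h}"][()], g[f"b{h}"][()]) for h in range(int(g.attrs["n_layers"]))
        ]
        phi = dnn.DNNParams(layers=layers, activation=str(g.attrs["activation"]))
        g = f["head"]
        head = lmsvm.LMSVMModel(
            w=g["w"][()],
            b=float(g.attrs["b"]),
            C=float(g.attrs["C"]),
            lam=float(g.attrs["lam"]),
        )
        norm = None
        if "normalizer" in f:
            norm = Normalizer(
                mean=f["normalizer"]["mean"][()], scale=f["normalizer"]["scale"][()]
            )
        raw = json.loads(f.attrs["config"])
        raw["hidden_units"] = tuple(raw["hidden_units"])
        cfg = IDNNConfig(**raw)
        acc = float(f.attrs["train_accuracy"])
    return IDNNModel(phi=phi, head=head, normalizer=norm, config=cfg, train_accuracy=acc)
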