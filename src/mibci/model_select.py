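"""Evaluation metric, the random half split, and hyperparameter search.

The metric is plain classification accuracy

    Acc = (TP + TN) / (TP + TN + FN + FP),

evaluated in exact rational arithmetic before conversion to float. Model
selection mirrors the experimental protocol: a stratified random 50/50
split of the trials (train half class-balanced), a greedy layer-by-layer
sweep over hidden-layer widths, then sweeps over learning rate and the
margin-mean weight lambda, each cell trained for a fixed iteration budget
and scored on the held-out half.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
import pandas as pd

from .idnn import IDNNConfig, fit_idnn, predict_idnn
from .preprocess import FeatureMatrix

__all__ = [
    "ConfusionCounts",
    "GridSpec",
    "GridSearchResult",
    "accuracy",
    "confusion_from_predictions",
    "accuracy_from_predictions",
    "split_half",
    "split_half_indices",
    "kfold_indices",
    "grid_search",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with +1 as the positive class."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / total, exact rational before float conversion."""
    if c.total == 0:
        raise ValueError("accuracy undefined for zero total count")
    return float(Fraction(c.TP + c.TN, c.total))


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true).ravel()
    y_pred = np.asarray(y_pred).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == -1) & (y_pred == -1))),
        FP=int(np.sum((y_true == -1) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == -1))),
    )


def accuracy_from_predictions(y_true, y_pred) -> float:
    return accuracy(confusion_from_predictions(y_true, y_pred))


def split_half_indices(labels, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random 50/50 split; returns (train_idx, test_idx).

    Each class contributes floor(n_c / 2) trials to the training half (so
    the train half is class-balanced when the classes are balanced); any
    odd leftover trial goes to the test half. The two index sets are
    disjoint, exhaustive, sorted and reproducible from ``seed``.
    """
    labels = np.asarray(labels).ravel()
    rng = np.random.default_rng(seed)
    train, test = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size < 2:
            raise ValueError(f"class {c} has fewer than 2 samples")
        perm = rng.permutation(idx)
        half = idx.size // 2
        train.append(perm[:half])
        test.append(perm[half:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def split_half(obj, seed: int):
    """Stratified half split of a TrialSet or FeatureMatrix."""
    labels = obj.y if isinstance(obj, FeatureMatrix) else obj.labels
    tr, te = split_half_indices(labels, seed)
    return obj.subset(tr), obj.subset(te)


def kfold_indices(labels, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold alternative to the single half split.

    Returns k (train_idx, test_idx) pairs; every index appears in exactly
    one test fold and folds are class-stratified up to rounding.
    """
    labels = np.asarray(labels).ravel()
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for c in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == c))
        if idx.size < k:
            raise ValueError(f"class {c} has fewer than k={k} samples")
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    out = []
    all_idx = np.arange(labels.size)
    for f in folds:
        test = np.sort(np.array(f))
        out.append((np.setdiff1d(all_idx, test), test))
    return out


@dataclass
class GridSpec:
    """Search space for :func:`grid_search`.

    ``widths`` x depths 1..``max_depth`` are explored greedily: the width
    of each new layer is swept while earlier layers keep their selected
    best widths. ``lrs`` and ``lams`` are then swept at the chosen
    architecture; empty lists skip those stages.
    """

    widths: tuple[int, ...] = tuple(range(5, 13))
    max_depth: int = 5
    lrs: tuple[float, ...] = ()
    lams: tuple[float, ...] = ()
    iters: int = 2500


@dataclass
class GridSearchResult:
    """All evaluated cells plus the selected configuration.

    ``records``: one dict per cell with stage, depth, units, lr, lam,
    accuracy (NaN on failure) and error message. ``best`` holds the
    winning (units, lr, lam) and its held-out accuracy; ``tie_break``
    records how the winner was chosen.
    """

    records: list[dict] = field(default_factory=list)
    best: dict = field(default_factory=dict)
    tie_break: str = ""

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.records)
        df["units"] = df["units"].map(lambda u: "x".join(map(str, u)))
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _rank_key(rec: dict):
    # max accuracy; ties -> fewer layers, fewer total units, lower lr, lower lam
    return (
        -rec["accuracy"],
        len(rec["units"]),
        sum(rec["units"]),
        rec["lr"],
        rec["lam"],
    )


def grid_search(
    fm: FeatureMatrix,
    grid: GridSpec | None = None,
    seed: int = 0,
    base_cfg: IDNNConfig | None = None,
) -> GridSearchResult:
    """Greedy protocol over architecture, then learning rate, then lambda.

    Every cell trains an IDNN with ``grid.iters`` iterations on the
    training half and scores accuracy on the test half; training failures
    are recorded per cell and the search continues (a fully failed grid
    raises). Fixed ``seed`` makes the whole search, including tie-breaks,
    reproducible.
    """
    grid = grid or GridSpec()
    base = base_cfg or IDNNConfig()
    if not grid.widths and not grid.lrs and not grid.lams:
        raise ValueError("empty grid")
    train, test = split_half(fm, seed)
    result = GridSearchResult()

    def eval_cell(stage, units, lr, lam):
        cfg = replace(
            base, hidden_units=tuple(units), lr=lr, lam=lam,
            iters=grid.iters, seed=seed,
        )
        rec = {
            "stage": stage, "depth": len(units), "units": tuple(units),
            "lr": lr, "lam": lam, "accuracy": np.nan, "error": "",
        }
        try:
            model = fit_idnn(train, cfg)
            pred = predict_idnn(model, test)[0]
            rec["accuracy"] = accuracy_from_predictions(test.y, pred)
        except Exception as exc:  # noqa: BLE001 - recorded per cell
            rec["error"] = f"{type(exc).__name__}: {exc}"
        result.records.append(rec)
        return rec

    # Stage 1: greedy layer-by-layer width selection
    chosen_units: list[int] = list(base.hidden_units)
    lr, lam = base.lr, base.lam
    if grid.widths:
        prefix: list[int] = []
        arch_cells = []
        for _depth in range(1, grid.max_depth + 1):
            layer_cells = [
                eval_cell("architecture", prefix + [wd], lr, lam) for wd in grid.widths
            ]
            ok = [r for r in layer_cells if not r["error"]]
            if not ok:
                break
            best_layer = min(ok, key=_rank_key)
            prefix = prefix + [best_layer["units"][-1]]
            arch_cells.extend(layer_cells)
        ok = [r for r in arch_cells if not r["error"]]
        if not ok:
            raise RuntimeError("grid search failed in every architecture cell")
        chosen_units = list(min(ok, key=_rank_key)["units"])

    # Stage 2: learning-rate sweep at the chosen architecture
    if grid.lrs:
        cells = [eval_cell("lr", chosen_units, v, lam) for v in grid.lrs]
        ok = [r for r in cells if not r["error"]]
        if ok:
            lr = min(ok, key=_rank_key)["lr"]

    # Stage 3: lambda sweep
    if grid.lams:
        cells = [eval_cell("lambda", chosen_units, lr, v) for v in grid.lams]
        ok = [r for r in cells if not r["error"]]
        if ok:
            lam = min(ok, key=_rank_key)["lam"]

    ok = [r for r in result.records if not r["error"]]
    if not ok:
        raise RuntimeError("grid search failed in every cell")
    # best = argmax-accuracy cell over everything evaluated
    winner = min(ok, key=_rank_key)
    result.best = {
        "units": winner["units"],
        "lr": winner["lr"],
        "lam": winner["lam"],
        "accuracy": winner["accuracy"],
    }
    result.tie_break = (
        "max accuracy; ties broken by fewer layers, then fewer total units, "
        "then lower learning rate, then lower lambda"
    )
    return result
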