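"""Seeded minibatch training, k-fold cross-validation and checkpoints.

Reproducibility contract: the shuffle RNG for epoch ``e`` of worker ``w``
(worker 0 = centralized training, client ids in federated runs) is
``np.random.default_rng([seed, w, e])``, so two runs with the same seed and
config produce bit-identical parameter trajectories, and a single federated
client with id 0 replays the centralized shuffle stream exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import Model
from .nn import Adam, WeightedCrossEntropyLoss
from .nn.loss import NOT_SUITABLE


@dataclass(frozen=True)
class LossSpec:
    """lambda_fn >= 1 multiplies the not-suitable class weight; 1 = plain CE."""

    lambda_fn: float = 1.0

    def __post_init__(self) -> None:
        if self.lambda_fn < 1.0:
            raise ValueError("lambda_fn must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    lr: float = 1e-3
    betas: tuple[float, float] = (0.9, 0.999)
    eps: float = 1e-8
    batch_size: int = 32
    folds: int = 5
    split_ratio: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError("split_ratio must be in (0, 1)")


@dataclass
class TrainResult:
    model: Model
    history: pd.DataFrame
    optimizer: Adam = field(repr=False, default=None)  # type: ignore[assignment]


def _metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    acc = float(np.mean(y_true == y_pred))
    actual_pos = y_true == NOT_SUITABLE
    if actual_pos.any():
        fn_rate = float(np.mean(y_pred[actual_pos] != NOT_SUITABLE))
    else:
        fn_rate = float("nan")
    return acc, fn_rate


def train_model(
    X: np.ndarray,
    y: np.ndarray,
    model: Model,
    config: TrainConfig,
    loss_spec: LossSpec = LossSpec(),
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    worker_id: int = 0,
    epoch_offset: int = 0,
    optimizer: Adam | None = None,
) -> TrainResult:
    """Train in place; returns the model plus a per-epoch history frame.

    ``epoch_offset`` shifts the shuffle-RNG epoch index so federated rounds
    continue the same deterministic stream instead of replaying epoch 0.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if len(X) == 0:
        raise ValueError("empty dataset")
    if len(np.unique(y)) < 2:
        raise ValueError("dataset contains a single class; need both labels")
    loss_fn = WeightedCrossEntropyLoss(loss_spec.lambda_fn)
    opt = optimizer or Adam(lr=config.lr, betas=config.betas, eps=config.eps)

    rows = []
    for local_epoch in range(config.epochs):
        epoch = epoch_offset + local_epoch
        rng = np.random.default_rng([config.seed, worker_id, epoch])
        order = rng.permutation(len(X))
        losses, preds, truth = [], [], []
        for i in range(0, len(X), config.batch_size):
            idx = order[i : i + config.batch_size]
            logits = model.forward_logits(X[idx], train=True)
            loss, probs = loss_fn.forward(logits, y[idx])
            model.net.backward(loss_fn.backward())
            opt.step(model.net.named_params(), model.net.named_grads())
            losses.append(loss * len(idx))
            preds.append(probs.argmax(axis=1))
            truth.append(y[idx])
        acc, fn_rate = _metrics(np.concatenate(truth), np.concatenate(preds))
        rows.append({"epoch": epoch, "split": "train",
                     "loss": float(np.sum(losses) / len(X)),
                     "accuracy": acc, "fn_rate": fn_rate})
        if X_val is not None and len(X_val):
            probs = model.predict_proba(X_val)
            vloss, _ = loss_fn.forward(np.log(np.clip(probs, 1e-12, None)), np.asarray(y_val))
            vacc, vfn = _metrics(np.asarray(y_val), probs.argmax(axis=1))
            rows.append({"epoch": epoch, "split": "val", "loss": vloss,
                         "accuracy": vacc, "fn_rate": vfn})
    history = pd.DataFrame(rows, columns=["epoch", "split", "loss", "accuracy", "fn_rate"])
    return TrainResult(model=model, history=history, optimizer=opt)


def kfold_indices(n: int, folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Disjoint test folds over a seeded permutation; train = complement."""
    order = np.random.default_rng([seed, 997]).permutation(n)
    chunks = np.array_split(order, folds)
    out = []
    for f in range(folds):
        test = chunks[f]
        train = np.concatenate([chunks[g] for g in range(folds) if g != f])
        out.append((train, test))
    return out


def split_train_test(n: int, ratio: float, seed: int,
                     labels: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Seeded 8:2-style holdout split, shared by centralized and FL runs.

    With ``labels`` the split is stratified per class, so a balanced pool
    stays exactly balanced on both sides.
    """
    rng = np.random.default_rng([seed, 131])
    if labels is None:
        order = rng.permutation(n)
        cut = int(round(n * ratio))
        return order[:cut], order[cut:]
    labels = np.asarray(labels)
    train_parts, test_parts = [], []
    for c in np.unique(labels):
        idx = np.where(labels == c)[0]
        idx = idx[rng.permutation(len(idx))]
        cut = int(round(len(idx) * ratio))
        train_parts.append(idx[:cut])
        test_parts.append(idx[cut:])
    train = np.concatenate(train_parts)
    test = np.concatenate(test_parts)
    return train[rng.permutation(len(train))], test[rng.permutation(len(test))]


def cross_validate(X, y, model_builder, config: TrainConfig,
                   loss_spec: LossSpec = LossSpec()) -> pd.DataFrame:
    """k-fold CV: fresh model per fold, returns per-fold accuracy / fn_rate."""
    rows = []
    for fold, (tr, te) in enumerate(kfold_indices(len(X), config.folds, config.seed)):
        model = model_builder(seed=config.seed + fold)
        train_model(X[tr], y[tr], model, config, loss_spec)
        y_pred = model.predict(X[te])
        acc, fn_rate = _metrics(y[te], y_pred)
        rows.append({"fold": fold, "accuracy": acc, "fn_rate": fn_rate,
                     "n_train": len(tr), "n_test": len(te)})
    return pd.DataFrame(rows)


def save_checkpoint(model: Model, path, config: dict | None = None,
                    seed: int | None = None) -> None:
    """npz of named tensors (incl. ``qdi.theta``) + JSON sidecar."""
    import pathlib

    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.get_weights())
    sidecar = {
        "kind": model.kind,
        "class_convention": {"suitable": 0, "not-suitable": 1,
                             "positive_class": "not-suitable"},
        "config": config or {},
        "seed": seed,
        "numpy_version": np.__version__,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(model: Model, path) -> Model:
    with np.load(path) as npz:
        model.set_weights({k: npz[k] for k in npz.files})
    return model
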