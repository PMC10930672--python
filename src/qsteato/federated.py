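"""Horizontal federated-learning simulation.

Sequential in-process clients exchange only :class:`ModelWeights` with the
aggregation step (no image arrays cross the client boundary); the default
strategy is vanilla federated averaging, which with the equal shard sizes
used throughout equals the plain per-tensor mean.  Every client participates
in every round; local Adam state is reset each round.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datasynth import DatasetManifest
from .models import Model
from .training import LossSpec, TrainConfig, _metrics, split_train_test, train_model

__all__ = [
    "FLConfig",
    "ModelWeights",
    "partition_dataset",
    "fedavg_aggregate",
    "run_federated",
    "client_grid_experiment",
]


@dataclass(frozen=True)
class FLConfig:
    n_clients: int = 4
    samples_per_client: int | None = None  # None: split everything evenly
    rounds: int = 15
    local_epochs: int = 1
    seed: int = 0
    aggregation: str = "size-weighted-mean"

    def __post_init__(self) -> None:
        if self.n_clients < 1:
            raise ValueError("n_clients must be >= 1")
        if self.rounds < 0:
            raise ValueError("rounds must be >= 0")
        if self.local_epochs < 1:
            raise ValueError("local_epochs must be >= 1")
        if self.aggregation != "size-weighted-mean":
            raise ValueError(f"unknown aggregation {self.aggregation!r}")


@dataclass
class ModelWeights:
    """Named tensors exchanged between client and server."""

    tensors: dict[str, np.ndarray]
    sample_count: int = 1

    def schema(self) -> dict[str, tuple]:
        return {k: v.shape for k, v in self.tensors.items()}


def partition_dataset(manifest, config: FLConfig,
                      indices: np.ndarray | None = None) -> dict[int, np.ndarray]:
    """Disjoint, equal-size, class-balanced shards; deterministic given seed.

    ``manifest`` may be a :class:`DatasetManifest` or a plain integer label
    array.  ``indices`` restricts partitioning to a subset (e.g. the training
    side of a holdout split).  When the manifest carries ``patient_id``,
    samples of a patient never land on two clients.
    """
    if isinstance(manifest, DatasetManifest):
        labels = manifest.labels
        patients = manifest.df["patient_id"].to_numpy() if "patient_id" in manifest.df else None
    else:
        labels = np.asarray(manifest)
        patients = None
    pool = np.arange(len(labels)) if indices is None else np.asarray(indices)

    per_client = config.samples_per_client
    if per_client is None:
        per_client = len(pool) // config.n_clients
    needed = config.n_clients * per_client
    if len(pool) < needed:
        raise ValueError(
            f"insufficient samples: need {needed} "
            f"({config.n_clients} clients x {per_client}), have {len(pool)}"
        )

    rng = np.random.default_rng([config.seed, 211])
    by_class = {c: pool[labels[pool] == c] for c in (0, 1)}
    for c in by_class:
        idx = by_class[c]
        if patients is None or len(np.unique(patients[idx])) == len(idx):
            by_class[c] = idx[rng.permutation(len(idx))]
        else:
            # shuffle whole patients, keeping a patient's tiles contiguous so
            # they land on one client (disjointness guaranteed per class)
            groups = pd.Series(np.arange(len(idx))).groupby(patients[idx]).groups
            keys = list(groups)
            order = rng.permutation(len(keys))
            by_class[c] = np.concatenate(
                [idx[np.asarray(groups[keys[k]])] for k in order]
            )

    half, odd = divmod(per_client, 2)
    shards: dict[int, np.ndarray] = {}
    pos0 = pos1 = 0
    for client in range(config.n_clients):
        n1 = half + (odd and client % 2 == 0)
        n0 = per_client - n1
        take0, take1 = by_class[0][pos0:pos0 + n0], by_class[1][pos1:pos1 + n1]
        if len(take0) < n0 or len(take1) < n1:
            raise ValueError(
                f"insufficient class-balanced samples for client {client}: "
                f"need ({n0}, {n1}) per class"
            )
        pos0 += n0
        pos1 += n1
        shard = np.concatenate([take0, take1])
        shards[client] = shard[np.random.default_rng([config.seed, 223, client]).permutation(len(shard))]
    return shards


def fedavg_aggregate(weights_list: list[ModelWeights]) -> ModelWeights:
    """Per-tensor average weighted by sample counts (vanilla FedAvg)."""
    if not weights_list:
        raise ValueError("need at least one client")
    schema = weights_list[0].schema()
    for w in weights_list[1:]:
        if w.schema() != schema:
            raise ValueError("client weight schemas do not match")
    total = sum(w.sample_count for w in weights_list)
    out = {
        name: sum(w.tensors[name] * (w.sample_count / total) for w in weights_list)
        for name in schema
    }
    return ModelWeights(tensors=out, sample_count=total)


@dataclass
class FLResult:
    model: Model
    history: pd.DataFrame
    shards: dict[int, np.ndarray] = field(repr=False, default=None)  # type: ignore


def run_federated(
    X: np.ndarray,
    y: np.ndarray,
    model: Model,
    fl_config: FLConfig,
    train_config: TrainConfig,
    loss_spec: LossSpec = LossSpec(),
    holdout: bool = True,
) -> FLResult:
    """Round loop: broadcast -> local train -> aggregate -> global eval.

    With ``holdout=True`` an 8:2-style split (ratio from ``train_config``) is
    taken before partitioning and the global model is evaluated on the held-out
    set each round.
    """
    y = np.asarray(y)
    if holdout:
        train_idx, test_idx = split_train_test(len(X), train_config.split_ratio,
                                               fl_config.seed, labels=y)
    else:
        train_idx, test_idx = np.arange(len(X)), np.array([], dtype=int)
    shards = partition_dataset(y, fl_config, indices=train_idx)

    rows = []
    for rnd in range(fl_config.rounds):
        client_weights = []
        global_named = model.get_weights()
        for client, shard in shards.items():
            model.set_weights(global_named)
            cfg = replace(train_config, epochs=fl_config.local_epochs)
            train_model(
                X[shard], y[shard], model, cfg, loss_spec,
                worker_id=client,
                epoch_offset=rnd * fl_config.local_epochs,
            )
            client_weights.append(ModelWeights(model.get_weights(), len(shard)))
        agg = fedavg_aggregate(client_weights)
        model.set_weights(agg.tensors)
        row = {"round": rnd, "accuracy": np.nan, "fn_rate": np.nan}
        if len(test_idx):
            acc, fn = _metrics(y[test_idx], model.predict(X[test_idx]))
            row.update(accuracy=acc, fn_rate=fn)
        rows.append(row)
    history = pd.DataFrame(rows, columns=["round", "accuracy", "fn_rate"])
    return FLResult(model=model, history=history, shards=shards)


def client_grid_experiment(
    X: np.ndarray,
    y: np.ndarray,
    model_builder,
    clients: list[int],
    samples_per_client: list[int],
    folds: int = 5,
    rounds: int = 15,
    local_epochs: int = 1,
    train_config: TrainConfig | None = None,
    loss_spec: LossSpec = LossSpec(),
    seed: int = 0,
) -> pd.DataFrame:
    """Accuracy table over the (samples_per_client x n_clients) grid.

    Each populated cell holds mean +/- std over ``folds`` repeated 8:2
    holdout splits; infeasible cells (not enough training samples) are
    marked absent (NaN), not zero.
    """
    base = train_config or TrainConfig()
    rows = []
    for spc in samples_per_client:
        for n_clients in clients:
            accs, fns = [], []
            feasible = True
            for fold in range(folds):
                fl_cfg = FLConfig(n_clients=n_clients, samples_per_client=spc,
                                  rounds=rounds, local_epochs=local_epochs,
                                  seed=seed * 1000 + fold)
                tc = replace(base, seed=seed * 1000 + fold)
                model = model_builder(seed=seed * 1000 + fold)
                try:
                    result = run_federated(X, y, model, fl_cfg, tc, loss_spec)
                except ValueError:
                    feasible = False
                    break
                accs.append(result.history["accuracy"].iloc[-1])
                fns.append(result.history["fn_rate"].iloc[-1])
            for fold, (a, f) in enumerate(zip(accs, fns)):
                rows.append({"samples_per_client": spc, "n_clients": n_clients,
                             "fold": fold, "accuracy": a, "fn_rate": f,
                             "feasible": feasible})
            if not feasible:
                rows.append({"samples_per_client": spc, "n_clients": n_clients,
                             "fold": np.nan, "accuracy": np.nan,
                             "fn_rate": np.nan, "feasible": False})
    return pd.DataFrame(rows)


def summarize_grid(per_fold: pd.DataFrame) -> pd.DataFrame:
    """Pivot to a mean +/- std table shaped like the clients-grid summary."""
    ok = per_fold[per_fold["feasible"].astype(bool) & per_fold["accuracy"].notna()]
    agg = ok.groupby(["samples_per_client", "n_clients"])["accuracy"].agg(["mean", "std"])
    agg["cell"] = (100 * agg["mean"]).round(2).astype(str) + " ± " + \
                  (100 * agg["std"].fillna(0.0)).round(2).astype(str)
    return agg.reset_index().pivot(index="samples_per_client", columns="n_clients",
                                   values="cell")
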