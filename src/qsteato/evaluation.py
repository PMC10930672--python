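"""Metrics, lambda / training-size sweeps and heatmap reassembly.

Positive-class convention everywhere: "not-suitable" (grade 2-3) is class 1,
a false negative is a not-suitable tile predicted suitable, and fn_rate is
FN / actual-not-suitable (miss rate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .models import Model
from .nn.loss import NOT_SUITABLE
from .training import LossSpec, TrainConfig, kfold_indices, train_model

logger = logging.getLogger(__name__)


@dataclass
class EvalReport:
    confusion_matrix: np.ndarray  # rows = truth (suitable, not-suitable), cols = predicted
    accuracy: float
    fn_rate: float | None
    n: int

    def to_dict(self) -> dict:
        return {
            "confusion_matrix": self.confusion_matrix.tolist(),
            "accuracy": self.accuracy,
            "fn_rate": self.fn_rate,
            "n": self.n,
        }


def report_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> EvalReport:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if len(y_true) == 0:
        raise ValueError("empty test set")
    cm = np.zeros((2, 2), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[t, p] += 1
    accuracy = float(np.trace(cm) / cm.sum())
    actual_pos = cm[NOT_SUITABLE].sum()
    if actual_pos == 0:
        logger.warning("no not-suitable samples in test set; fn_rate undefined")
        fn_rate = None
    else:
        fn_rate = float(cm[NOT_SUITABLE, 1 - NOT_SUITABLE] / actual_pos)
    return EvalReport(confusion_matrix=cm, accuracy=accuracy, fn_rate=fn_rate,
                      n=int(cm.sum()))


def evaluate(model: Model, X: np.ndarray, y: np.ndarray) -> EvalReport:
    """Deterministic eval-mode metrics on a labeled tile set."""
    if len(X) == 0:
        raise ValueError("empty test set")
    return report_from_predictions(y, model.predict(X))


# ---------------------------------------------------------------------------
# Sweeps.
# ---------------------------------------------------------------------------


def lambda_sweep(
    lambdas: list[float],
    X: np.ndarray,
    y: np.ndarray,
    model_builder,
    train_config: TrainConfig,
) -> pd.DataFrame:
    """Per-lambda k-fold CV of accuracy and FN rate.

    Folds are identical across lambda values (seeded by the train config), so
    differences are attributable to the loss weighting alone.
    """
    if not lambdas:
        raise ValueError("lambda grid must be non-empty")
    rows = []
    folds = kfold_indices(len(X), train_config.folds, train_config.seed)
    for lam in lambdas:
        for fold, (tr, te) in enumerate(folds):
            model = model_builder(seed=train_config.seed + fold)
            train_model(X[tr], y[tr], model, train_config, LossSpec(lambda_fn=lam))
            rep = evaluate(model, X[te], y[te])
            rows.append({"lambda": lam, "fold": fold, "accuracy": rep.accuracy,
                         "fn_rate": rep.fn_rate})
    return pd.DataFrame(rows)


def summarize_lambda_sweep(per_fold: pd.DataFrame) -> pd.DataFrame:
    g = per_fold.groupby("lambda")[["accuracy", "fn_rate"]].agg(["mean", "std"])
    g.columns = ["_".join(c) for c in g.columns]
    out = g.reset_index()
    out["fn_below_5pct"] = out["fn_rate_mean"] < 0.05  # reported, not asserted
    return out


def train_size_sweep(
    sizes: list[int],
    X: np.ndarray,
    y: np.ndarray,
    model_builders: dict[str, object],
    train_config: TrainConfig,
    test_size: int = 400,
    n_seeds: int = 1,
) -> pd.DataFrame:
    """Learning curve: for each size, train on a nested seeded subsample and
    evaluate all model kinds on one fixed held-out test set."""
    if len(X) < max(sizes) + test_size:
        raise ValueError(
            f"pool of {len(X)} too small for max size {max(sizes)} + "
            f"test {test_size}"
        )
    rows = []
    for rep in range(n_seeds):
        rng = np.random.default_rng([train_config.seed, 313, rep])
        order = rng.permutation(len(X))
        test_idx = order[:test_size]
        pool = order[test_size:]
        for size in sorted(sizes):
            train_idx = pool[:size]  # nested: smaller sets are subsets of larger
            for kind, builder in model_builders.items():
                model = builder(seed=train_config.seed + rep)
                train_model(X[train_idx], y[train_idx], model,
                            replace(train_config, seed=train_config.seed + rep))
                rep_eval = evaluate(model, X[test_idx], y[test_idx])
                rows.append({"size": size, "model": kind, "seed_rep": rep,
                             "accuracy": rep_eval.accuracy,
                             "fn_rate": rep_eval.fn_rate,
                             "test_ids_hash": int(np.sum(test_idx) % 2**31)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Heatmap reassembly.
# ---------------------------------------------------------------------------


def reassemble_heatmap(
    tile_predictions: list[tuple[int, int, float]],
    grid_shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Rebuild a per-tile probability map into a slide-level heatmap.

    Returns ``(matrix, rgb)``: the probability matrix (NaN where no tile) and
    an RGB uint8 rendering with a diverging colormap over P(not-suitable),
    missing cells neutral grey.
    """
    n_rows, n_cols = grid_shape
    matrix = np.full((n_rows, n_cols), np.nan)
    seen = set()
    for row, col, prob in tile_predictions:
        if not (0 <= row < n_rows and 0 <= col < n_cols):
            raise ValueError(f"tile coordinate ({row}, {col}) outside grid {grid_shape}")
        if (row, col) in seen:
            raise ValueError(f"duplicate tile coordinate ({row}, {col})")
        seen.add((row, col))
        matrix[row, col] = prob

    from matplotlib import colormaps

    cmap = colormaps["coolwarm"]
    rgb = np.full((n_rows, n_cols, 3), 200, dtype=np.uint8)  # neutral grey
    filled = ~np.isnan(matrix)
    if filled.any():
        colored = (np.asarray(cmap(matrix[filled]))[:, :3] * 255).astype(np.uint8)
        rgb[filled] = colored
    return matrix, rgb
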