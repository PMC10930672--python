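"""Softmax and the class-weighted cross-entropy.

The weighted loss is  l = -sum_c w_c * y_c * log(p_c)  with w_c = lambda on
the not-suitable class (index 1, the positive / clinically dangerous class)
and 1 on the suitable class; lambda = 1 recovers the plain cross-entropy.
"""

from __future__ import annotations

import numpy as np

EPS = 1e-12
NOT_SUITABLE = 1  # class index of the penalized ("not suitable") class


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def weighted_cross_entropy(
    probabilities: np.ndarray, true_class: int, lambda_fn: float
) -> float:
    """Single-sample weighted cross-entropy over k = 2 classes."""
    p = np.asarray(probabilities, dtype=np.float64)
    if p.shape != (2,):
        raise ValueError("expected a length-2 probability vector")
    if abs(float(p.sum()) - 1.0) > 1e-6:
        raise ValueError(f"probabilities sum to {p.sum():.8f}, not 1")
    if true_class not in (0, 1):
        raise ValueError(f"true_class must be 0 or 1, got {true_class}")
    if lambda_fn < 1.0:
        raise ValueError("lambda_fn must be >= 1")
    w = lambda_fn if true_class == NOT_SUITABLE else 1.0
    return float(-w * np.log(max(float(p[true_class]), EPS)))


class WeightedCrossEntropyLoss:
    """Batched loss head: softmax + weighted CE, with gradient w.r.t. logits."""

    def __init__(self, lambda_fn: float = 1.0) -> None:
        if lambda_fn < 1.0:
            raise ValueError("lambda_fn must be >= 1")
        self.lambda_fn = float(lambda_fn)

    def forward(self, logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
        probs = softmax(logits)
        B = logits.shape[0]
        w = np.where(targets == NOT_SUITABLE, self.lambda_fn, 1.0)
        p_true = np.clip(probs[np.arange(B), targets], EPS, None)
        loss = float(np.mean(-w * np.log(p_true)))
        self._probs, self._targets, self._w = probs, targets, w
        return loss, probs

    def backward(self) -> np.ndarray:
        B, k = self._probs.shape
        onehot = np.zeros((B, k))
        onehot[np.arange(B), self._targets] = 1.0
        return self._w[:, None] * (self._probs - onehot) / B
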