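"""Quantum depth-infused (QDI) circuit head.

The circuit interleaves trainable single-qubit rotations (one "variational
row" of RX gates followed by an entangling CNOT layer) with data re-uploading
blocks that encode classical features as RZ angles:

    |0..0>  -> variational row 0
            -> for b = 1..B:  encode features[(b-1)n : bn] as RZ, then row b
            -> readout transform (fan-in CNOTs onto qubit 0)
            -> per-qubit Pauli-Y expectations

With ``n`` qubits and ``B`` blocks the head encodes ``n*B`` features and has
``(B+1)*n`` trainable angles; the defaults (5 qubits, 20 blocks) give the
100-feature / 105-gate configuration.

Gradients use the two-point parameter-shift rule, which is exact for
single-qubit rotation generators.  The same rule differentiates the feature
encodings, so the layer is trainable end-to-end without an autodiff framework.
The batched engine evaluates all shifted circuits for a whole minibatch in one
vectorized pass over the gate sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .state import (
    _ROTATIONS,
    _apply_cnot,
    _expectation,
)

__all__ = [
    "QDIConfig",
    "QDIParameters",
    "qdi_forward",
    "qdi_gradient",
    "qdi_forward_batch",
    "qdi_forward_and_grad_batch",
]


@dataclass(frozen=True)
class QDIConfig:
    """Circuit shape of the QDI head."""

    n_qubits: int = 5
    n_reupload_blocks: int = 20
    encoding_axis: str = "Z"
    variational_axis: str = "X"
    entangler: str = "chain"  # "chain" or "ring"
    readout_observable: str = "Y"

    def __post_init__(self) -> None:
        if self.n_qubits < 1:
            raise ValueError("n_qubits must be >= 1")
        if self.n_reupload_blocks < 1:
            raise ValueError("n_reupload_blocks must be >= 1")
        if self.entangler not in ("chain", "ring"):
            raise ValueError(f"unknown entangler {self.entangler!r}")
        for name in (self.encoding_axis, self.variational_axis, self.readout_observable):
            if name.upper() not in ("X", "Y", "Z"):
                raise ValueError(f"invalid Pauli label {name!r}")

    @property
    def feature_capacity(self) -> int:
        """Number of classical features the circuit encodes (n_qubits * blocks)."""
        return self.n_qubits * self.n_reupload_blocks

    @property
    def n_variational_gates(self) -> int:
        """Trainable single-qubit rotations: (blocks + 1) rows of n_qubits."""
        return (self.n_reupload_blocks + 1) * self.n_qubits

    @property
    def theta_shape(self) -> tuple[int, int]:
        return (self.n_reupload_blocks + 1, self.n_qubits)

    def entangler_pairs(self) -> list[tuple[int, int]]:
        pairs = [(q, q + 1) for q in range(self.n_qubits - 1)]
        if self.entangler == "ring" and self.n_qubits > 2:
            pairs.append((self.n_qubits - 1, 0))
        return pairs

    def to_dict(self) -> dict:
        return {
            "n_qubits": self.n_qubits,
            "n_reupload_blocks": self.n_reupload_blocks,
            "encoding_axis": self.encoding_axis,
            "variational_axis": self.variational_axis,
            "entangler": self.entangler,
            "readout_observable": self.readout_observable,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QDIConfig":
        return cls(**{k: d[k] for k in d if k in cls.__dataclass_fields__})


@dataclass
class QDIParameters:
    """Trainable rotation-angle lattice, shape (blocks + 1, n_qubits)."""

    theta: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=np.float64)
        if self.theta.ndim != 2:
            raise ValueError("theta must be a 2-D (rows x qubits) array")

    @classmethod
    def zeros(cls, config: QDIConfig) -> "QDIParameters":
        return cls(np.zeros(config.theta_shape))

    @classmethod
    def random(cls, config: QDIConfig, rng: np.random.Generator) -> "QDIParameters":
        # Zero angles make the output feature-independent (RZ on the ground
        # state is a pure phase), so initialization must break that symmetry.
        return cls(rng.uniform(-np.pi, np.pi, size=config.theta_shape))

    def validate(self, config: QDIConfig) -> None:
        if self.theta.shape != config.theta_shape:
            raise ValueError(
                f"theta shape {self.theta.shape} does not match config "
                f"{config.theta_shape}"
            )


def _check_features(features: np.ndarray, config: QDIConfig) -> np.ndarray:
    feats = np.asarray(features, dtype=np.float64)
    if feats.shape[-1] != config.feature_capacity:
        raise ValueError(
            f"expected {config.feature_capacity} features "
            f"(n_qubits x n_reupload_blocks), got {feats.shape[-1]}"
        )
    return feats


def _run_circuit(
    features: np.ndarray, theta: np.ndarray, config: QDIConfig,
    dtype=np.complex128,
) -> np.ndarray:
    """Evaluate the circuit for arbitrary leading batch axes.

    features: (..., F); theta: (..., B+1, n) broadcastable against features'
    leading axes.  Returns per-qubit readout expectations, shape (..., n).
    ``dtype=complex64`` trades ~1e-6 accuracy for speed in training loops.
    """
    n = config.n_qubits
    lead = np.broadcast_shapes(features.shape[:-1], theta.shape[:-2])
    amp = np.zeros(lead + (1 << n,), dtype=dtype)
    amp[..., 0] = 1.0

    rot_var = _ROTATIONS[config.variational_axis.upper()]
    rot_enc = _ROTATIONS[config.encoding_axis.upper()]
    theta_b = np.broadcast_to(theta, lead + theta.shape[-2:])
    feats_b = np.broadcast_to(features, lead + features.shape[-1:])
    pairs = config.entangler_pairs()

    def variational_row(row: int) -> None:
        for q in range(n):
            rot_var(amp, n, q, theta_b[..., row, q])
        for c, t in pairs:
            _apply_cnot(amp, n, c, t)

    variational_row(0)
    for b in range(1, config.n_reupload_blocks + 1):
        base = (b - 1) * n
        for q in range(n):
            rot_enc(amp, n, q, feats_b[..., base + q])
        variational_row(b)

    for q in range(1, n):  # readout fan-in onto qubit 0
        _apply_cnot(amp, n, q, 0)

    obs = config.readout_observable.upper()
    out = np.stack([_expectation(amp, n, q, obs) for q in range(n)], axis=-1)
    return out.astype(np.float64)


def qdi_forward(
    features: np.ndarray, params: QDIParameters, config: QDIConfig | None = None
) -> np.ndarray:
    """Readout expectations for a single feature vector; shape (n_qubits,)."""
    config = config or QDIConfig()
    params.validate(config)
    feats = _check_features(features, config)
    if feats.ndim != 1:
        raise ValueError("qdi_forward takes a single 1-D feature vector")
    return _run_circuit(feats, params.theta, config)


def qdi_forward_batch(
    features: np.ndarray, params: QDIParameters, config: QDIConfig | None = None
) -> np.ndarray:
    """Vectorized forward over a (batch, F) feature array; returns (batch, n)."""
    config = config or QDIConfig()
    params.validate(config)
    feats = _check_features(features, config)
    return _run_circuit(feats, params.theta, config)


def _shift_stacks(
    feats: np.ndarray, theta: np.ndarray, config: QDIConfig, with_features: bool
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Build the +/- pi/2 shifted parameter and feature stacks.

    Returns (feat_stack, theta_stack, P, F) where the stack axis enumerates
    [theta+ (P), theta- (P), feat+ (F), feat- (F)] shifted circuit instances.
    """
    P = theta.size
    F = config.feature_capacity if with_features else 0
    S = 2 * P + 2 * F
    flat = theta.reshape(-1)
    theta_stack = np.broadcast_to(flat, (S, P)).copy()
    shift = np.pi / 2.0
    idx = np.arange(P)
    theta_stack[idx, idx] += shift
    theta_stack[P + idx, idx] -= shift
    theta_stack = theta_stack.reshape(S, *theta.shape)

    feat_stack = np.broadcast_to(
        feats[..., None, :], feats.shape[:-1] + (S, feats.shape[-1])
    ).copy()
    if with_features:
        fidx = np.arange(F)
        feat_stack[..., 2 * P + fidx, fidx] += shift
        feat_stack[..., 2 * P + F + fidx, fidx] -= shift
    return feat_stack, theta_stack, P, F


def qdi_gradient(
    features: np.ndarray, params: QDIParameters, config: QDIConfig | None = None
) -> np.ndarray:
    """Parameter-shift gradient of every readout w.r.t. every theta entry.

    Returns shape ``theta_shape + (n_qubits,)``: entry [b, q, k] is
    d<Y_k>/d theta[b, q], computed exactly as (f(+pi/2) - f(-pi/2)) / 2.
    """
    config = config or QDIConfig()
    params.validate(config)
    feats = _check_features(features, config)
    if feats.ndim != 1:
        raise ValueError("qdi_gradient takes a single 1-D feature vector")
    feat_stack, theta_stack, P, _ = _shift_stacks(feats, params.theta, config, False)
    out = _run_circuit(feat_stack, theta_stack, config)  # (2P, n)
    grad = (out[:P] - out[P : 2 * P]) / 2.0
    return grad.reshape(*config.theta_shape, config.n_qubits)


def qdi_forward_and_grad_batch(
    features: np.ndarray, params: QDIParameters, config: QDIConfig | None = None,
    dtype=np.complex128,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched forward plus gradients w.r.t. theta and input features.

    features: (batch, F).  Returns

    - out:    (batch, n)            readout expectations
    - dtheta: (batch, B+1, n, n)    d out_k / d theta[b, q]
    - dfeat:  (batch, F, n)         d out_k / d feature_j

    Both gradients come from the parameter-shift rule (exact); all shifted
    circuits for the batch are evaluated in a single vectorized pass.
    """
    config = config or QDIConfig()
    params.validate(config)
    feats = _check_features(features, config)
    if feats.ndim != 2:
        raise ValueError("expected a (batch, features) array")
    feat_stack, theta_stack, P, F = _shift_stacks(feats, params.theta, config, True)
    # feat_stack: (batch, S, F); theta_stack: (S, B+1, n)
    out_shift = _run_circuit(feat_stack, theta_stack, config, dtype=dtype)  # (batch, S, n)
    out = _run_circuit(feats, params.theta, config, dtype=dtype)  # (batch, n)
    n = config.n_qubits
    dtheta = (out_shift[:, :P] - out_shift[:, P : 2 * P]) / 2.0
    dtheta = dtheta.reshape(feats.shape[0], *config.theta_shape, n)
    dfeat = (out_shift[:, 2 * P : 2 * P + F] - out_shift[:, 2 * P + F :]) / 2.0
    return out, dtheta, dfeat
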