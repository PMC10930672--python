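"""Dense statevector simulation primitives.

Amplitudes are stored little-endian: qubit 0 is the least significant bit of
the basis-state index.  The rotation convention is R_A(phi) = exp(-i phi A / 2).

All public operations are pure: they return a new :class:`QuantumState` and
leave the input untouched.  The private ``_apply_*`` kernels operate in place
on raw complex arrays of shape ``(..., 2**n)`` so the same code paths serve
both the single-state API and the batched circuit engine used for training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "QuantumState",
    "apply_rotation",
    "apply_cnot",
    "expectation_pauli",
    "readout_transform",
]

_NORM_ATOL = 1e-10


@dataclass
class QuantumState:
    """State of an ``n_qubits`` register as a dense complex amplitude vector."""

    n_qubits: int
    amplitudes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not 1 <= self.n_qubits <= 8:
            raise ValueError(f"n_qubits must be in [1, 8], got {self.n_qubits}")
        dim = 1 << self.n_qubits
        if self.amplitudes is None:
            amp = np.zeros(dim, dtype=np.complex128)
            amp[0] = 1.0
            self.amplitudes = amp
        else:
            self.amplitudes = np.asarray(self.amplitudes, dtype=np.complex128)
            if self.amplitudes.shape != (dim,):
                raise ValueError(
                    f"amplitude vector must have length {dim}, "
                    f"got shape {self.amplitudes.shape}"
                )
            if abs(self.norm() - 1.0) > _NORM_ATOL:
                raise ValueError("state is not normalized")

    @classmethod
    def ground(cls, n_qubits: int) -> "QuantumState":
        """|0...0> on ``n_qubits`` qubits."""
        return cls(n_qubits=n_qubits)

    @classmethod
    def from_basis_index(cls, n_qubits: int, index: int) -> "QuantumState":
        amp = np.zeros(1 << n_qubits, dtype=np.complex128)
        amp[index] = 1.0
        return cls(n_qubits=n_qubits, amplitudes=amp)

    def norm(self) -> float:
        return float(np.sqrt(np.sum(np.abs(self.amplitudes) ** 2)))

    def probabilities(self) -> np.ndarray:
        return np.abs(self.amplitudes) ** 2

    def copy(self) -> "QuantumState":
        return QuantumState(self.n_qubits, self.amplitudes.copy())


# ---------------------------------------------------------------------------
# Raw-array kernels.  ``amp`` has shape (..., 2**n); ``angle`` is a scalar or
# an array broadcastable over the leading axes.  All kernels mutate ``amp``.
# ---------------------------------------------------------------------------


def _qubit_view(amp: np.ndarray, n: int, qubit: int) -> np.ndarray:
    """Reshape so the target qubit becomes its own axis of length 2."""
    lead = amp.shape[:-1]
    return amp.reshape(*lead, 1 << (n - qubit - 1), 2, 1 << qubit)


def _angle_cols(amp: np.ndarray, angle) -> np.ndarray:
    """Broadcast an angle array over the two trailing axes of a qubit view."""
    a = np.asarray(angle, dtype=np.float64)
    if a.ndim == 0:
        return a
    return a.reshape(*a.shape, 1, 1)


def _real_dtype(amp: np.ndarray):
    return np.float32 if amp.dtype == np.complex64 else np.float64


def _apply_rx(amp: np.ndarray, n: int, qubit: int, angle) -> None:
    view = _qubit_view(amp, n, qubit)
    a = _angle_cols(amp, angle)
    rt = _real_dtype(amp)
    c = np.cos(a / 2.0).astype(rt)
    s = np.sin(a / 2.0).astype(rt)
    a0 = view[..., 0, :].copy()
    a1 = view[..., 1, :]
    view[..., 0, :] = c * a0 - 1j * s * a1
    view[..., 1, :] = -1j * s * a0 + c * a1


def _apply_ry(amp: np.ndarray, n: int, qubit: int, angle) -> None:
    view = _qubit_view(amp, n, qubit)
    a = _angle_cols(amp, angle)
    rt = _real_dtype(amp)
    c = np.cos(a / 2.0).astype(rt)
    s = np.sin(a / 2.0).astype(rt)
    a0 = view[..., 0, :].copy()
    a1 = view[..., 1, :]
    view[..., 0, :] = c * a0 - s * a1
    view[..., 1, :] = s * a0 + c * a1


def _apply_rz(amp: np.ndarray, n: int, qubit: int, angle) -> None:
    view = _qubit_view(amp, n, qubit)
    a = _angle_cols(amp, angle)
    view[..., 0, :] *= np.exp(-0.5j * a).astype(amp.dtype)
    view[..., 1, :] *= np.exp(0.5j * a).astype(amp.dtype)


_ROTATIONS = {"X": _apply_rx, "Y": _apply_ry, "Z": _apply_rz}


def _cnot_permutation(n: int, control: int, target: int) -> np.ndarray:
    idx = np.arange(1 << n)
    control_set = (idx >> control) & 1 == 1
    perm = np.where(control_set, idx ^ (1 << target), idx)
    return perm


def _apply_cnot(amp: np.ndarray, n: int, control: int, target: int) -> None:
    perm = _cnot_permutation(n, control, target)
    amp[...] = amp[..., perm]


def _apply_pauli(amp: np.ndarray, n: int, qubit: int, observable: str) -> np.ndarray:
    """Return O|psi> for a single-qubit Pauli, without mutating ``amp``."""
    out = amp.copy()
    view = _qubit_view(out, n, qubit)
    a0 = view[..., 0, :].copy()
    a1 = view[..., 1, :].copy()
    if observable == "X":
        view[..., 0, :] = a1
        view[..., 1, :] = a0
    elif observable == "Y":
        view[..., 0, :] = -1j * a1
        view[..., 1, :] = 1j * a0
    elif observable == "Z":
        view[..., 1, :] = -a1
    else:
        raise ValueError(f"unknown observable {observable!r}")
    return out


def _expectation(amp: np.ndarray, n: int, qubit: int, observable: str) -> np.ndarray:
    opsi = _apply_pauli(amp, n, qubit, observable)
    val = np.sum(np.conj(amp) * opsi, axis=-1)
    return np.real(val)


# ---------------------------------------------------------------------------
# Public single-state operations.
# ---------------------------------------------------------------------------


def _check_qubit(state: QuantumState, qubit: int) -> None:
    if not 0 <= qubit < state.n_qubits:
        raise IndexError(
            f"qubit index {qubit} out of range for {state.n_qubits} qubits"
        )


def apply_rotation(
    state: QuantumState, qubit: int, axis: str, angle: float
) -> QuantumState:
    """R_axis(angle) = exp(-i angle Pauli_axis / 2) on one qubit."""
    _check_qubit(state, qubit)
    axis = axis.upper()
    if axis not in _ROTATIONS:
        raise ValueError(f"axis must be one of X, Y, Z, got {axis!r}")
    amp = state.amplitudes.copy()
    _ROTATIONS[axis](amp, state.n_qubits, qubit, float(angle))
    return QuantumState(state.n_qubits, amp)


def apply_cnot(state: QuantumState, control: int, target: int) -> QuantumState:
    """Controlled-NOT: flip ``target`` where the ``control`` bit is 1."""
    _check_qubit(state, control)
    _check_qubit(state, target)
    if control == target:
        raise ValueError("control and target must differ")
    amp = state.amplitudes.copy()
    _apply_cnot(amp, state.n_qubits, control, target)
    return QuantumState(state.n_qubits, amp)


def expectation_pauli(state: QuantumState, qubit: int, observable: str) -> float:
    """<psi| O_qubit |psi> for O in {X, Y, Z}; real, in [-1, 1]."""
    _check_qubit(state, qubit)
    return float(_expectation(state.amplitudes, state.n_qubits, qubit, observable.upper()))


def readout_transform(state: QuantumState) -> QuantumState:
    """CNOT(control=q, target=0) for q = 1..n-1 in ascending order.

    Spreads the subsequent per-qubit Y measurement across the register; for a
    single qubit this is the identity.
    """
    amp = state.amplitudes.copy()
    for q in range(1, state.n_qubits):
        _apply_cnot(amp, state.n_qubits, q, 0)
    return QuantumState(state.n_qubits, amp)
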