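"""Independent dense-matrix oracles for the quantum circuit tests.

Built from numpy.kron / scipy.linalg.expm only -- no simulator kernels -- so
they stay independent of the code paths they check.
"""

import numpy as np

_PAULI = {
    "X": np.array([[0, 1], [1, 0]], dtype=complex),
    "Y": np.array([[0, -1j], [1j, 0]], dtype=complex),
    "Z": np.array([[1, 0], [0, -1]], dtype=complex),
    "I": np.eye(2, dtype=complex),
}


def one_qubit_op(n, qubit, u):
    """Embed a 2x2 operator on a little-endian qubit as a 2^n x 2^n matrix."""
    full = np.eye(1, dtype=complex)
    for q in range(n - 1, -1, -1):
        full = np.kron(full, u if q == qubit else _PAULI["I"])
    return full


def rotation_matrix(axis, angle):
    from scipy.linalg import expm

    return expm(-0.5j * angle * _PAULI[axis])


def cnot_matrix(n, control, target):
    dim = 1 << n
    mat = np.zeros((dim, dim), dtype=complex)
    for i in range(dim):
        j = i ^ (1 << target) if (i >> control) & 1 else i
        mat[j, i] = 1.0
    return mat


def oracle_qdi_unitary(features, theta, config):
    """Full circuit unitary assembled gate by gate as dense matrices."""
    n = config.n_qubits
    u = np.eye(1 << n, dtype=complex)

    def row(r):
        nonlocal u
        for q in range(n):
            u = one_qubit_op(n, q, rotation_matrix("X", theta[r, q])) @ u
        for c, t in config.entangler_pairs():
            u = cnot_matrix(n, c, t) @ u

    row(0)
    for b in range(1, config.n_reupload_blocks + 1):
        for q in range(n):
            u = one_qubit_op(n, q, rotation_matrix("Z", features[(b - 1) * n + q])) @ u
        row(b)
    for q in range(1, n):
        u = cnot_matrix(n, q, 0) @ u
    return u


def oracle_qdi_forward(features, theta, config):
    n = config.n_qubits
    psi0 = np.zeros(1 << n, dtype=complex)
    psi0[0] = 1.0
    psi = oracle_qdi_unitary(features, theta, config) @ psi0
    return np.array(
        [np.real(psi.conj() @ one_qubit_op(n, q, _PAULI["Y"]) @ psi) for q in range(n)]
    )
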