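"""Statevector simulator and QDI circuit tests, checked against independent
dense-matrix oracles built with numpy.kron."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qsteato.quantum import (
    QDIConfig,
    QDIParameters,
    QuantumState,
    apply_cnot,
    apply_rotation,
    expectation_pauli,
    qdi_forward,
    qdi_forward_and_grad_batch,
    qdi_forward_batch,
    qdi_gradient,
    readout_transform,
)

from _oracles import (
    _PAULI,
    cnot_matrix,
    one_qubit_op,
    oracle_qdi_forward,
    rotation_matrix,
)

ATOL = 1e-10


# ---------------------------------------------------------------------------
# Single-gate contracts.
# ---------------------------------------------------------------------------


class TestRotations:
    def test_rx_pi_is_bit_flip(self):
        out = apply_rotation(QuantumState.ground(1), 0, "X", np.pi)
        np.testing.assert_allclose(out.amplitudes, [0, -1j], atol=ATOL)
        np.testing.assert_allclose(out.probabilities(), [0, 1], atol=ATOL)

    def test_rz_on_ground_is_pure_phase(self):
        theta = 0.7321
        out = apply_rotation(QuantumState.ground(1), 0, "Z", theta)
        np.testing.assert_allclose(out.amplitudes[0], np.exp(-0.5j * theta), atol=ATOL)
        np.testing.assert_allclose(out.probabilities(), [1, 0], atol=ATOL)

    def test_rx_half_pi(self):
        out = apply_rotation(QuantumState.ground(1), 0, "X", np.pi / 2)
        np.testing.assert_allclose(
            out.amplitudes, np.array([1, -1j]) / np.sqrt(2), atol=ATOL
        )

    @pytest.mark.parametrize("axis", ["X", "Y", "Z"])
    def test_matches_matrix_exponential(self, axis):
        rng = np.random.default_rng(11)
        for _ in range(5):
            n, q = 3, int(rng.integers(3))
            angle = rng.uniform(-2 * np.pi, 2 * np.pi)
            amp = rng.normal(size=8) + 1j * rng.normal(size=8)
            amp /= np.linalg.norm(amp)
            state = QuantumState(3, amp)
            out = apply_rotation(state, q, axis, angle)
            expected = one_qubit_op(n, q, rotation_matrix(axis, angle)) @ amp
            np.testing.assert_allclose(out.amplitudes, expected, atol=ATOL)

    def test_other_qubits_untouched(self):
        state = QuantumState.from_basis_index(3, 0b101)
        out = apply_rotation(state, 1, "X", np.pi)
        np.testing.assert_allclose(out.probabilities()[0b111], 1.0, atol=ATOL)

    def test_qubit_out_of_range(self):
        with pytest.raises(IndexError):
            apply_rotation(QuantumState.ground(2), 2, "X", 0.1)

    def test_bad_axis(self):
        with pytest.raises(ValueError):
            apply_rotation(QuantumState.ground(1), 0, "W", 0.1)


class TestCnot:
    def test_control_set_flips_target(self):
        state = QuantumState.from_basis_index(2, 0b01)  # qubit 0 set
        out = apply_cnot(state, 0, 1)
        np.testing.assert_allclose(out.probabilities()[0b11], 1.0, atol=ATOL)

    def test_control_clear_is_identity(self):
        rng = np.random.default_rng(3)
        amp = np.zeros(4, dtype=complex)
        amp[0b00], amp[0b10] = rng.normal(size=2)  # qubit 0 clear in both
        amp /= np.linalg.norm(amp)
        out = apply_cnot(QuantumState(2, amp), 0, 1)
        np.testing.assert_allclose(out.amplitudes, amp, atol=ATOL)

    def test_bell_state(self):
        plus = apply_rotation(QuantumState.ground(2), 0, "Y", np.pi / 2)
        bell = apply_cnot(plus, 0, 1)
        expected = np.zeros(4)
        expected[0b00] = expected[0b11] = 0.5
        np.testing.assert_allclose(bell.probabilities(), expected, atol=ATOL)

    def test_control_equals_target(self):
        with pytest.raises(ValueError):
            apply_cnot(QuantumState.ground(2), 1, 1)

    def test_matches_matrix_oracle(self):
        rng = np.random.default_rng(5)
        amp = rng.normal(size=8) + 1j * rng.normal(size=8)
        amp /= np.linalg.norm(amp)
        out = apply_cnot(QuantumState(3, amp), 2, 0)
        np.testing.assert_allclose(out.amplitudes, cnot_matrix(3, 2, 0) @ amp, atol=ATOL)


class TestExpectation:
    def test_y_of_ground_is_zero(self):
        assert expectation_pauli(QuantumState.ground(1), 0, "Y") == pytest.approx(0.0, abs=ATOL)

    @pytest.mark.parametrize("theta", [0.0, 0.3, np.pi / 2, 1.9, np.pi])
    def test_y_after_rx_is_minus_sin(self, theta):
        state = apply_rotation(QuantumState.ground(1), 0, "X", theta)
        assert expectation_pauli(state, 0, "Y") == pytest.approx(-np.sin(theta), abs=ATOL)

    def test_z_of_one(self):
        state = QuantumState.from_basis_index(1, 1)
        assert expectation_pauli(state, 0, "Z") == pytest.approx(-1.0, abs=ATOL)

    def test_bounds_random_states(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            amp = rng.normal(size=16) + 1j * rng.normal(size=16)
            amp /= np.linalg.norm(amp)
            state = QuantumState(4, amp)
            for obs in "XYZ":
                val = expectation_pauli(state, int(rng.integers(4)), obs)
                assert -1.0 - ATOL <= val <= 1.0 + ATOL


class TestReadoutTransform:
    def test_all_zero_fixed_point(self):
        out = readout_transform(QuantumState.ground(2))
        np.testing.assert_allclose(out.probabilities()[0], 1.0, atol=ATOL)

    def test_qubit1_set_flips_qubit0(self):
        out = readout_transform(QuantumState.from_basis_index(2, 0b10))
        np.testing.assert_allclose(out.probabilities()[0b11], 1.0, atol=ATOL)

    def test_single_qubit_identity(self):
        amp = np.array([0.6, 0.8j])
        out = readout_transform(QuantumState(1, amp))
        np.testing.assert_allclose(out.amplitudes, amp, atol=ATOL)


@settings(max_examples=25, deadline=None)
@given(st.lists(st.tuples(st.integers(0, 2), st.sampled_from("XYZ"),
                          st.floats(-6.28, 6.28, allow_nan=False)),
                min_size=1, max_size=12),
       st.randoms(use_true_random=False))
def test_norm_preserved_by_gate_sequences(gates, rnd):
    state = QuantumState.ground(3)
    for qubit, axis, angle in gates:
        state = apply_rotation(state, qubit, axis, angle)
        if rnd.random() < 0.3:
            c, t = rnd.sample(range(3), 2)
            state = apply_cnot(state, c, t)
    assert state.norm() == pytest.approx(1.0, abs=ATOL)


# ---------------------------------------------------------------------------
# QDI circuit.
# ---------------------------------------------------------------------------


class TestQDIForward:
    def test_all_zero_defaults(self):
        config = QDIConfig()
        out = qdi_forward(np.zeros(100), QDIParameters.zeros(config), config)
        np.testing.assert_allclose(out, np.zeros(5), atol=ATOL)

    @pytest.mark.parametrize("x", [0.0, np.pi / 4, np.pi / 2, np.pi])
    def test_one_qubit_closed_form(self, x):
        # RX(pi/2), RZ(x), RX(0) then <Y>: closed form -cos(x) by 2x2 algebra.
        config = QDIConfig(n_qubits=1, n_reupload_blocks=1)
        params = QDIParameters(np.array([[np.pi / 2], [0.0]]))
        out = qdi_forward(np.array([x]), params, config)
        assert out[0] == pytest.approx(-np.cos(x), abs=ATOL)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_unitary_oracle(self, seed):
        rng = np.random.default_rng(seed)
        config = QDIConfig(n_qubits=5, n_reupload_blocks=3)
        feats = rng.uniform(-np.pi, np.pi, config.feature_capacity)
        params = QDIParameters.random(config, rng)
        out = qdi_forward(feats, params, config)
        expected = oracle_qdi_forward(feats, params.theta, config)
        np.testing.assert_allclose(out, expected, atol=ATOL)

    def test_ring_entangler_matches_oracle(self):
        rng = np.random.default_rng(42)
        config = QDIConfig(n_qubits=4, n_reupload_blocks=2, entangler="ring")
        feats = rng.uniform(-np.pi, np.pi, config.feature_capacity)
        params = QDIParameters.random(config, rng)
        np.testing.assert_allclose(
            qdi_forward(feats, params, config),
            oracle_qdi_forward(feats, params.theta, config),
            atol=ATOL,
        )

    def test_feature_length_mismatch(self):
        config = QDIConfig()
        with pytest.raises(ValueError):
            qdi_forward(np.zeros(99), QDIParameters.zeros(config), config)
        with pytest.raises(ValueError):
            qdi_forward(np.zeros(101), QDIParameters.zeros(config), config)

    def test_output_bounds(self):
        rng = np.random.default_rng(7)
        config = QDIConfig(n_qubits=3, n_reupload_blocks=4)
        for _ in range(5):
            out = qdi_forward(
                rng.uniform(-np.pi, np.pi, config.feature_capacity),
                QDIParameters.random(config, rng),
                config,
            )
            assert np.all(out >= -1 - ATOL) and np.all(out <= 1 + ATOL)

    def test_identity_initial_row_ignores_block1_features(self):
        # With variational row 0 = identity, RZ on |0..0> is a pure phase, so
        # block-1 features cannot influence the output.
        rng = np.random.default_rng(0)
        config = QDIConfig(n_qubits=3, n_reupload_blocks=2)
        theta = rng.uniform(-np.pi, np.pi, config.theta_shape)
        theta[0, :] = 0.0
        params = QDIParameters(theta)
        feats = rng.uniform(-np.pi, np.pi, config.feature_capacity)
        base = qdi_forward(feats, params, config)
        for _ in range(3):
            other = feats.copy()
            other[: config.n_qubits] = rng.uniform(-np.pi, np.pi, config.n_qubits)
            np.testing.assert_allclose(qdi_forward(other, params, config), base, atol=ATOL)

    def test_batch_matches_loop(self):
        rng = np.random.default_rng(2)
        config = QDIConfig(n_qubits=4, n_reupload_blocks=3)
        params = QDIParameters.random(config, rng)
        feats = rng.uniform(-np.pi, np.pi, (6, config.feature_capacity))
        batch = qdi_forward_batch(feats, params, config)
        for i in range(6):
            np.testing.assert_allclose(batch[i], qdi_forward(feats[i], params, config), atol=ATOL)

    def test_feature_capacity_default(self):
        assert QDIConfig().feature_capacity == 100
        assert QDIConfig().n_variational_gates == 105


class TestQDIGradient:
    def finite_difference(self, feats, params, config, h=1e-5):
        grad = np.zeros(config.theta_shape + (config.n_qubits,))
        for b in range(config.theta_shape[0]):
            for q in range(config.theta_shape[1]):
                tp, tm = params.theta.copy(), params.theta.copy()
                tp[b, q] += h
                tm[b, q] -= h
                fp = qdi_forward(feats, QDIParameters(tp), config)
                fm = qdi_forward(feats, QDIParameters(tm), config)
                grad[b, q] = (fp - fm) / (2 * h)
        return grad

    def test_single_qubit_shift_example(self):
        # f(theta) = <Y> after RX(theta) = -sin(theta); slope at 0 is -1,
        # recovered exactly as [f(pi/2) - f(-pi/2)] / 2 = (-1 - 1)/2.
        config = QDIConfig(n_qubits=1, n_reupload_blocks=1)
        params = QDIParameters(np.array([[0.0], [0.0]]))
        grad = qdi_gradient(np.zeros(1), params, config)
        assert grad[0, 0, 0] == pytest.approx(-1.0, abs=ATOL)

    def test_zero_instance_matches_finite_differences(self):
        config = QDIConfig()  # default 5x20
        params = QDIParameters.zeros(config)
        feats = np.zeros(100)
        grad = qdi_gradient(feats, params, config)
        # finite differences on the full default config are slow; check a
        # deterministic subset of entries
        rng = np.random.default_rng(0)
        h = 1e-5
        for _ in range(6):
            b = int(rng.integers(config.theta_shape[0]))
            q = int(rng.integers(config.theta_shape[1]))
            tp, tm = params.theta.copy(), params.theta.copy()
            tp[b, q] += h
            tm[b, q] -= h
            fd = (qdi_forward(feats, QDIParameters(tp), config)
                  - qdi_forward(feats, QDIParameters(tm), config)) / (2 * h)
            np.testing.assert_allclose(grad[b, q], fd, atol=1e-6)

    @pytest.mark.parametrize("seed", [101, 202, 303])
    def test_random_instances_match_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        config = QDIConfig(n_qubits=5, n_reupload_blocks=2)
        params = QDIParameters.random(config, rng)
        feats = rng.uniform(-np.pi, np.pi, config.feature_capacity)
        grad = qdi_gradient(feats, params, config)
        fd = self.finite_difference(feats, params, config)
        assert np.max(np.abs(grad - fd)) < 1e-6

    def test_batched_forward_and_grad(self):
        rng = np.random.default_rng(9)
        config = QDIConfig(n_qubits=3, n_reupload_blocks=2)
        params = QDIParameters.random(config, rng)
        feats = rng.uniform(-np.pi, np.pi, (4, config.feature_capacity))
        out, dtheta, dfeat = qdi_forward_and_grad_batch(feats, params, config)
        for i in range(4):
            np.testing.assert_allclose(out[i], qdi_forward(feats[i], params, config), atol=ATOL)
            np.testing.assert_allclose(dtheta[i], qdi_gradient(feats[i], params, config), atol=ATOL)
        # feature gradients vs finite differences
        h = 1e-5
        for j in [0, 3, 5]:
            fp, fm = feats.copy(), feats.copy()
            fp[:, j] += h
            fm[:, j] -= h
            fd = (qdi_forward_batch(fp, params, config)
                  - qdi_forward_batch(fm, params, config)) / (2 * h)
            np.testing.assert_allclose(dfeat[:, j, :], fd, atol=1e-6)
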