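"""Statevector core: gates, encoding, readout, gradients vs independent oracles."""

import numpy as np
import pytest

from quanvit.quantum import (
    EntanglementPattern,
    apply_cnot,
    apply_variational_layer,
    encode,
    ground_state,
    measure_z,
    parameter_shift_gradient,
    rotation_matrix,
    run_circuit,
    validate_state,
)


def kron_state(per_qubit):
    """Oracle: little-endian tensor product of per-qubit 2-vectors."""
    state = np.array([1.0 + 0j])
    for q in per_qubit:  # qubit 0 fastest-varying
        state = np.kron(q, state)
    return state


def single_qubit_encoding(x):
    """Oracle: explicit 2x2 matrix product Ry(pi x) Rz(pi x) |0>."""
    t = np.pi * x
    ry = np.array([[np.cos(t / 2), -np.sin(t / 2)], [np.sin(t / 2), np.cos(t / 2)]])
    rz = np.diag([np.exp(-1j * t / 2), np.exp(1j * t / 2)])
    return ry @ rz @ np.array([1.0, 0.0])


class TestRotationMatrix:
    def test_identity_at_zero(self):
        assert np.allclose(rotation_matrix("Y", 0.0), np.eye(2))
        assert np.allclose(rotation_matrix("Z", 0.0), np.eye(2))

    def test_printed_forms(self):
        # Ry(pi) and Rz(pi/2) written out with theta substituted
        assert np.allclose(rotation_matrix("Y", np.pi), [[0, -1], [1, 0]], atol=1e-12)
        assert np.allclose(
            rotation_matrix("Z", np.pi / 2),
            np.diag([np.exp(-1j * np.pi / 4), np.exp(1j * np.pi / 4)]),
        )

    def test_unitarity_1000_random_angles(self, rng):
        thetas = rng.uniform(-10, 10, size=1000)
        for axis in ("Y", "Z"):
            mats = rotation_matrix(axis, thetas)
            prod = np.einsum("...ji,...jk->...ik", mats.conj(), mats)
            assert np.allclose(prod, np.eye(2), atol=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rotation_matrix("Y", np.nan)
        with pytest.raises(ValueError):
            rotation_matrix("X", 1.0)


class TestEncode:
    def test_all_zero_features_give_ground_state(self):
        state = encode([0, 0, 0, 0])
        probs = np.abs(state) ** 2
        assert probs[0] == pytest.approx(1.0, abs=1e-12)

    def test_feature_one_flips_qubit(self):
        assert measure_z(encode([1.0]))[0] == pytest.approx(-1.0, abs=1e-12)

    def test_half_feature_zero_expectation(self):
        # oracle: explicit matrix product, then <Z> = |a0|^2 - |a1|^2
        amps = single_qubit_encoding(0.5)
        expected = abs(amps[0]) ** 2 - abs(amps[1]) ** 2
        assert expected == pytest.approx(0.0, abs=1e-12)
        assert measure_z(encode([0.5]))[0] == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_features_clip_with_warning(self):
        with pytest.warns(UserWarning):
            state = encode([1.5, -0.2])
        validate_state(state)

    def test_matches_tensor_product_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 5))
            x = rng.random(n)
            expected = kron_state([single_qubit_encoding(v) for v in x])
            assert np.allclose(encode(x), expected, atol=1e-12)

    def test_norm_is_one(self, rng):
        for _ in range(20):
            validate_state(encode(rng.random(4)))


class TestCnot:
    def test_control_unset_is_identity(self):
        state = ground_state(2)
        assert np.allclose(apply_cnot(state, 0, 1), state)

    def test_truth_table(self):
        # |q1 q0> = |01> (index 1): control qubit 0 set -> flips target
        state = np.zeros(4, dtype=complex)
        state[1] = 1.0
        out = apply_cnot(state, 0, 1)
        assert out[3] == pytest.approx(1.0)

    def test_self_inverse(self, rng):
        state = rng.normal(size=8) + 1j * rng.normal(size=8)
        state /= np.linalg.norm(state)
        assert np.allclose(apply_cnot(apply_cnot(state, 2, 0), 2, 0), state)

    def test_norm_preserved(self, rng):
        state = rng.normal(size=16) + 1j * rng.normal(size=16)
        state /= np.linalg.norm(state)
        validate_state(apply_cnot(state, 1, 3))

    def test_index_errors(self):
        state = ground_state(2)
        with pytest.raises(ValueError):
            apply_cnot(state, 0, 0)
        with pytest.raises(ValueError):
            apply_cnot(state, 0, 5)


class TestVariationalLayer:
    def test_zero_angles_do_nothing(self, rng):
        state = encode(rng.random(3))
        assert np.allclose(apply_variational_layer(state, np.zeros(3)), state)

    def test_pi_rotation_flips_ground_state(self):
        out = apply_variational_layer(ground_state(1), np.array([np.pi]))
        assert measure_z(out)[0] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_dense_kron_oracle(self, rng):
        state = rng.normal(size=16) + 1j * rng.normal(size=16)
        state /= np.linalg.norm(state)
        thetas = rng.uniform(0, 2 * np.pi, size=4)
        # oracle: full 16x16 unitary built by kron (qubit 0 = rightmost factor)
        U = np.array([[1.0]])
        for q in reversed(range(4)):
            U = np.kron(U, rotation_matrix("Y", thetas[q]))
        assert np.allclose(apply_variational_layer(state, thetas), U @ state, atol=1e-10)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            apply_variational_layer(ground_state(3), np.zeros(2))


class TestMeasureZ:
    def test_ground_state_all_plus_one(self):
        assert np.allclose(measure_z(ground_state(4)), 1.0)

    def test_equal_superposition_is_zero(self):
        state = np.array([1.0, 1.0]) / np.sqrt(2)
        assert measure_z(state)[0] == pytest.approx(0.0, abs=1e-12)

    def test_brute_force_enumeration_oracle(self):
        x = np.array([0.3, 0.7, 0.1, 0.9])
        pattern = EntanglementPattern.linear_chain(4)
        state = encode(x)
        for c, t in pattern.pairs:
            state = apply_cnot(state, c, t)
        probs = np.abs(state) ** 2
        expected = np.array(
            [
                sum((1 if (b >> q) & 1 == 0 else -1) * probs[b] for b in range(16))
                for q in range(4)
            ]
        )
        assert np.allclose(measure_z(state), expected, atol=1e-12)
        assert np.all(np.abs(measure_z(state)) <= 1 + 1e-12)


class TestRunCircuit:
    def test_zero_features_all_plus_one(self):
        out = run_circuit(np.zeros(4), EntanglementPattern.linear_chain(4))
        assert np.allclose(out, 1.0, atol=1e-12)

    def test_closed_form_without_entanglement(self, rng):
        x = rng.random(4)
        assert np.allclose(run_circuit(x), np.cos(np.pi * x), atol=1e-12)

    def test_deterministic(self, rng):
        x = rng.random(4)
        thetas = rng.uniform(0, 2 * np.pi, 4)
        pattern = EntanglementPattern.linear_chain(4)
        a = run_circuit(x, pattern, thetas)
        b = run_circuit(x, pattern, thetas)
        assert np.array_equal(a, b)

    def test_rz_only_phase_invariance(self):
        # Rz on |0..0> is a pure phase: encode with x=0 then any CNOTs keep
        # <Z> = +1; equivalently features 0 with a variational layer of zeros
        state = ground_state(4)
        for q in range(4):
            from quanvit.quantum import apply_single_qubit_gate

            state = apply_single_qubit_gate(
                state, rotation_matrix("Z", 1.234 + q), q
            )
        assert np.allclose(measure_z(state), 1.0, atol=1e-12)


class TestParameterShift:
    def test_zero_configuration_gradient_zero(self):
        grad = parameter_shift_gradient(
            np.zeros(4), EntanglementPattern.linear_chain(4), np.zeros(4), 0
        )
        assert grad[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_finite_differences(self, rng):
        pattern = EntanglementPattern.linear_chain(4)
        h = 1e-5
        for _ in range(100):
            x = rng.random(4)
            thetas = rng.uniform(0, 2 * np.pi, 4)
            q_out = int(rng.integers(0, 4))
            grad = parameter_shift_gradient(x, pattern, thetas, q_out)
            for k in range(4):
                plus, minus = thetas.copy(), thetas.copy()
                plus[k] += h
                minus[k] -= h
                fd = (
                    run_circuit(x, pattern, plus)[q_out]
                    - run_circuit(x, pattern, minus)[q_out]
                ) / (2 * h)
                assert grad[k] == pytest.approx(fd, abs=1e-4)

    def test_disconnected_qubit_zero_gradient(self, rng):
        # no entanglement: theta on qubit 3 cannot move <Z_0>
        x = rng.random(4)
        thetas = rng.uniform(0, 2 * np.pi, 4)
        grad = parameter_shift_gradient(x, None, thetas, 0)
        assert grad[3] == pytest.approx(0.0, abs=1e-12)


def test_gate_applications_preserve_norm(rng):
    state = encode(rng.random(4))
    pattern = EntanglementPattern.linear_chain(4, ring=True)
    for c, t in pattern.pairs:
        state = apply_cnot(state, c, t)
    state = apply_variational_layer(state, rng.uniform(0, 7, 4))
    validate_state(state)


def test_entanglement_pattern_validation():
    with pytest.raises(ValueError):
        EntanglementPattern(((0, 0),))
    with pytest.raises(ValueError):
        EntanglementPattern(((0, 5),)).validate(4)
    assert EntanglementPattern.linear_chain(4).pairs == ((0, 1), (1, 2), (2, 3))
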