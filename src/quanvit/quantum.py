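"""Exact statevector simulation of shallow angle-encoding circuits.

This module implements the 4-qubit feature-encoding circuit that powers the
quanvolutional layers: single-qubit Ry/Rz rotations with angles ``pi * x_i``
for normalized features ``x_i in [0, 1]``, CNOT entanglement, a Pauli-Z
expectation readout per qubit, and parameter-shift gradients for the optional
trainable rotation layer.

Conventions
-----------
* States are dense complex128 amplitude vectors of length ``2**n_qubits``.
  Any number of leading batch axes is allowed; every operation is vectorized
  over them, which is what makes sliding-window quanvolution affordable on a
  CPU (one call simulates ``windows x filters`` circuits at once).
* Bit ordering is little-endian: qubit 0 is the least-significant bit of the
  basis-state index, so basis index ``b`` assigns bit ``(b >> q) & 1`` to
  qubit ``q``.
* The encoding of a single feature ``x`` is ``Ry(pi x) @ Rz(pi x) |0>``
  (Rz applied first); the multi-qubit state is the tensor product over
  qubits.  On ``|0>`` the Rz contributes only a phase, so Z expectations of
  the product state reduce to ``cos(pi x)`` per qubit.

All gate applications are exactly unitary up to floating-point rounding; a
norm tolerance of 1e-10 is used for validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "NORM_ATOL",
    "EntanglementPattern",
    "rotation_matrix",
    "ground_state",
    "validate_state",
    "encode",
    "apply_single_qubit_gate",
    "apply_cnot",
    "apply_variational_layer",
    "measure_z",
    "run_circuit",
    "parameter_shift_gradient",
]

#: absolute tolerance for norm / unitarity checks
NORM_ATOL = 1e-10


@dataclass(frozen=True)
class EntanglementPattern:
    """Ordered list of (control, target) CNOT pairs applied after encoding.

    The default pattern used throughout the package is a linear chain
    ``0->1, 1->2, ..., (n-2)->(n-1)``, the shallowest entangling layout;
    ring closure (an extra ``(n-1)->0`` pair) is available but off by
    default.
    """

    pairs: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        pairs = tuple((int(c), int(t)) for c, t in self.pairs)
        for c, t in pairs:
            if c == t:
                raise ValueError(f"control and target coincide: {c}")
            if c < 0 or t < 0:
                raise ValueError(f"negative qubit index in pair ({c}, {t})")
        object.__setattr__(self, "pairs", pairs)

    @classmethod
    def linear_chain(cls, n_qubits: int, ring: bool = False) -> "EntanglementPattern":
        pairs = [(q, q + 1) for q in range(n_qubits - 1)]
        if ring and n_qubits > 1:
            pairs.append((n_qubits - 1, 0))
        return cls(tuple(pairs))

    def validate(self, n_qubits: int) -> None:
        for c, t in self.pairs:
            if not (0 <= c < n_qubits and 0 <= t < n_qubits):
                raise ValueError(
                    f"pair ({c}, {t}) out of range for {n_qubits} qubits"
                )

    def to_dict(self) -> dict:
        return {"pairs": [list(p) for p in self.pairs]}


def rotation_matrix(axis: str, theta: float | np.ndarray) -> np.ndarray:
    """Single-qubit rotation matrix about the Y or Z axis.

    Ry(theta) = [[cos(theta/2), -sin(theta/2)],
                 [sin(theta/2),  cos(theta/2)]]
    Rz(theta) = diag(exp(-i theta/2), exp(+i theta/2))

    ``theta`` may be an array; the matrix axes are appended last, giving
    shape ``theta.shape + (2, 2)``.
    """
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("rotation angle must be finite")
    half = theta / 2.0
    out = np.zeros(theta.shape + (2, 2), dtype=np.complex128)
    if axis.upper() == "Y":
        c, s = np.cos(half), np.sin(half)
        out[..., 0, 0] = c
        out[..., 0, 1] = -s
        out[..., 1, 0] = s
        out[..., 1, 1] = c
    elif axis.upper() == "Z":
        out[..., 0, 0] = np.exp(-1j * half)
        out[..., 1, 1] = np.exp(1j * half)
    else:
        raise ValueError(f"axis must be 'Y' or 'Z', got {axis!r}")
    return out


def ground_state(n_qubits: int, batch_shape: tuple[int, ...] = ()) -> np.ndarray:
    """|0...0> statevector, optionally with leading batch axes."""
    if n_qubits < 1:
        raise ValueError("n_qubits must be >= 1")
    state = np.zeros(batch_shape + (2**n_qubits,), dtype=np.complex128)
    state[..., 0] = 1.0
    return state


def _n_qubits_of(state: np.ndarray) -> int:
    dim = state.shape[-1]
    n = int(round(np.log2(dim)))
    if 2**n != dim:
        raise ValueError(f"state length {dim} is not a power of two")
    return n


def validate_state(state: np.ndarray, atol: float = NORM_ATOL) -> int:
    """Check normalization; return the qubit count."""
    n = _n_qubits_of(state)
    norms = np.sum(np.abs(state) ** 2, axis=-1)
    if not np.allclose(norms, 1.0, atol=atol, rtol=0):
        raise ValueError("statevector is not normalized")
    return n


def _clip_features(features: np.ndarray) -> np.ndarray:
    if np.any(features < 0) or np.any(features > 1):
        warnings.warn(
            "features outside [0, 1] were clipped before angle encoding",
            stacklevel=3,
        )
        features = np.clip(features, 0.0, 1.0)
    return features


def encode(features: Sequence[float] | np.ndarray) -> np.ndarray:
    """Angle-encode normalized features into a product statevector.

    Each feature ``x`` is mapped to one qubit prepared as
    ``Ry(pi x) Rz(pi x) |0>``; the joint state is their tensor product.
    ``features`` may carry leading batch axes: shape ``(..., n)`` gives a
    state of shape ``(..., 2**n)``.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim == 0:
        features = features[None]
    if not np.all(np.isfinite(features)):
        raise ValueError("features must be finite")
    features = _clip_features(features)
    n = features.shape[-1]
    theta = np.pi * features
    # per-qubit amplitudes of Ry(theta) Rz(theta) |0>:
    #   a0 = cos(theta/2) e^{-i theta/2},  a1 = sin(theta/2) e^{-i theta/2}
    phase = np.exp(-1j * theta / 2.0)
    a0 = np.cos(theta / 2.0) * phase
    a1 = np.sin(theta / 2.0) * phase
    # tensor product, little-endian: qubit 0 is the fastest-varying bit
    state = np.ones(features.shape[:-1] + (1,), dtype=np.complex128)
    for q in range(n):
        amp_q = np.stack([a0[..., q], a1[..., q]], axis=-1)  # (..., 2)
        # new index = bit_q * 2**q + old index
        state = (amp_q[..., :, None] * state[..., None, :]).reshape(
            features.shape[:-1] + (2 ** (q + 1),)
        )
    return state


def apply_single_qubit_gate(
    state: np.ndarray, gate: np.ndarray, qubit: int
) -> np.ndarray:
    """Apply a 2x2 gate to one qubit of a (batched) statevector.

    ``gate`` may itself carry batch axes broadcastable against the state's
    batch axes (shape ``(..., 2, 2)``).
    """
    n = _n_qubits_of(state)
    if not (0 <= qubit < n):
        raise ValueError(f"qubit {qubit} out of range for {n} qubits")
    low = 2**qubit
    high = 2 ** (n - qubit - 1)
    work = state.reshape(state.shape[:-1] + (high, 2, low))
    out = np.einsum("...ij,...hjl->...hil", gate, work)
    # the batch shape may have grown by broadcasting against the gate's
    return out.reshape(out.shape[:-3] + (2**n,))


def apply_cnot(state: np.ndarray, control: int, target: int) -> np.ndarray:
    """Apply CNOT: flip the target bit on basis states whose control bit is 1.

    Implemented as a fixed index permutation of the amplitude vector (CNOT
    is a self-inverse permutation matrix), so it is exact and batch-friendly.
    """
    n = _n_qubits_of(state)
    if control == target:
        raise ValueError("control and target must differ")
    for name, q in (("control", control), ("target", target)):
        if not (0 <= q < n):
            raise ValueError(f"{name} qubit {q} out of range for {n} qubits")
    idx = np.arange(2**n)
    flipped = np.where((idx >> control) & 1 == 1, idx ^ (1 << target), idx)
    return state[..., flipped]


def apply_variational_layer(state: np.ndarray, thetas: np.ndarray) -> np.ndarray:
    """Apply one Ry(theta_q) rotation per qubit.

    ``thetas`` has shape ``(..., n_qubits)``; leading axes broadcast against
    the state's batch axes (e.g. a filter axis against a window axis).
    """
    n = _n_qubits_of(state)
    thetas = np.asarray(thetas, dtype=float)
    if thetas.shape[-1] != n:
        raise ValueError(
            f"expected {n} angles (one per qubit), got {thetas.shape[-1]}"
        )
    for q in range(n):
        state = apply_single_qubit_gate(
            state, rotation_matrix("Y", thetas[..., q]), q
        )
    return state


def measure_z(state: np.ndarray) -> np.ndarray:
    """Pauli-Z expectation of every qubit: <Z_q> = P(bit_q = 0) - P(bit_q = 1).

    Returns shape ``(..., n_qubits)``; every value lies in [-1, 1].
    """
    n = _n_qubits_of(state)
    probs = np.abs(state) ** 2
    idx = np.arange(2**n)
    signs = 1.0 - 2.0 * ((idx[None, :] >> np.arange(n)[:, None]) & 1)  # (n, 2**n)
    return probs @ signs.T


def run_circuit(
    features: np.ndarray,
    pattern: EntanglementPattern | None = None,
    thetas: np.ndarray | None = None,
) -> np.ndarray:
    """Encode -> entangle -> optional Ry layer -> Z readout.

    Parameters
    ----------
    features : array, shape (..., n_qubits)
        Normalized features in [0, 1] (clipped with a warning otherwise).
    pattern : EntanglementPattern, optional
        CNOT pairs applied in order after encoding. ``None`` means no
        entanglement (the product-state limit, where <Z_i> = cos(pi x_i)).
    thetas : array, shape broadcastable to (..., n_qubits), optional
        Angles of a trailing per-qubit Ry layer; omitted if ``None``.

    Returns
    -------
    expectations : array, shape broadcast(features, thetas).shape
        Per-qubit Pauli-Z expectations in [-1, 1].
    """
    features = np.asarray(features, dtype=float)
    n = features.shape[-1]
    state = encode(features)
    if pattern is not None:
        pattern.validate(n)
        for c, t in pattern.pairs:
            state = apply_cnot(state, c, t)
    if thetas is not None:
        state = apply_variational_layer(state, np.asarray(thetas, dtype=float))
    return measure_z(state)


def parameter_shift_gradient(
    features: np.ndarray,
    pattern: EntanglementPattern | None,
    thetas: np.ndarray,
    qubit_out: int,
) -> np.ndarray:
    """Exact gradient of <Z_{qubit_out}> w.r.t. each variational angle.

    Uses the parameter-shift rule for rotation generators:
    d<Z>/d theta_k = (f(theta_k + pi/2) - f(theta_k - pi/2)) / 2.
    """
    thetas = np.asarray(thetas, dtype=float)
    if thetas.ndim != 1:
        raise ValueError("thetas must be a 1-D angle vector")
    features = np.asarray(features, dtype=float)
    n = features.shape[-1]
    if not (0 <= qubit_out < n):
        raise ValueError(f"qubit_out {qubit_out} out of range")
    grad = np.empty(thetas.shape[0], dtype=float)
    for k in range(thetas.shape[0]):
        plus = thetas.copy()
        minus = thetas.copy()
        plus[k] += np.pi / 2.0
        minus[k] -= np.pi / 2.0
        f_plus = run_circuit(features, pattern, plus)[..., qubit_out]
        f_minus = run_circuit(features, pattern, minus)[..., qubit_out]
        grad[k] = 0.5 * (f_plus - f_minus)
    return grad
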