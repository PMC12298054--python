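"""Quanvolution: sliding-window quantum feature extraction.

A quanvolutional layer replaces the multiply-accumulate kernel of a
convolution with a small quantum circuit.  Each window of the input is
average-pooled to a 2x2 grid (4 features, one per qubit; channels are
averaged first), angle-encoded into a 4-qubit state, entangled with a CNOT
chain, optionally rotated by a per-filter bank of fixed seeded Ry angles,
and read out as Pauli-Z expectations.  The affine map ``(1 + <Z>) / 2``
keeps outputs in [0, 1], matching the input normalization convention.

Filter diversity comes from the seeded angle bank (`QuanvKernelBank`): one
circuit layout, many fixed random rotation layers, which is the standard
way a single small circuit yields a multi-channel feature map.

The implementation is vectorized: a single call simulates every
(window, filter) circuit pair of a layer in one batched statevector pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .quantum import EntanglementPattern, run_circuit

__all__ = [
    "QuanvLayerSpec",
    "QuanvKernelBank",
    "output_shape",
    "pad_amounts",
    "patch_to_features",
    "quanvolve",
    "quanv_pool",
]


@dataclass(frozen=True)
class QuanvLayerSpec:
    """Geometry and readout convention of one quanvolutional layer."""

    window: tuple[int, int]
    stride: int = 1
    padding: Literal["valid", "same"] = "valid"
    n_qubits: int = 4
    n_filters: int = 1
    entanglement: EntanglementPattern | None = None
    readout: Literal["mean_z", "per_qubit_z"] = "mean_z"

    def __post_init__(self) -> None:
        h, w = self.window
        if h < 1 or w < 1:
            raise ValueError("window dims must be >= 1")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.padding not in ("valid", "same"):
            raise ValueError("padding must be 'valid' or 'same'")
        if self.n_filters < 1:
            raise ValueError("n_filters must be >= 1")
        if self.readout not in ("mean_z", "per_qubit_z"):
            raise ValueError("readout must be 'mean_z' or 'per_qubit_z'")
        if self.readout == "per_qubit_z" and self.n_filters % self.n_qubits:
            raise ValueError(
                "per_qubit_z readout requires n_filters to be a multiple "
                f"of n_qubits ({self.n_qubits})"
            )
        if self.entanglement is None:
            object.__setattr__(
                self, "entanglement", EntanglementPattern.linear_chain(self.n_qubits)
            )
        self.entanglement.validate(self.n_qubits)

    @property
    def n_circuits(self) -> int:
        """Circuits evaluated per window (one per output-channel group)."""
        if self.readout == "per_qubit_z":
            return self.n_filters // self.n_qubits
        return self.n_filters

    def to_dict(self) -> dict:
        return {
            "window": list(self.window),
            "stride": self.stride,
            "padding": self.padding,
            "n_qubits": self.n_qubits,
            "n_filters": self.n_filters,
            "entanglement": self.entanglement.to_dict(),
            "readout": self.readout,
        }


@dataclass(frozen=True)
class QuanvKernelBank:
    """Fixed per-filter Ry angles drawn once from a seeded RNG.

    Regenerating with the same (seed, shape) yields bit-identical angles,
    which makes every quanvolution output reproducible.  The bank is frozen
    by default: angles act as random fixed filters and contribute no
    trainable parameters.
    """

    seed: int
    thetas: np.ndarray  # (n_circuits, n_qubits), radians in [0, 2*pi)
    trainable: bool = False

    @classmethod
    def for_spec(cls, spec: QuanvLayerSpec, seed: int, trainable: bool = False):
        rng = np.random.default_rng(seed)
        thetas = rng.uniform(0.0, 2.0 * np.pi, size=(spec.n_circuits, spec.n_qubits))
        return cls(seed=seed, thetas=thetas, trainable=trainable)

    @classmethod
    def zeros(cls, spec: QuanvLayerSpec, trainable: bool = False):
        """Identity bank (all angles zero) — useful for closed-form checks."""
        return cls(
            seed=-1,
            thetas=np.zeros((spec.n_circuits, spec.n_qubits)),
            trainable=trainable,
        )

    @property
    def n_parameters(self) -> int:
        return int(self.thetas.size) if self.trainable else 0


def output_shape(
    spec: QuanvLayerSpec, input_shape: tuple[int, ...]
) -> tuple[int, int, int]:
    """Spatial output arithmetic shared by quanvolution and pooling.

    valid: H_out = floor((H - h) / stride) + 1
    same:  H_out = ceil(H / stride), with symmetric zero padding
    """
    H, W = int(input_shape[0]), int(input_shape[1])
    if H < 1 or W < 1:
        raise ValueError("input dims must be positive")
    h, w = spec.window
    s = spec.stride
    if spec.padding == "valid":
        if h > H or w > W:
            raise ValueError(
                f"window {h}x{w} larger than input {H}x{W} with valid padding"
            )
        return ((H - h) // s + 1, (W - w) // s + 1, spec.n_filters)
    return (-(-H // s), -(-W // s), spec.n_filters)


def pad_amounts(spec: QuanvLayerSpec, input_shape: tuple[int, ...]):
    """(top, bottom, left, right) zero-padding realizing 'same' output size."""
    if spec.padding == "valid":
        return (0, 0, 0, 0)
    H, W = int(input_shape[0]), int(input_shape[1])
    h, w = spec.window
    s = spec.stride
    H_out, W_out, _ = output_shape(spec, input_shape)
    pad_h = max((H_out - 1) * s + h - H, 0)
    pad_w = max((W_out - 1) * s + w - W, 0)
    return (pad_h // 2, pad_h - pad_h // 2, pad_w // 2, pad_w - pad_w // 2)


def _quadrant_pool(windows: np.ndarray) -> np.ndarray:
    """Average-pool windows (..., h, w) down to 4 row-major features.

    Halves overlap by one row/column when the extent is odd; a 1-pixel
    extent replicates its value into both halves (this is how 1x1 kernels
    still feed all 4 qubits).
    """
    h, w = windows.shape[-2], windows.shape[-1]
    r_hi, r_lo = -(-h // 2), h // 2  # ceil, floor
    c_hi, c_lo = -(-w // 2), w // 2
    if h == 1:
        r_hi, r_lo = 1, 0
    if w == 1:
        c_hi, c_lo = 1, 0
    f00 = windows[..., :r_hi, :c_hi].mean(axis=(-2, -1))
    f01 = windows[..., :r_hi, c_lo:].mean(axis=(-2, -1))
    f10 = windows[..., r_lo:, :c_hi].mean(axis=(-2, -1))
    f11 = windows[..., r_lo:, c_lo:].mean(axis=(-2, -1))
    return np.stack([f00, f01, f10, f11], axis=-1)


def patch_to_features(patch: np.ndarray) -> np.ndarray:
    """Map one window to the 4 encoded features (2x2 average pool).

    Multi-channel patches are averaged across channels first; values are
    clipped to [0, 1] with a warning if they stray outside.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.ndim == 3:
        patch = patch.mean(axis=-1)
    if patch.ndim != 2:
        raise ValueError("patch must be (h, w) or (h, w, C)")
    if np.any(patch < 0) or np.any(patch > 1):
        warnings.warn("patch values outside [0, 1] were clipped", stacklevel=2)
        patch = np.clip(patch, 0.0, 1.0)
    return _quadrant_pool(patch)


def _extract_windows(image: np.ndarray, spec: QuanvLayerSpec) -> np.ndarray:
    """All strided windows of a (H, W, C) image -> (H_out, W_out, h, w)."""
    t, b, l, r = pad_amounts(spec, image.shape)
    if any((t, b, l, r)):
        image = np.pad(image, ((t, b), (l, r), (0, 0)))
    chan_mean = image.mean(axis=-1)
    h, w = spec.window
    view = sliding_window_view(chan_mean, (h, w))  # (H-h+1, W-w+1, h, w)
    return view[:: spec.stride, :: spec.stride]


def quanvolve(
    image: np.ndarray, spec: QuanvLayerSpec, bank: QuanvKernelBank
) -> np.ndarray:
    """Quanvolve one image -> feature map of shape (H_out, W_out, n_filters).

    Every window is pooled to 4 features, run through the encoding circuit
    once per filter (with that filter's bank angles), and mapped to [0, 1]
    via ``(1 + readout) / 2``.  ``mean_z`` averages the 4 qubit expectations
    into one channel per circuit; ``per_qubit_z`` emits all 4 per circuit.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        image = image[..., None]
    if image.ndim != 3:
        raise ValueError("image must be (H, W) or (H, W, C)")
    if bank.thetas.shape != (spec.n_circuits, spec.n_qubits):
        raise ValueError(
            f"bank shape {bank.thetas.shape} does not match spec "
            f"({spec.n_circuits}, {spec.n_qubits})"
        )
    H_out, W_out, _ = output_shape(spec, image.shape)
    windows = _extract_windows(image, spec)  # (H_out, W_out, h, w)
    feats = _quadrant_pool(windows).reshape(-1, spec.n_qubits)
    if np.any(feats < 0) or np.any(feats > 1):
        warnings.warn("image values outside [0, 1] were clipped", stacklevel=2)
        feats = np.clip(feats, 0.0, 1.0)
    # broadcast windows against filters: (n_windows, n_circuits, n_qubits)
    expectations = run_circuit(
        feats[:, None, :], spec.entanglement, bank.thetas[None, :, :]
    )
    if spec.readout == "mean_z":
        out = expectations.mean(axis=-1)  # (n_windows, n_circuits)
    else:
        out = expectations.reshape(feats.shape[0], -1)
    out = (1.0 + out) / 2.0
    return out.reshape(H_out, W_out, spec.n_filters)


def quanv_pool(
    fmap: np.ndarray,
    window: tuple[int, int],
    stride: int,
    padding: Literal["valid", "same"] = "valid",
) -> np.ndarray:
    """Channel-wise max pooling over sliding windows of a feature map."""
    fmap = np.asarray(fmap, dtype=float)
    if fmap.ndim == 2:
        fmap = fmap[..., None]
    if fmap.ndim != 3:
        raise ValueError("feature map must be (H, W) or (H, W, C)")
    geom = QuanvLayerSpec(
        window=window, stride=stride, padding=padding, n_filters=fmap.shape[-1]
    )
    H_out, W_out, _ = output_shape(geom, fmap.shape)
    t, b, l, r = pad_amounts(geom, fmap.shape)
    if any((t, b, l, r)):
        fmap = np.pad(
            fmap, ((t, b), (l, r), (0, 0)), constant_values=-np.inf
        )
    h, w = window
    view = sliding_window_view(fmap, (h, w), axis=(0, 1))
    view = view[::stride, ::stride]  # (H_out, W_out, C, h, w)
    return view.max(axis=(-2, -1))
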