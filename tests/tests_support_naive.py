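"""Shared independent oracle: naive per-window, per-filter quanvolution."""

import numpy as np

from quanvit.quantum import run_circuit
from quanvit.quanvolution import output_shape, pad_amounts, patch_to_features


def naive_quanvolve(image, spec, bank):
    H_out, W_out, _ = output_shape(spec, image.shape)
    img = image if image.ndim == 3 else image[..., None]
    t, b, l, r = pad_amounts(spec, img.shape)
    img = np.pad(img, ((t, b), (l, r), (0, 0)))
    h, w = spec.window
    out = np.zeros((H_out, W_out, spec.n_filters))
    for i in range(H_out):
        for j in range(W_out):
            patch = img[i * spec.stride : i * spec.stride + h,
                        j * spec.stride : j * spec.stride + w]
            feats = patch_to_features(patch)
            for f in range(spec.n_circuits):
                z = run_circuit(feats, spec.entanglement, bank.thetas[f])
                if spec.readout == "mean_z":
                    out[i, j, f] = (1 + z.mean()) / 2
                else:
                    out[i, j, 4 * f : 4 * (f + 1)] = (1 + z) / 2
    return out
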