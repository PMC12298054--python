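"""scikit-learn estimators wrapping the hybrid classifier and the quanvolution.

`QuanViTClassifier` follows the sklearn contract (``fit`` / ``predict`` /
``predict_proba``, ``get_params`` / ``set_params``, fitted attributes with a
trailing underscore) so it composes with pipelines and model selection.
Inputs are image batches of shape (n_samples, H, W, 3) with values in
[0, 1] (uint8 accepted and rescaled).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .architecture import ModelConfig, ViTSpec, build_model, count_macs
from .pipeline import TrainSpec, train
from .quanvolution import QuanvKernelBank, QuanvLayerSpec, quanvolve

__all__ = ["QuanViTClassifier", "QuanvolutionTransformer"]


def _check_images(X) -> np.ndarray:
    X = np.asarray(X)
    if X.dtype == np.uint8:
        X = X.astype(float) / 255.0
    if X.ndim == 3 and X.shape[-1] in (1, 3, 4):  # a single image
        X = X[None]
    if X.ndim != 4:
        raise ValueError("X must be a 4-D image batch (n, H, W, C)")
    return X


class QuanViTClassifier(ClassifierMixin, BaseEstimator):
    """Hybrid backbone + vision-transformer image classifier.

    Parameters
    ----------
    mode : {'qnn', 'cnn'}
        'qnn' uses a frozen quanvolutional backbone (only the transformer
        and head train); 'cnn' uses a fully trainable convolutional one.
    scale : float in (0, 1]
        Width/depth multiplier; 1.0 is the full published geometry.
    validation_fraction : float
        Stratified fraction of the training data held out internally for
        early stopping when no explicit validation set is passed to fit.
    """

    def __init__(
        self,
        mode: str = "qnn",
        scale: float = 0.125,
        lr: float = 1e-3,
        batch_size: int = 32,
        max_epochs: int = 20,
        patience: int = 5,
        validation_fraction: float = 0.2,
        vit_depth: int = 12,
        vit_dim: int = 768,
        vit_heads: int = 12,
        upsample_tokens: bool = False,
        use_norm: bool = True,
        quanv_seed: int | None = None,
        seed: int = 0,
    ):
        self.mode = mode
        self.scale = scale
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.vit_depth = vit_depth
        self.vit_dim = vit_dim
        self.vit_heads = vit_heads
        self.upsample_tokens = upsample_tokens
        self.use_norm = use_norm
        self.quanv_seed = quanv_seed
        self.seed = seed

    # -- sklearn plumbing ----------------------------------------------------
    def _make_config(self, input_size, n_classes) -> ModelConfig:
        mode = {"qnn": "quantum", "cnn": "classical"}.get(self.mode, self.mode)
        return ModelConfig(
            input_size=input_size,
            mode=mode,
            n_classes=n_classes,
            scale=self.scale,
            vit=ViTSpec(
                dim=self.vit_dim,
                depth=self.vit_depth,
                heads=self.vit_heads,
                mlp_dim=4 * self.vit_dim,
                upsample_tokens=self.upsample_tokens,
            ),
            use_norm=self.use_norm,
            seed=self.seed,
            quanv_seed=self.quanv_seed,
        )

    def fit(self, X, y, X_val=None, y_val=None):
        """Fit on images X (n, H, W, 3) and labels y.

        An explicit validation set may be supplied; otherwise a stratified
        ``validation_fraction`` of (X, y) is held out for early stopping.
        """
        X = _check_images(X)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        if X_val is None:
            from sklearn.model_selection import train_test_split

            X, X_val, y_idx, y_val_idx = train_test_split(
                X, y_idx, test_size=self.validation_fraction,
                stratify=y_idx, random_state=self.seed,
            )
        else:
            X_val = _check_images(X_val)
            y_val_idx = np.searchsorted(self.classes_, np.asarray(y_val))
        self.config_ = self._make_config(X.shape[1:], len(self.classes_))
        self.model_ = build_model(self.config_)
        spec = TrainSpec(
            lr=self.lr, batch_size=self.batch_size, max_epochs=self.max_epochs,
            patience=self.patience, seed=self.seed,
        )
        self.history_ = train(self.model_, X, y_idx, X_val, y_val_idx, spec)
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = _check_images(X)
        out = []
        for i in range(0, len(X), 64):
            out.append(self.model_.predict_proba(X[i : i + 64]))
        return np.concatenate(out)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[proba.argmax(axis=1)]

    def complexity(self):
        """ComplexityReport (parameters / MACs / FLOPs / circuit evals)."""
        check_is_fitted(self, "model_")
        return count_macs(self.model_)


class QuanvolutionTransformer(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer applying one quanvolutional layer.

    transform maps (n, H, W, C) image batches to flattened quanvolution
    feature maps; the seeded angle bank is drawn in ``fit``.
    """

    def __init__(self, window: int = 2, stride: int = 2, padding: str = "valid",
                 n_filters: int = 4, readout: str = "mean_z", seed: int = 0):
        self.window = window
        self.stride = stride
        self.padding = padding
        self.n_filters = n_filters
        self.readout = readout
        self.seed = seed

    def fit(self, X, y=None):
        self.spec_ = QuanvLayerSpec(
            window=(self.window, self.window), stride=self.stride,
            padding=self.padding, n_filters=self.n_filters, readout=self.readout,
        )
        self.bank_ = QuanvKernelBank.for_spec(self.spec_, self.seed)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "bank_")
        X = _check_images(X)
        maps = np.stack([quanvolve(img, self.spec_, self.bank_) for img in X])
        return maps.reshape(len(maps), -1)
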