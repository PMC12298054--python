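"""Preprocessing, training, holdout evaluation and k-fold cross-validation.

Training minimizes cross-entropy with Adam, records per-epoch train and
validation accuracy/loss, early-stops on validation loss and restores the
best-validation weights.  When the backbone is a frozen quanvolutional
feature extractor its features are computed once per image and cached, so
only the transformer and head are optimized.

Cross-validation is stratified, disjoint and exhaustive over the train+val
pool; the reserved test holdout is never touched and a fresh model is fit
per fold.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .architecture import HybridModel, ModelConfig, build_model
from .metrics import (
    MetricSet,
    MultiClassMetrics,
    aggregate_folds,
    compute_metrics,
    confusion_matrix,
)
from .nn import Adam, BatchChannelNorm, cross_entropy, _collect_modules

logger = logging.getLogger("quanvit")

__all__ = [
    "PreprocessSpec",
    "TrainSpec",
    "TrainHistory",
    "preprocess",
    "train",
    "evaluate",
    "crossval",
]


@dataclass(frozen=True)
class PreprocessSpec:
    """Resize target and [0, 1] intensity normalization."""

    resize: int = 224


def preprocess(images: np.ndarray, spec: PreprocessSpec) -> np.ndarray:
    """Resize a uint8/float batch and normalize intensities into [0, 1]."""
    from skimage.transform import resize

    images = np.asarray(images)
    if images.dtype == np.uint8:
        images = images.astype(float) / 255.0
    if images.ndim == 3:
        images = images[None]
    n, h, w, c = images.shape
    if (h, w) != (spec.resize, spec.resize):
        images = np.stack(
            [
                resize(img, (spec.resize, spec.resize, c), preserve_range=True,
                       anti_aliasing=h > spec.resize)
                for img in images
            ]
        )
    return np.clip(images, 0.0, 1.0)


@dataclass(frozen=True)
class TrainSpec:
    """Optimizer and schedule hyper-parameters."""

    lr: float = 1e-3
    betas: tuple[float, float] = (0.9, 0.99)  # beta2 0.99 adapts faster at small step counts
    batch_size: int = 32
    max_epochs: int = 50
    patience: int = 5
    clip_norm: float = 1.0  # global gradient-norm clip (0 disables)
    seed: int = 0

    def __post_init__(self):
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainHistory:
    """Per-epoch curves plus the epoch whose weights were restored."""

    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1
    seconds: float = 0.0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train_loss) + 1),
                "train_loss": self.train_loss,
                "train_accuracy": self.train_accuracy,
                "val_loss": self.val_loss,
                "val_accuracy": self.val_accuracy,
            }
        )


def _refresh_norm_stats(model: HybridModel, X: np.ndarray, batch: int) -> None:
    """Precise normalization statistics: one forward-only pass over X.

    Running batchnorm averages lag the weights by the EMA horizon, which at
    desk scale (a handful of optimizer steps per epoch) makes evaluation-mode
    accuracy badly stale; re-estimating the statistics after each epoch
    removes the lag at the cost of one gradient-free forward pass.
    """
    norms = [
        m for m in _collect_modules(model) if isinstance(m, BatchChannelNorm)
    ]
    if not norms:
        return
    for norm in norms:
        norm.begin_stat_refresh()
    model.train()
    for i in range(0, len(X), batch):
        model.forward(X[i : i + batch])
    for norm in norms:
        norm.end_stat_refresh()


def _forward_dataset(model: HybridModel, feats: np.ndarray, labels: np.ndarray,
                     batch: int):
    """Loss and accuracy over a cached-feature dataset (no gradients)."""
    losses, correct = [], 0
    model.eval()
    for i in range(0, len(labels), batch):
        logits = model.head_forward(feats[i : i + batch])
        loss = cross_entropy(logits, labels[i : i + batch])
        losses.append(loss.data.item() * len(labels[i : i + batch]))
        correct += int((logits.data.argmax(axis=1) == labels[i : i + batch]).sum())
    return sum(losses) / len(labels), correct / len(labels)


def train(
    model: HybridModel,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    spec: TrainSpec | None = None,
) -> TrainHistory:
    """Fit the model; returns per-epoch history with best weights restored."""
    spec = spec or TrainSpec()
    if len(X_train) == 0 or len(X_val) == 0:
        raise ValueError("train and validation splits must be non-empty")
    if set(np.unique(y_train)) & set(np.unique(y_val)) == set():
        raise ValueError("train and validation share no classes")
    t0 = time.time()
    rng = np.random.default_rng(spec.seed)
    logger.info(
        "training %s-mode model: %d train / %d val, lr=%g, batch=%d",
        model.config.mode, len(y_train), len(y_val), spec.lr, spec.batch_size,
    )
    # frozen backbone => cache features once; trainable => recompute per batch
    if model.backbone_frozen:
        feats_train = model.backbone_features(X_train)
        feats_val = model.backbone_features(X_val)
    else:
        feats_train = feats_val = None
    params = list(model.parameters())
    opt = Adam(params, lr=spec.lr, betas=spec.betas)
    history = TrainHistory()
    best_val = np.inf
    best_state = model.state_dict()
    since_best = 0
    for epoch in range(spec.max_epochs):
        model.train()
        order = rng.permutation(len(y_train))
        ep_loss, ep_correct = 0.0, 0
        for i in range(0, len(order), spec.batch_size):
            idx = order[i : i + spec.batch_size]
            if feats_train is not None:
                logits = model.head_forward(feats_train[idx])
            else:
                logits = model.forward(X_train[idx])
            loss = cross_entropy(logits, y_train[idx])
            ep_loss += loss.data.item() * len(idx)
            ep_correct += int((logits.data.argmax(axis=1) == y_train[idx]).sum())
            opt.zero_grad()
            loss.backward()
            if spec.clip_norm > 0:
                total = np.sqrt(
                    sum(float((p.grad**2).sum()) for p in params
                        if p.grad is not None)
                )
                if total > spec.clip_norm:
                    for p in params:
                        if p.grad is not None:
                            p.grad *= spec.clip_norm / total
            opt.step()
        history.train_loss.append(ep_loss / len(y_train))
        history.train_accuracy.append(ep_correct / len(y_train))
        if feats_train is None:
            _refresh_norm_stats(model, X_train, spec.batch_size)
        if feats_val is not None:
            val_loss, val_acc = _forward_dataset(
                model, feats_val, y_val, spec.batch_size
            )
        else:
            model.eval()
            losses, correct = 0.0, 0
            for i in range(0, len(y_val), spec.batch_size):
                logits = model.forward(X_val[i : i + spec.batch_size])
                losses += cross_entropy(
                    logits, y_val[i : i + spec.batch_size]
                ).data.item() * len(y_val[i : i + spec.batch_size])
                correct += int(
                    (logits.data.argmax(axis=1) == y_val[i : i + spec.batch_size]).sum()
                )
            val_loss, val_acc = losses / len(y_val), correct / len(y_val)
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)
        logger.info(
            "epoch %d: train loss %.4f acc %.3f | val loss %.4f acc %.3f",
            epoch + 1, history.train_loss[-1], history.train_accuracy[-1],
            val_loss, val_acc,
        )
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = model.state_dict()
            history.best_epoch = epoch + 1
            since_best = 0
        else:
            since_best += 1
            if since_best >= spec.patience:
                logger.info("early stop at epoch %d", epoch + 1)
                break
    model.load_state_dict(best_state)
    model.eval()
    history.seconds = time.time() - t0
    return history


def evaluate(
    model: HybridModel, X: np.ndarray, y: np.ndarray, n_classes: int | None = None
) -> tuple[np.ndarray, MetricSet | MultiClassMetrics]:
    """Confusion matrix and metric set of the fitted model on (X, y)."""
    if n_classes is None:
        n_classes = model.config.n_classes
    probs = []
    for i in range(0, len(y), 64):
        probs.append(model.predict_proba(X[i : i + 64]))
    pred = np.concatenate(probs).argmax(axis=1)
    cm = confusion_matrix(y, pred, n_classes)
    return cm, compute_metrics(cm)


def crossval(
    config: ModelConfig,
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    seed: int = 0,
    train_spec: TrainSpec | None = None,
):
    """Stratified k-fold cross-validation with a fresh model per fold.

    Returns (per-fold metric rows, per-fold confusion matrices, summary of
    per-metric mean +- sample SD).
    """
    from sklearn.model_selection import StratifiedKFold

    if k < 2:
        raise ValueError("k must be >= 2")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"stratification infeasible: smallest class has {counts.min()} < k={k}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_metrics: list[MetricSet | MultiClassMetrics] = []
    fold_cms: list[np.ndarray] = []
    for fold, (tr, va) in enumerate(skf.split(np.zeros(len(y)), y)):
        from dataclasses import replace

        model = build_model(config)
        spec = replace(train_spec or TrainSpec(), seed=(train_spec or TrainSpec()).seed + fold)
        train(model, X[tr], y[tr], X[va], y[va], spec)
        cm, metrics = evaluate(model, X[va], y[va])
        fold_metrics.append(metrics)
        fold_cms.append(cm)
    if isinstance(fold_metrics[0], MetricSet):
        summary = aggregate_folds(fold_metrics)
    else:
        from .metrics import fold_mean_sd

        summary = {
            "overall_accuracy": fold_mean_sd(
                [m.overall_accuracy for m in fold_metrics]
            )
        }
    return fold_metrics, fold_cms, summary
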