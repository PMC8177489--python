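"""Task-specific CNN for ONH SLO images, plus an inception-style benchmark.

The classifier is deliberately compact for the low-data regime: three
convolutional blocks of 3, 2 and 2 stride-1 conv layers (batch norm + ReLU
after each), every block preceded by a 2x2 average pooling and followed by a
2x2 max pooling, then a 128-unit fully connected layer, dropout at 0.60 and
a 2-unit softmax head.  Training uses Adam (lr 0.001), two-class
cross-entropy, Glorot-uniform kernels / zero biases, up to 250 epochs with
the best-validation-accuracy epoch checkpointed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .preprocess import AugmentationConfig, augment


class ArchitectureError(ValueError):
    """Architecture spec incompatible with its input shape or task."""


@dataclass(frozen=True)
class CnnArchitectureSpec:
    """Structure of the task-specific CNN; defaults match the full-size model.

    ``filters_per_block`` is exposed because the publication figure this
    architecture follows does not pin the counts; 8/16/32 keeps the model in
    the intended low-parameter regime.
    """

    input_shape: tuple[int, int, int] = (156, 238, 1)
    conv_layer_counts: tuple[int, ...] = (3, 2, 2)
    filters_per_block: tuple[int, ...] = (8, 16, 32)
    kernel_size: int = 3
    dense_units: int = 128
    dropout_rate: float = 0.60
    n_classes: int = 2

    def validate(self) -> None:
        if len(self.conv_layer_counts) != len(self.filters_per_block):
            raise ArchitectureError("one filter count required per block")
        if self.n_classes != 2:
            raise ArchitectureError(
                f"final layer width must be 2 for the binary task, got {self.n_classes}"
            )
        if self.input_shape[2] != 1:
            raise ArchitectureError("expects single-channel input")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ArchitectureError("dropout rate must lie in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol; defaults follow the study training recipe."""

    learning_rate: float = 0.001
    max_epochs: int = 250
    batch_size: int = 16
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainedModel:
    """A checkpointed network plus its per-epoch history."""

    network: nn.Sequential
    history: pd.DataFrame  # epoch, train_loss, train_acc, val_loss, val_acc
    best_epoch: int

    @property
    def best_val_accuracy(self) -> float:
        return float(self.history["val_acc"].iloc[self.best_epoch])


def build_custom_cnn(spec: CnnArchitectureSpec | None = None, seed: int = 0) -> nn.Sequential:
    """Build the untrained task-specific CNN.

    Raises :class:`ArchitectureError` when the pooling schedule exhausts the
    spatial extent of the input (each block halves it twice).
    """
    spec = spec or CnnArchitectureSpec()
    spec.validate()
    rng = np.random.default_rng(seed)
    h, w, in_ch = spec.input_shape
    layers: list[nn.Layer] = []
    for b, (n_conv, n_filt) in enumerate(
        zip(spec.conv_layer_counts, spec.filters_per_block)
    ):
        layers.append(nn.AvgPool2())
        h, w = h // 2, w // 2
        if h < 1 or w < 1:
            raise ArchitectureError(
                f"input {spec.input_shape[:2]} exhausted at block {b} average pooling"
            )
        for _ in range(n_conv):
            layers += [
                nn.Conv2D(in_ch, n_filt, ksize=spec.kernel_size, rng=rng),
                nn.BatchNorm(n_filt),
                nn.ReLU(),
            ]
            in_ch = n_filt
        layers.append(nn.MaxPool2())
        h, w = h // 2, w // 2
        if h < 1 or w < 1:
            raise ArchitectureError(
                f"input {spec.input_shape[:2]} exhausted at block {b} max pooling"
            )
    layers += [
        nn.Flatten(),
        nn.Dense(h * w * in_ch, spec.dense_units, rng=rng),
        nn.ReLU(),
        nn.Dropout(spec.dropout_rate, rng=np.random.default_rng(rng.integers(2**31))),
        nn.Dense(spec.dense_units, spec.n_classes, rng=rng),
    ]
    return nn.Sequential(layers)


def build_modified_inception(
    input_shape: tuple[int, int, int] = (156, 238, 1),
    head_widths: tuple[int, int] = (128, 2),
    pretrained: bool = False,
    seed: int = 0,
    stem_filters: int = 16,
    block_widths: tuple[tuple[int, int, int, int], ...] = (
        (16, 24, 8, 8),
        (32, 48, 16, 16),
        (48, 64, 24, 24),
    ),
) -> nn.Sequential:
    """Inception-style benchmark: multi-branch backbone + a new 128/2 head.

    The backbone stacks parallel-branch (1x1 / 3x3 / double-3x3 / pooled)
    modules between pooling stages, global-average-pools, then applies the
    replacement fully connected layers of sizes 128 and 2.  The whole model
    is trainable.  No pretrained weight file ships with this package, so
    ``pretrained=True`` raises.
    """
    if pretrained:
        raise FileNotFoundError(
            "no pretrained backbone weights are available locally; "
            "build with pretrained=False for random initialization"
        )
    if head_widths[1] != 2:
        raise ArchitectureError("final head width must be 2 for the binary task")
    rng = np.random.default_rng(seed)
    h, w, in_ch = input_shape
    layers: list[nn.Layer] = [
        nn.Conv2D(in_ch, stem_filters, ksize=3, rng=rng),
        nn.BatchNorm(stem_filters),
        nn.ReLU(),
        nn.MaxPool2(),
        nn.MaxPool2(),
    ]
    ch = stem_filters
    for widths in block_widths:
        block = nn.InceptionBlock(ch, widths, rng=rng)
        layers.append(block)
        ch = block.out_ch
        layers.append(nn.MaxPool2())
    layers += [
        nn.GlobalAvgPool(),
        nn.Dense(ch, head_widths[0], rng=rng),
        nn.ReLU(),
        nn.Dense(head_widths[0], head_widths[1], rng=rng),
    ]
    return nn.Sequential(layers)


def select_best_epoch(val_accuracies) -> int:
    """Index of the maximum validation accuracy; ties go to the earlier epoch."""
    val_accuracies = np.asarray(val_accuracies)
    if val_accuracies.size == 0:
        raise ValueError("empty validation history")
    return int(np.argmax(val_accuracies))


def _accuracy(probs: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean(probs.argmax(axis=1) == y))


def train_model(
    network: nn.Sequential,
    train_images: np.ndarray,
    train_y: np.ndarray,
    val_images: np.ndarray,
    val_y: np.ndarray,
    config: TrainConfig | None = None,
    augmentation: AugmentationConfig | None = None,
) -> TrainedModel:
    """Train with Adam + cross-entropy, checkpointing on validation accuracy.

    ``train_y``/``val_y`` are integer class indices (0 = control,
    1 = glaucoma).  Augmentation, when given, is redrawn for every training
    image every epoch; validation images are never augmented.
    """
    config = config or TrainConfig()
    config.validate()
    if len(np.unique(train_y)) < 2:
        raise ValueError("training set must contain both classes")
    if len(val_images) == 0:
        raise ValueError("validation set must be non-empty")
    rng = np.random.default_rng(config.seed)
    optimizer = nn.Adam(network, learning_rate=config.learning_rate)

    x_train = np.asarray(train_images, dtype=float)
    x_val = np.asarray(val_images, dtype=float)[..., None]
    history = []
    best_state, best_acc, best_epoch = None, -np.inf, -1
    n = len(x_train)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        losses, accs = [], []
        for start in range(0, n, config.batch_size):
            idx = order[start: start + config.batch_size]
            xb = x_train[idx]
            if augmentation is not None:
                xb = np.stack([augment(im, augmentation, rng) for im in xb])
            yb = train_y[idx]
            logits = network.forward(xb[..., None], train=True)
            probs = nn.softmax(logits)
            losses.append(nn.cross_entropy(probs, yb))
            accs.append(_accuracy(probs, yb))
            grad = probs.copy()
            grad[np.arange(len(yb)), yb] -= 1.0
            grad /= len(yb)
            for layer in reversed(network.layers):
                grad = layer.backward(grad)
            optimizer.step()
        val_probs = network.predict_proba(x_val)
        val_loss = nn.cross_entropy(val_probs, val_y)
        val_acc = _accuracy(val_probs, val_y)
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "train_acc": float(np.mean(accs)),
                "val_loss": val_loss,
                "val_acc": val_acc,
            }
        )
        if val_acc > best_acc:  # strict: ties keep the earlier epoch
            best_acc, best_epoch = val_acc, epoch
            best_state = network.get_weights()
    network.set_weights(best_state)
    return TrainedModel(
        network=network, history=pd.DataFrame(history), best_epoch=best_epoch
    )


def predict_support(model: TrainedModel | nn.Sequential, images: np.ndarray) -> np.ndarray:
    """Per-image (p_control, p_glaucoma) pairs; deterministic at inference."""
    network = model.network if isinstance(model, TrainedModel) else model
    images = np.asarray(images, dtype=float)
    if images.ndim == 2:
        images = images[None]
    if images.ndim != 3:
        raise ValueError(f"expected (n, height, width) images, got shape {images.shape}")
    return network.predict_proba(images[..., None])


def make_cnn_trainer(
    spec: CnnArchitectureSpec | None = None,
    config: TrainConfig | None = None,
    augmentation: AugmentationConfig | None = None,
):
    """Adapter turning the CNN into an ensemble-module trainer callable.

    The returned ``trainer(x_train, y_train, x_val, y_val, seed)`` accepts
    string class labels, builds a freshly initialized network per call and
    returns the checkpointed :class:`TrainedModel`.
    """
    from dataclasses import replace

    from .evaluation import CONTROL, GLAUCOMA

    spec = spec or CnnArchitectureSpec()
    config = config or TrainConfig()
    label_to_int = {CONTROL: 0, GLAUCOMA: 1}

    def trainer(x_train, y_train, x_val, y_val, seed):
        net = build_custom_cnn(spec, seed=seed)
        y_tr = np.array([label_to_int[l] for l in y_train])
        y_va = np.array([label_to_int[l] for l in y_val])
        return train_model(
            net, x_train, y_tr, x_val, y_va,
            config=replace(config, seed=seed), augmentation=augmentation,
        )

    return trainer


def cnn_support_fn(model: TrainedModel, images: np.ndarray) -> np.ndarray:
    """Ensemble-module support function for trained CNNs."""
    return predict_support(model, images)
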