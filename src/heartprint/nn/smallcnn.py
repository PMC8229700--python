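"""The small residual CNN: declarative 27-layer spec, parameter count,
training, and prediction.

The network is a compact residual classifier for square RGB scalogram
images: a 7x7/32 stem with max pooling, an identity residual block at
32 channels, two strided residual stages (64 then 128 channels) whose
shortcuts are a 1x1 stride-2 projection convolution followed by a
stride-2 max pooling, global max pooling, and a fully connected softmax
head.  Because the head sits behind global max pooling, the learnable
parameter count is independent of the input image size; the canonical
input is 224x224x3 and smaller inputs (32 or 64) are used for CPU-scale
experiments.

Training is plain mini-batch SGD with momentum (defaults: batch 150,
momentum 0.9, learning rate 0.001, 80 epochs) minimizing cross-entropy.
Everything is NumPy; runs are bit-deterministic under a fixed seed.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .layers import (BatchNorm2d, Conv2d, Dense, GlobalMaxPool, MaxPool2d,
                     ReLU, cross_entropy_grad, softmax)

__all__ = ["LayerSpec", "SmallCnnSpec", "TrainConfig", "TrainedModel",
           "build_small_cnn", "count_parameters", "SmallCnn", "train",
           "predict", "Classifier", "SmallCnnClassifier"]

KINDS = {"image_input", "convolution", "max_pooling", "relu", "batch_norm",
         "addition", "global_max_pooling", "fully_connected", "softmax",
         "classification_output"}


@dataclass(frozen=True)
class LayerSpec:
    index: int
    kind: str
    n_filters: int | None = None
    filter_size: int | None = None
    stride: int | None = None
    padding: int | None = None
    in_channels: int | None = None
    inputs: tuple[int, ...] = ()   # indices of source layers (DAG wiring)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")


@dataclass
class SmallCnnSpec:
    layers: list[LayerSpec]
    num_classes: int
    input_size: int = 224

    def __post_init__(self) -> None:
        if len(self.layers) != 27:
            raise ValueError(f"small CNN must have 27 layers, got {len(self.layers)}")
        n_add = sum(1 for l in self.layers if l.kind == "addition")
        if n_add != 3:
            raise ValueError(f"small CNN must have 3 addition layers, got {n_add}")

    @property
    def n_layers(self) -> int:
        return len(self.layers)


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    momentum: float = 0.9
    batch_size: int = 150
    epochs: int = 80
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.momentum, self.batch_size,
               self.epochs) <= 0:
            raise ValueError("training hyperparameters must be positive")


def build_small_cnn(num_classes: int, input_size: int = 224) -> SmallCnnSpec:
    """Declarative 27-layer spec of the small residual CNN."""
    if num_classes < 2:
        raise ValueError("num_classes must be >= 2")
    L = LayerSpec
    layers = [
        L(1, "image_input"),
        L(2, "convolution", 32, 7, 1, 3, in_channels=3, inputs=(1,)),
        L(3, "max_pooling", None, 2, 2, 1, inputs=(2,)),
        L(4, "relu", inputs=(3,)),
        L(5, "batch_norm", in_channels=32, inputs=(4,)),
        L(6, "convolution", 32, 3, 1, 1, in_channels=32, inputs=(5,)),
        L(7, "convolution", 32, 3, 1, 1, in_channels=32, inputs=(6,)),
        L(8, "batch_norm", in_channels=32, inputs=(7,)),
        L(9, "addition", inputs=(5, 8)),
        L(10, "relu", inputs=(9,)),
        L(11, "convolution", 64, 3, 2, 1, in_channels=32, inputs=(10,)),
        L(12, "convolution", 64, 3, 2, 1, in_channels=64, inputs=(11,)),
        L(13, "batch_norm", in_channels=64, inputs=(12,)),
        L(14, "convolution", 64, 1, 2, 0, in_channels=32, inputs=(10,)),
        L(15, "max_pooling", None, 2, 2, 1, inputs=(14,)),
        L(16, "addition", inputs=(13, 15)),
        L(17, "batch_norm", in_channels=64, inputs=(16,)),
        L(18, "convolution", 128, 3, 2, 1, in_channels=64, inputs=(17,)),
        L(19, "convolution", 128, 3, 2, 1, in_channels=128, inputs=(18,)),
        L(20, "batch_norm", in_channels=128, inputs=(19,)),
        L(21, "convolution", 128, 1, 2, 0, in_channels=64, inputs=(17,)),
        L(22, "max_pooling", None, 2, 2, 1, inputs=(21,)),
        L(23, "addition", inputs=(20, 22)),
        L(24, "global_max_pooling", inputs=(23,)),
        L(25, "fully_connected", n_filters=num_classes, in_channels=128,
          inputs=(24,)),
        L(26, "softmax", inputs=(25,)),
        L(27, "classification_output", inputs=(26,)),
    ]
    return SmallCnnSpec(layers=layers, num_classes=num_classes,
                        input_size=input_size)


def count_parameters(spec: SmallCnnSpec) -> int:
    """Learnable parameters: conv/FC weights+biases, BN scale+offset.

    Strides, padding, and pooling carry no parameters, so the count is
    robust to input-size and stride choices.
    """
    total = 0
    for l in spec.layers:
        if l.kind == "convolution":
            total += l.filter_size ** 2 * l.in_channels * l.n_filters + l.n_filters
        elif l.kind == "batch_norm":
            total += 2 * l.in_channels
        elif l.kind == "fully_connected":
            total += l.in_channels * l.n_filters + l.n_filters
    return total


class SmallCnn:
    """Runtime network instantiated from a :class:`SmallCnnSpec`."""

    def __init__(self, spec: SmallCnnSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.modules: dict[int, object] = {}
        for l in spec.layers:
            if l.kind == "convolution":
                self.modules[l.index] = Conv2d(l.in_channels, l.n_filters,
                                               l.filter_size, l.stride,
                                               l.padding, rng=rng)
            elif l.kind == "batch_norm":
                self.modules[l.index] = BatchNorm2d(l.in_channels)
            elif l.kind == "relu":
                self.modules[l.index] = ReLU()
            elif l.kind == "max_pooling":
                self.modules[l.index] = MaxPool2d(l.filter_size, l.stride,
                                                  l.padding)
            elif l.kind == "global_max_pooling":
                self.modules[l.index] = GlobalMaxPool()
            elif l.kind == "fully_connected":
                self.modules[l.index] = Dense(l.in_channels, l.n_filters,
                                              rng=rng)

    def n_parameters(self) -> int:
        return sum(m.n_parameters() for m in self.modules.values()
                   if hasattr(m, "n_parameters"))

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        """x is NHWC float32; returns class probabilities (N, classes)."""
        outs: dict[int, np.ndarray] = {1: x}
        for l in self.spec.layers[1:]:
            if l.kind == "addition":
                a, b = (outs[i] for i in l.inputs)
                if a.shape != b.shape:
                    raise ValueError(
                        f"addition layer {l.index}: branch shapes differ "
                        f"({a.shape} vs {b.shape}); input size "
                        f"{x.shape[-1]} is incompatible with this wiring")
                outs[l.index] = a + b
            elif l.kind == "softmax":
                outs[l.index] = softmax(outs[l.inputs[0]])
            elif l.kind == "classification_output":
                outs[l.index] = outs[l.inputs[0]]
            elif l.kind == "batch_norm":
                outs[l.index] = self.modules[l.index].forward(
                    outs[l.inputs[0]], training=training)
            else:
                outs[l.index] = self.modules[l.index].forward(outs[l.inputs[0]])
        self._outs = outs
        return outs[27]

    def backward(self, grad_logits: np.ndarray) -> None:
        """Backprop from the gradient w.r.t. the FC logits (layer 25)."""
        # consumers map: layer index -> accumulated downstream gradient
        grads: dict[int, np.ndarray] = {25: grad_logits}
        for l in reversed(self.spec.layers):
            if l.index not in grads or l.kind in ("image_input",):
                continue
            g = grads.pop(l.index)
            if l.kind in ("softmax", "classification_output"):
                continue  # handled analytically via cross_entropy_grad
            if l.kind == "addition":
                up = [(i, g) for i in l.inputs]
            else:
                up = [(l.inputs[0], self.modules[l.index].backward(g))]
            for idx, gu in up:
                grads[idx] = grads[idx] + gu if idx in grads else gu

    def parameters(self):
        ps, gs = [], []
        for idx in sorted(self.modules):
            m = self.modules[idx]
            ps.extend(m.params())
            gs.extend(m.grads())
        return ps, gs


@dataclass
class TrainedModel:
    spec: SmallCnnSpec
    network: SmallCnn
    classes: list[str]
    log: list[dict] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "TrainedModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def _check_images(images: np.ndarray) -> np.ndarray:
    images = np.ascontiguousarray(images, dtype=np.float32)
    if images.ndim != 4 or images.shape[3] != 3:
        raise ValueError("images must be (n, H, W, 3)")
    return images


def train(spec: SmallCnnSpec, images: np.ndarray, labels: np.ndarray,
          config: TrainConfig = TrainConfig()) -> TrainedModel:
    """Train the small CNN on labelled images (NHWC, float in [0, 1]).

    Deterministic given ``config.seed``: weight init, per-epoch
    shuffling, and all arithmetic are seeded NumPy.
    """
    labels = np.asarray(labels, dtype=object)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("training requires at least two classes")
    if len(classes) != spec.num_classes:
        missing = spec.num_classes - len(classes)
        raise ValueError(f"spec expects {spec.num_classes} classes, data has "
                         f"{len(classes)} ({missing} absent)")
    class_to_idx = {c: i for i, c in enumerate(classes)}
    y = np.array([class_to_idx[l] for l in labels])
    x = _check_images(images)
    if x.shape[1] != spec.input_size:
        raise ValueError(f"images are {x.shape[1]}px, spec expects "
                         f"{spec.input_size}px")

    net = SmallCnn(spec, seed=config.seed)
    params, _ = net.parameters()
    velocity = [np.zeros_like(p) for p in params]
    rng = np.random.default_rng(config.seed + 1)
    log = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(x))
        losses, correct = [], 0
        for start in range(0, len(x), config.batch_size):
            idx = order[start:start + config.batch_size]
            probs = net.forward(x[idx], training=True)
            loss, grad = cross_entropy_grad(probs, y[idx])
            net.backward(grad.astype(np.float32))
            _, grads = net.parameters()
            for p, v, g in zip(params, velocity, grads):
                v *= config.momentum
                v += g
                p -= config.learning_rate * v
            losses.append(loss * len(idx))
            correct += int((probs.argmax(axis=1) == y[idx]).sum())
        log.append({"epoch": epoch + 1,
                    "loss": sum(losses) / len(x),
                    "accuracy": correct / len(x)})
    return TrainedModel(spec=spec, network=net, classes=classes, log=log)


def predict(model: TrainedModel, images: np.ndarray,
            batch_size: int = 150) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and probability vectors for a batch of images.

    Probabilities sum to 1; the label is the argmax with ties broken by
    the lowest class index (NumPy argmax convention).
    """
    x = _check_images(images)
    probs = np.concatenate([
        model.network.forward(x[i:i + batch_size], training=False)
        for i in range(0, len(x), batch_size)])
    labels = np.array([model.classes[i] for i in probs.argmax(axis=1)],
                      dtype=object)
    return labels, probs


# ---------------------------------------------------------------------------
# Classifier plug-in interface
# ---------------------------------------------------------------------------

class Classifier:
    """Fit/predict contract for any image classifier (plug-in point for
    transfer-learning backbones or baseline models)."""

    def fit(self, images: np.ndarray, labels: np.ndarray) -> "Classifier":
        raise NotImplementedError

    def predict(self, images: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class SmallCnnClassifier(Classifier):
    def __init__(self, num_classes: int, input_size: int = 224,
                 config: TrainConfig = TrainConfig()):
        self.spec = build_small_cnn(num_classes, input_size=input_size)
        self.config = config
        self.model: TrainedModel | None = None

    def fit(self, images, labels):
        self.model = train(self.spec, images, labels, self.config)
        return self

    def predict(self, images):
        if self.model is None:
            raise RuntimeError("classifier is not fitted")
        labels, _ = predict(self.model, images)
        return labels
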