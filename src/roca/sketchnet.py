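"""The sketch classifier: a small fire-module convolutional network.

The network follows the squeeze-and-expand design: a stem convolution, a
stack of fire modules (1x1 squeeze feeding parallel 1x1 and 3x3 expand
convolutions concatenated along channels) with occasional spatial
downsampling, a 1x1 convolution to one channel per class, global average
pooling, and softmax.  The default class inventory is task x {correct,
incorrect} — six classes — and multiclass predictions are *condensed* to a
binary correct/incorrect judgment per drawing for scoring.

Training is seeded mini-batch Adam on cross-entropy, at desk scale, from
scratch on synthetic drawings.  A transfer-learning hook accepts an
externally supplied checkpoint (``TrainSpec.pretrained_source``); no weight
download is ever required.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from . import nn
from .drawing import PreprocessSpec, RasterImage, StrokeDrawing, drawing_to_input, TASKS
from .synth import SynthLabel

CHECKPOINT_VERSION = 1


class ConfigError(ValueError):
    """A network or training configuration violates its invariants."""


class DataError(ValueError):
    """A training dataset is unusable (unknown or missing classes)."""


class ShapeError(ValueError):
    """An input image does not match the configured input size."""


def default_class_names() -> tuple[str, ...]:
    return tuple(f"{task}_{v}" for task in TASKS for v in ("correct", "incorrect"))


def class_name_for(task: str, correct: bool) -> str:
    return f"{task}_{'correct' if correct else 'incorrect'}"


def class_is_correct(name: str) -> bool:
    """Condensation: total deterministic mapping class name -> correct/incorrect."""
    return name.endswith("_correct")


@dataclass(frozen=True)
class NetConfig:
    input_size: int = 96
    class_names: tuple[str, ...] = field(default_factory=default_class_names)
    stem_channels: int = 16
    fire_specs: tuple[tuple[int, int, int], ...] = ((8, 16, 16), (16, 32, 32), (16, 32, 32))
    pool_after: tuple[int, ...] = (0, 1)   # fire-module indices followed by 2x2 pooling
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_size < 16:
            raise ConfigError("input_size must be at least 16")
        if not self.class_names or len(set(self.class_names)) != len(self.class_names):
            raise ConfigError("class_names must be non-empty and unique")
        if not self.fire_specs:
            raise ConfigError("at least one fire module is required")
        for i, (sq, e1, e3) in enumerate(self.fire_specs):
            if sq >= e1 + e3:
                raise ConfigError(
                    f"fire module {i}: squeeze channels ({sq}) must be smaller than "
                    f"expand1 + expand3 ({e1}+{e3})")
        bad = [i for i in self.pool_after if not (0 <= i < len(self.fire_specs))]
        if bad:
            raise ConfigError(f"pool_after indices out of range: {bad}")


@dataclass(frozen=True)
class TrainSpec:
    epochs: int = 40
    batch_size: int = 32
    learning_rate: float = 2e-3
    validation_fraction: float = 0.2
    seed: int = 0
    pretrained_source: str | None = None

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ConfigError("epochs must be at least 1")
        if not (0.0 < self.validation_fraction < 1.0):
            raise ConfigError("validation_fraction must lie strictly between 0 and 1")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be at least 1")


@dataclass(frozen=True)
class ClassifierOutput:
    probabilities: dict[str, float]
    predicted_class: str
    condensed_correct: bool


class SketchNet:
    """The assembled network.  Use :func:`build_model` to construct one."""

    def __init__(self, config: NetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        layers: list = [nn.Conv2d(1, config.stem_channels, 3, stride=2, pad=1, rng=rng),
                        nn.ReLU(), nn.MaxPool2x2()]
        channels = config.stem_channels
        for i, (sq, e1, e3) in enumerate(config.fire_specs):
            layers.append(nn.Fire(channels, sq, e1, e3, rng))
            channels = e1 + e3
            if i in config.pool_after:
                layers.append(nn.MaxPool2x2())
        layers.append(nn.Conv2d(channels, len(config.class_names), 1, rng=rng))
        layers.append(nn.GlobalAvgPool())
        self.layers = layers

    def params(self) -> list[nn.Param]:
        return [p for layer in self.layers for p in layer.params()]

    def logits(self, x: np.ndarray) -> np.ndarray:
        s = self.config.input_size
        if x.ndim != 4 or x.shape[1:] != (1, s, s):
            raise ShapeError(f"expected (n, 1, {s}, {s}) input, got {x.shape}")
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return nn.softmax(self.logits(x))

    # -- checkpointing ------------------------------------------------------

    def state_arrays(self) -> list[np.ndarray]:
        return [p.value for p in self.params()]

    def save(self, path: Union[str, Path], extra: dict | None = None) -> None:
        meta = {"version": CHECKPOINT_VERSION,
                "config": {"input_size": self.config.input_size,
                           "class_names": list(self.config.class_names),
                           "stem_channels": self.config.stem_channels,
                           "fire_specs": [list(f) for f in self.config.fire_specs],
                           "pool_after": list(self.config.pool_after),
                           "seed": self.config.seed},
                "extra": extra or {}}
        arrays = {f"param_{i}": a for i, a in enumerate(self.state_arrays())}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "SketchNet":
        return cls.load_with_meta(path)[0]

    @classmethod
    def load_with_meta(cls, path: Union[str, Path]) -> tuple["SketchNet", dict]:
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            if meta["version"] != CHECKPOINT_VERSION:
                raise ConfigError(f"unsupported checkpoint version {meta['version']}")
            cfg = meta["config"]
            config = NetConfig(input_size=cfg["input_size"],
                               class_names=tuple(cfg["class_names"]),
                               stem_channels=cfg["stem_channels"],
                               fire_specs=tuple(tuple(f) for f in cfg["fire_specs"]),
                               pool_after=tuple(cfg["pool_after"]),
                               seed=cfg["seed"])
            model = cls(config)
            for i, p in enumerate(model.params()):
                arr = data[f"param_{i}"]
                if arr.shape != p.value.shape:
                    raise ConfigError("checkpoint parameter shapes do not match config")
                p.value[...] = arr
        return model, meta


def build_model(config: NetConfig) -> SketchNet:
    """Construct an untrained network with seeded parameter initialization."""
    return SketchNet(config)


# ---------------------------------------------------------------------------
# dataset plumbing
# ---------------------------------------------------------------------------

def raster_to_input(image: RasterImage, input_size: int) -> np.ndarray:
    if image.height != input_size or image.width != input_size:
        raise ShapeError(f"expected a {input_size}x{input_size} raster, "
                         f"got {image.height}x{image.width}")
    return image.pixels[None, :, :].astype(np.float64)


def drawings_to_arrays(pairs: Sequence[tuple[StrokeDrawing, SynthLabel]],
                       spec: PreprocessSpec = PreprocessSpec()
                       ) -> tuple[np.ndarray, list[str]]:
    """Rasterize + preprocess labeled drawings into (X, class-name) arrays."""
    xs, names = [], []
    for drawing, label in pairs:
        img = drawing_to_input(drawing, spec)
        xs.append(img.pixels[None, :, :])
        names.append(class_name_for(label.task, label.correct))
    return np.stack(xs), names


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train(model: SketchNet, x: np.ndarray, class_labels: Sequence[str],
          spec: TrainSpec = TrainSpec(),
          preprocess: PreprocessSpec | None = None) -> tuple["TrainedClassifier", dict]:
    """Seeded mini-batch cross-entropy training with a held-out validation split.

    Returns the trained classifier and a report with per-epoch training and
    validation accuracy.  Identical (model seed, spec, data) reproduce the
    report exactly; numpy reductions here are deterministic, so the report's
    ``nondeterminism_flags`` list stays empty on supported platforms.
    """
    names = model.config.class_names
    index = {c: i for i, c in enumerate(names)}
    unknown = sorted(set(class_labels) - set(names))
    if unknown:
        raise DataError(f"labels not in the configured class set: {unknown}")
    y = np.array([index[c] for c in class_labels])
    if x.shape[0] != len(y) or x.shape[0] < 2:
        raise DataError("need at least two labeled images with matching x/y lengths")

    if spec.pretrained_source is not None:
        pretrained = SketchNet.load(spec.pretrained_source)
        if pretrained.config.class_names != names:
            raise ConfigError("pretrained checkpoint has a different class inventory")
        for p, q in zip(model.params(), pretrained.params()):
            p.value[...] = q.value

    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(y))
    n_val = max(int(round(len(y) * spec.validation_fraction)), 1)
    val_idx, train_idx = order[:n_val], order[n_val:]
    missing = sorted(set(names) - {names[i] for i in y[train_idx]})
    if missing:
        raise DataError(f"classes absent from the training split: {missing}")

    xt, yt = x[train_idx], y[train_idx]
    xv, yv = x[val_idx], y[val_idx]
    opt = nn.Adam(model.params(), lr=spec.learning_rate)

    def accuracy(xs: np.ndarray, ys: np.ndarray) -> float:
        preds = []
        for i in range(0, len(ys), 128):
            preds.append(model.logits(xs[i:i + 128]).argmax(axis=1))
        return float((np.concatenate(preds) == ys).mean())

    report: dict = {"epochs": [], "train_acc": [], "val_acc": [], "loss": [],
                    "n_train": len(yt), "n_val": len(yv),
                    "nondeterminism_flags": []}
    for epoch in range(spec.epochs):
        perm = rng.permutation(len(yt))
        losses = []
        for i in range(0, len(yt), spec.batch_size):
            batch = perm[i:i + spec.batch_size]
            opt.zero_grad()
            logits = model.logits(xt[batch])
            loss, grad = nn.cross_entropy_grad(logits, yt[batch])
            model.backward(grad)
            opt.step()
            losses.append(loss)
        report["epochs"].append(epoch)
        report["loss"].append(float(np.mean(losses)))
        report["train_acc"].append(accuracy(xt, yt))
        report["val_acc"].append(accuracy(xv, yv))
    report["final_val_acc"] = report["val_acc"][-1]
    return TrainedClassifier(model, preprocess), report


class TrainedClassifier:
    """A trained network plus the preprocessing contract for single drawings."""

    def __init__(self, model: SketchNet,
                 preprocess: PreprocessSpec | None = None):
        self.model = model
        self.preprocess = preprocess or PreprocessSpec(out_size=model.config.input_size)
        if self.preprocess.out_size != model.config.input_size:
            raise ConfigError("preprocess out_size must equal the network input size")

    def classify_raster(self, image: RasterImage) -> ClassifierOutput:
        x = raster_to_input(image, self.model.config.input_size)[None, ...]
        probs = self.model.predict_proba(x)[0]
        names = self.model.config.class_names
        pred = names[int(probs.argmax())]
        return ClassifierOutput(probabilities={c: float(p) for c, p in zip(names, probs)},
                                predicted_class=pred,
                                condensed_correct=class_is_correct(pred))

    def classify_drawing(self, drawing: StrokeDrawing) -> ClassifierOutput:
        return self.classify_raster(drawing_to_input(drawing, self.preprocess))

    def save(self, path: Union[str, Path]) -> None:
        self.model.save(path, extra={"preprocess": {
            "out_size": self.preprocess.out_size,
            "stroke_thickness": self.preprocess.stroke_thickness,
            "polarity": self.preprocess.polarity,
            "margin_fraction": self.preprocess.margin_fraction}})

    @classmethod
    def load(cls, path: Union[str, Path]) -> "TrainedClassifier":
        model, meta = SketchNet.load_with_meta(path)
        pp = meta.get("extra", {}).get("preprocess")
        return cls(model, PreprocessSpec(**pp) if pp else None)


def evaluate_classifier(classifier: TrainedClassifier,
                        pairs: Sequence[tuple[StrokeDrawing, SynthLabel]]) -> dict:
    """Per-task condensed confusion matrices and screening metrics.

    Positive = *incorrect drawing* (the classifier's job is to flag errors),
    so TP counts incorrect drawings recognized as incorrect.  Also reports
    the overall condensed accuracy across all drawings.
    """
    from .screen_eval import confusion_from_predictions, metrics_from_confusion

    by_task: dict[str, tuple[list[str], list[str]]] = {t: ([], []) for t in TASKS}
    hits = 0
    for drawing, label in pairs:
        out = classifier.classify_drawing(drawing)
        pred, true = by_task[label.task]
        pred.append("negative" if out.condensed_correct else "positive")
        true.append("negative" if label.correct else "positive")
        hits += out.condensed_correct == label.correct
    result: dict = {"overall_condensed_accuracy": hits / len(pairs), "per_task": {}}
    for task, (pred, true) in by_task.items():
        if not true:
            continue
        cm = confusion_from_predictions(pred, true)
        result["per_task"][task] = {"confusion": cm, "metrics": metrics_from_confusion(cm)}
    return result
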