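"""Barcode classification of capture events from raw fractional-current signal.

The classifier ladder mirrors the progression from summary statistics to
learned features:

* ``logreg_mean`` — logistic regression on the event's mean fractional
  current alone;
* ``random_forest_5feat`` — random forest on the five summary features
  (mean, median, standard deviation, maximum, minimum);
* ``cnn4`` — a 4-layer CNN (conv + ReLU + max-pool per layer, then a fully
  connected layer with log-sigmoid activation and a per-class output layer)
  applied to the first two-second window (20,000 samples at 10 kHz) of the
  event, reshaped row-major into a 2D array;
* ``resnet18_style`` — a residual CNN in the ResNet mold (identity skip
  blocks between downsampling stages), depth configurable and kept shallow
  by default for CPU training.

All estimators follow scikit-learn conventions (``fit`` / ``predict`` /
``predict_proba``, ``get_params``, trailing-underscore fitted attributes) and
take the raw window matrix ``(n_events, n_samples)``; feature computation is
internal to the feature-based families.  Prediction confidence is the
softmax-normalized score of the argmax class; predictions below a preset
confidence threshold can be filtered out.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from . import nn
from .extract import CaptureEvent

__all__ = [
    "EventWindow",
    "ClassifierSpec",
    "BarcodePrediction",
    "EvalReport",
    "make_window",
    "windows_matrix",
    "featurize_5",
    "MeanLogRegClassifier",
    "FiveFeatureForestClassifier",
    "Cnn4Classifier",
    "ResNetStyleClassifier",
    "make_classifier",
    "train",
    "predict",
    "evaluate",
    "save_model",
    "load_model",
]

WINDOW_SAMPLES = 20_000  # first two seconds at 10 kHz
DEFAULT_SHAPE_2D = (100, 200)  # row-major reshape of the window

FAMILIES = ("logreg_mean", "random_forest_5feat", "cnn4", "resnet18_style")


@dataclass(frozen=True)
class EventWindow:
    """The fixed-length signal window fed to the classifiers."""

    values: np.ndarray  # exactly WINDOW_SAMPLES fractional-current samples
    shape_2d: tuple[int, int] = DEFAULT_SHAPE_2D

    def __post_init__(self) -> None:
        if len(self.values) != self.shape_2d[0] * self.shape_2d[1]:
            raise ValueError(
                f"window has {len(self.values)} values; expected "
                f"{self.shape_2d[0] * self.shape_2d[1]} for shape {self.shape_2d}"
            )

    def as_2d(self) -> np.ndarray:
        return np.asarray(self.values).reshape(self.shape_2d)  # row-major

    @classmethod
    def from_2d(cls, arr: np.ndarray) -> "EventWindow":
        return cls(np.asarray(arr).reshape(-1), tuple(arr.shape))


def make_window(
    event: CaptureEvent,
    n_samples: int = WINDOW_SAMPLES,
    shape_2d: tuple[int, int] = DEFAULT_SHAPE_2D,
) -> EventWindow:
    """Extract the first ``n_samples`` fractional samples of an event.

    Events shorter than the window indicate a pipeline-ordering bug (the 2 s
    length filter must run first) and raise.
    """
    if shape_2d[0] * shape_2d[1] != n_samples:
        raise ValueError("shape_2d must multiply out to n_samples")
    if len(event.fractional_samples) < n_samples:
        raise ValueError(
            f"event of {len(event.fractional_samples)} samples is shorter than the "
            f"{n_samples}-sample window; apply the length filter first"
        )
    return EventWindow(np.asarray(event.fractional_samples[:n_samples], dtype=np.float32), shape_2d)


def windows_matrix(events: Sequence[CaptureEvent], n_samples: int = WINDOW_SAMPLES) -> np.ndarray:
    """Stack event windows into an (n_events, n_samples) float32 matrix."""
    out = np.empty((len(events), n_samples), dtype=np.float32)
    for i, ev in enumerate(events):
        out[i] = make_window(ev, n_samples=n_samples).values
    return out


def featurize_5(event_or_samples) -> np.ndarray:
    """Five-feature vector in fixed order (mean, median, sd, max, min).

    Accepts a :class:`CaptureEvent` (uses its stored features — single source
    of truth) or a raw 1D sample array.
    """
    if isinstance(event_or_samples, CaptureEvent):
        f = event_or_samples.features
        return np.array([f["mean"], f["median"], f["sd"], f["maximum"], f["minimum"]])
    x = np.asarray(event_or_samples, dtype=float)
    sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    return np.array([np.mean(x), np.median(x), sd, np.max(x), np.min(x)])


def _features_from_windows(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    return np.column_stack(
        [
            X.mean(axis=1),
            np.median(X, axis=1),
            X.std(axis=1, ddof=1),
            X.max(axis=1),
            X.min(axis=1),
        ]
    )


# ---------------------------------------------------------------------------
# Estimators


def _check_min_class_counts(y: np.ndarray, minimum: int = 2) -> None:
    classes, counts = np.unique(y, return_counts=True)
    bad = classes[counts < minimum]
    if len(bad):
        raise ValueError(f"classes {list(bad)} have fewer than {minimum} examples")


class MeanLogRegClassifier(BaseEstimator, ClassifierMixin):
    """Logistic regression on the event mean fractional current."""

    def __init__(self, seed: int = 0, max_iter: int = 2000, C: float = 1e4):
        self.seed = seed
        self.max_iter = max_iter
        self.C = C

    def fit(self, X, y):
        X = np.asarray(X)
        _check_min_class_counts(np.asarray(y))
        means = X.mean(axis=1, dtype=np.float64).reshape(-1, 1)
        # standardize the single feature: multi-way interval boundaries need
        # sharp logits, which weak regularization on a tiny scale prevents
        self._center = float(means.mean())
        self._scale = float(means.std()) or 1.0
        self._lr = LogisticRegression(
            max_iter=self.max_iter, C=self.C, random_state=self.seed
        )
        self._lr.fit((means - self._center) / self._scale, y)
        self.classes_ = self._lr.classes_
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "classes_")
        X = np.asarray(X)
        means = X.mean(axis=1, dtype=np.float64).reshape(-1, 1)
        return self._lr.predict_proba((means - self._center) / self._scale)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class FiveFeatureForestClassifier(BaseEstimator, ClassifierMixin):
    """Random forest on the five raw-signal summary features."""

    def __init__(self, n_estimators: int = 200, seed: int = 0):
        self.n_estimators = n_estimators
        self.seed = seed

    def fit(self, X, y):
        _check_min_class_counts(np.asarray(y))
        self._rf = RandomForestClassifier(
            n_estimators=self.n_estimators, random_state=self.seed, n_jobs=1
        )
        self._rf.fit(_features_from_windows(X), y)
        self.classes_ = self._rf.classes_
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "classes_")
        return self._rf.predict_proba(_features_from_windows(X))

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class _WindowNetClassifier(BaseEstimator, ClassifierMixin):
    """Shared plumbing of the window-based neural families."""

    shape_2d: tuple[int, int]
    input_pool: int
    epochs: int
    batch_size: int
    lr: float
    seed: int

    def _build(self, n_classes: int, rng: np.random.Generator) -> nn.Network:
        raise NotImplementedError

    def _to_4d(self, X: np.ndarray) -> np.ndarray:
        # fixed affine rescaling: fractional currents live in (0, 0.7); map
        # the usable band to roughly unit scale for well-conditioned training
        X = (np.asarray(X, dtype=np.float32) - np.float32(self.input_center)) / np.float32(
            self.input_scale
        )
        h, w = self.shape_2d
        return X.reshape(len(X), 1, h, w)

    def fit(self, X, y):
        y = np.asarray(y)
        _check_min_class_counts(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        rng = np.random.default_rng(self.seed)
        self.net_ = self._build(len(self.classes_), rng)
        self.history_ = self.net_.fit(
            self._to_4d(X),
            y_idx,
            epochs=self.epochs,
            batch_size=self.batch_size,
            lr=self.lr,
            seed=self.seed,
        )
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "net_")
        return self.net_.predict_proba(self._to_4d(X))

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class Cnn4Classifier(_WindowNetClassifier):
    """Four conv layers (ReLU + 2x2 max pool each), an FC layer with
    log-sigmoid activation, and a per-class output layer.

    The 2D window is average-pooled ``input_pool`` x before the first
    convolution: blockade structure lives at far lower bandwidth than the
    10 kHz sampling, and the downsampling makes CPU training tractable.
    """

    def __init__(
        self,
        shape_2d: tuple[int, int] = DEFAULT_SHAPE_2D,
        input_pool: int = 5,
        channels: tuple[int, int, int, int] = (8, 16, 32, 32),
        kernel: int = 3,
        hidden: int = 64,
        epochs: int = 250,
        batch_size: int = 128,
        lr: float = 3e-3,
        seed: int = 0,
        input_center: float = 0.4,
        input_scale: float = 0.15,
    ):
        self.shape_2d = tuple(shape_2d)
        self.input_pool = input_pool
        self.input_center = input_center
        self.input_scale = input_scale
        self.channels = tuple(channels)
        self.kernel = kernel
        self.hidden = hidden
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.seed = seed

    def _build(self, n_classes: int, rng: np.random.Generator) -> nn.Network:
        layers: list[nn.Layer] = []
        if self.input_pool > 1:
            layers.append(nn.AvgPool(self.input_pool))
        c_in = 1
        for c_out in self.channels:
            layers += [nn.Conv2D(c_in, c_out, self.kernel, rng), nn.ReLU(), nn.MaxPool2()]
            c_in = c_out
        conv = nn.Network(layers + [nn.Flatten()])
        flat = conv.logits(np.zeros((1, 1, *self.shape_2d), dtype=np.float32)).shape[1]
        layers += [
            nn.Flatten(),
            nn.Dense(flat, self.hidden, rng),
            nn.LogSigmoid(),
            nn.Dense(self.hidden, n_classes, rng),
        ]
        return nn.Network(layers)


class ResNetStyleClassifier(_WindowNetClassifier):
    """Residual CNN: stem conv, then stages of identity-skip blocks with
    channel-doubling downsampling transitions, then a dense head."""

    def __init__(
        self,
        shape_2d: tuple[int, int] = DEFAULT_SHAPE_2D,
        input_pool: int = 5,
        stage_channels: tuple[int, ...] = (8, 16, 32),
        blocks_per_stage: int = 1,
        hidden: int = 64,
        kernel: int = 3,
        epochs: int = 250,
        batch_size: int = 128,
        lr: float = 3e-3,
        seed: int = 0,
        input_center: float = 0.4,
        input_scale: float = 0.15,
    ):
        self.shape_2d = tuple(shape_2d)
        self.input_pool = input_pool
        self.input_center = input_center
        self.input_scale = input_scale
        self.stage_channels = tuple(stage_channels)
        self.blocks_per_stage = blocks_per_stage
        self.hidden = hidden
        self.kernel = kernel
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.seed = seed

    def _build(self, n_classes: int, rng: np.random.Generator) -> nn.Network:
        layers: list[nn.Layer] = []
        if self.input_pool > 1:
            layers.append(nn.AvgPool(self.input_pool))
        c_in = 1
        for c_out in self.stage_channels:
            layers += [nn.Conv2D(c_in, c_out, self.kernel, rng), nn.ReLU(), nn.MaxPool2()]
            layers += [
                nn.ResidualBlock(c_out, self.kernel, rng)
                for _ in range(self.blocks_per_stage)
            ]
            c_in = c_out
        conv = nn.Network(layers + [nn.Flatten()])
        flat = conv.logits(np.zeros((1, 1, *self.shape_2d), dtype=np.float32)).shape[1]
        layers += [
            nn.Flatten(),
            nn.Dense(flat, self.hidden, rng),
            nn.ReLU(),
            nn.Dense(self.hidden, n_classes, rng),
        ]
        return nn.Network(layers)


def make_classifier(family: str, seed: int = 0, epochs: int = 250, **kwargs):
    if family == "logreg_mean":
        return MeanLogRegClassifier(seed=seed, **kwargs)
    if family == "random_forest_5feat":
        return FiveFeatureForestClassifier(seed=seed, **kwargs)
    if family == "cnn4":
        return Cnn4Classifier(seed=seed, epochs=epochs, **kwargs)
    if family == "resnet18_style":
        return ResNetStyleClassifier(seed=seed, epochs=epochs, **kwargs)
    raise ValueError(f"unknown classifier family {family!r}; choose from {FAMILIES}")


# ---------------------------------------------------------------------------
# Training / prediction / evaluation contracts


@dataclass
class ClassifierSpec:
    family: str
    n_classes: int
    train_fraction: float = 0.8
    epochs: int = 250
    seed: int = 0
    confidence_threshold: float | None = None
    model_kwargs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.confidence_threshold is not None and not 0 < self.confidence_threshold < 1:
            raise ValueError("confidence_threshold must be in (0, 1)")


@dataclass
class BarcodePrediction:
    event_index: int
    predicted_label: str
    confidence: float
    passed_confidence_filter: bool


@dataclass
class EvalReport:
    labels: list
    accuracy: float
    confusion: np.ndarray  # rows = true class, cols = predicted
    precision: dict
    recall: dict
    threshold: float | None = None
    filtered_accuracy: float | None = None
    fraction_retained: float | None = None


@dataclass
class TrainedModel:
    model: BaseEstimator
    spec: ClassifierSpec
    history: list[float]
    report: EvalReport
    test_indices: np.ndarray


def _cap_at_smallest_class(
    X: np.ndarray, y: np.ndarray, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Subsample every class to the size of the smallest (class balance as
    dictated by the least-captured barcode)."""
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    cap = counts.min()
    keep = np.concatenate(
        [rng.choice(np.flatnonzero(y == c), size=cap, replace=False) for c in classes]
    )
    keep.sort()
    return X[keep], y[keep], keep


def train(spec: ClassifierSpec, windows: np.ndarray, labels: Sequence[str]) -> TrainedModel:
    """Fit a classifier per ``spec`` with a stratified train/test split.

    The sample is first capped at the smallest class, then split
    ``train_fraction`` / remainder stratified by class.  Deterministic given
    ``spec.seed``.
    """
    y = np.asarray(labels)
    X = np.asarray(windows)
    classes = np.unique(y)
    if len(classes) != spec.n_classes:
        raise ValueError(f"expected {spec.n_classes} classes, found {len(classes)}")
    _check_min_class_counts(y)
    X, y, kept = _cap_at_smallest_class(X, y, spec.seed)
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx,
        train_size=spec.train_fraction,
        stratify=y,
        random_state=spec.seed % (2**32),
        shuffle=True,
    )
    model = make_classifier(spec.family, seed=spec.seed, epochs=spec.epochs, **spec.model_kwargs)
    model.fit(X[train_idx], y[train_idx])
    history = list(getattr(model, "history_", []))
    report = evaluate(model, X[test_idx], y[test_idx], threshold=spec.confidence_threshold)
    return TrainedModel(model, spec, history, report, kept[test_idx])


def predict(
    model: BaseEstimator, windows: np.ndarray, threshold: float | None = None
) -> list[BarcodePrediction]:
    """Per-event barcode predictions with confidence and the preset-threshold
    filter flag (no threshold -> everything passes)."""
    proba = model.predict_proba(np.asarray(windows))
    arg = np.argmax(proba, axis=1)
    conf = proba[np.arange(len(arg)), arg]
    return [
        BarcodePrediction(
            event_index=i,
            predicted_label=str(model.classes_[a]),
            confidence=float(c),
            passed_confidence_filter=(threshold is None) or (c >= threshold),
        )
        for i, (a, c) in enumerate(zip(arg, conf))
    ]


def evaluate(
    model: BaseEstimator,
    windows: np.ndarray,
    labels: Sequence[str],
    threshold: float | None = None,
) -> EvalReport:
    """Accuracy, confusion matrix, per-class precision/recall on a test set,
    plus confidence-filtered accuracy and retained fraction if a threshold
    is given."""
    y = np.asarray(labels)
    if len(y) == 0:
        raise ValueError("empty test set")
    proba = model.predict_proba(np.asarray(windows))
    arg = np.argmax(proba, axis=1)
    pred = model.classes_[arg]
    conf = proba[np.arange(len(arg)), arg]
    cls = list(model.classes_)
    cm = _sk_confusion(y, pred, labels=cls)
    accuracy = float(np.trace(cm) / cm.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.diag(cm) / np.maximum(cm.sum(axis=0), 1)
        rec = np.diag(cm) / np.maximum(cm.sum(axis=1), 1)
    report = EvalReport(
        labels=cls,
        accuracy=accuracy,
        confusion=cm,
        precision={c: float(p) for c, p in zip(cls, prec)},
        recall={c: float(r) for c, r in zip(cls, rec)},
    )
    if threshold is not None:
        keep = conf >= threshold
        report.threshold = threshold
        report.fraction_retained = float(keep.mean())
        report.filtered_accuracy = (
            float(np.mean(pred[keep] == y[keep])) if keep.any() else float("nan")
        )
    return report


# ---------------------------------------------------------------------------
# Model persistence


def save_model(trained: TrainedModel, directory) -> None:
    """Serialize a trained model (weights + spec + training manifest)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spec = trained.spec
    manifest = {
        "family": spec.family,
        "n_classes": spec.n_classes,
        "train_fraction": spec.train_fraction,
        "epochs": spec.epochs,
        "seed": spec.seed,
        "confidence_threshold": spec.confidence_threshold,
        "model_kwargs": spec.model_kwargs,
        "classes": [str(c) for c in trained.model.classes_],
        "history": trained.history,
        "test_accuracy": trained.report.accuracy,
        "params": trained.model.get_params(),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    if isinstance(trained.model, _WindowNetClassifier):
        np.savez(directory / "weights.npz", **trained.model.net_.state_arrays())
        np.save(directory / "classes.npy", trained.model.classes_)
    else:
        joblib.dump(trained.model, directory / "model.joblib")


def load_model(directory) -> BaseEstimator:
    """Reload a serialized model; predictions are bit-identical to the
    original on the same machine."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    if (directory / "model.joblib").exists():
        return joblib.load(directory / "model.joblib")
    model = make_classifier(
        manifest["family"],
        seed=manifest["seed"],
        epochs=manifest["epochs"],
        **{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in manifest["model_kwargs"].items()
        },
    )
    classes = np.load(directory / "classes.npy", allow_pickle=True)
    rng = np.random.default_rng(manifest["seed"])
    model.classes_ = classes
    model.net_ = model._build(len(classes), rng)
    with np.load(directory / "weights.npz") as state:
        model.net_.load_state_arrays(dict(state))
    return model
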