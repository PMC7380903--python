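"""Window tensors, channel normalization and the CNN recognizer.

The classifier is a small convolutional network over 3-second windows
(30 time steps x C sensor channels): two convolution layers with 8 and
16 feature maps, a 32-node fully connected layer, ReLU activations and
a softmax head over the five activity classes.  Convolution runs along
the time axis with the sensor channels as input depth.

:class:`WindowCNNClassifier` is a scikit-learn estimator (``fit`` /
``predict`` / ``predict_proba`` on ``(n, 30, C)`` arrays) so it
composes with sklearn model selection; :func:`train_recognizer` /
:func:`predict` wrap it for :class:`~rehabhar.sessions.Window` objects
and sensor-subset bookkeeping.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from ._cnn import SmallCNN
from .classes import ExerciseClass, SensorSubset
from .sessions import Window


def build_window_tensor(window: Window, subset: SensorSubset) -> np.ndarray:
    """Select and order the subset's channels from a window.

    Returns the (30, C) time x channel matrix, values untouched.
    """
    values = window.values
    if values.shape[1] < max(subset.indices) + 1:
        raise ValueError(
            f"window has {values.shape[1]} channels; subset {subset.name} "
            f"needs channel index {max(subset.indices)}"
        )
    return values[:, list(subset.indices)]


def windows_to_tensor(
    windows: Sequence[Window], subset: SensorSubset
) -> tuple[np.ndarray, np.ndarray]:
    """Stack windows into (n, 30, C) X and integer label vector y."""
    if not windows:
        raise ValueError("need at least one window")
    X = np.stack([build_window_tensor(w, subset) for w in windows])
    y = np.array([int(w.label) for w in windows], dtype=int)
    return X, y


class ChannelNormalizer(TransformerMixin, BaseEstimator):
    """Per-channel z-scoring of window tensors.

    Statistics are computed over all samples of all training windows,
    one (mean, SD) pair per channel; SDs are floored at ``eps`` so a
    constant channel maps to zeros rather than NaN.
    """

    def __init__(self, eps: float = 1e-8):
        self.eps = eps

    def fit(self, X: np.ndarray, y=None) -> "ChannelNormalizer":
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[0] < 1:
            raise ValueError("X must be a non-empty (n, time, channels) array")
        self.mean_ = X.mean(axis=(0, 1))
        self.scale_ = np.maximum(X.std(axis=(0, 1)), self.eps)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "mean_")
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_


def fit_normalizer(windows: Sequence[Window], subset: SensorSubset) -> ChannelNormalizer:
    X, _ = windows_to_tensor(windows, subset)
    return ChannelNormalizer().fit(X)


def apply_normalizer(normalizer: ChannelNormalizer, tensor: np.ndarray) -> np.ndarray:
    return normalizer.transform(tensor)


@dataclasses.dataclass
class CNNConfig:
    """Architecture and training hyperparameters.

    Feature-map and node counts default to the recognizer's fixed
    architecture (8/16 feature maps, 32 dense nodes, 5 outputs);
    kernel length 5 and pool length 2 give each unit a receptive field
    of roughly one second at 10 Hz.
    """

    conv1_maps: int = 8
    conv2_maps: int = 16
    dense_units: int = 32
    n_outputs: int = len(ExerciseClass)
    kernel_size: int = 5
    pool_size: int = 2
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("conv1_maps", "conv2_maps", "dense_units", "n_outputs",
                     "kernel_size", "pool_size", "epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


class WindowCNNClassifier(ClassifierMixin, BaseEstimator):
    """CNN classifier over IMU window tensors.

    Parameters mirror :class:`CNNConfig`.  ``fit`` expects ``X`` of
    shape (n, time, channels) and integer labels ``y``; inputs are
    z-scored per channel with training-set statistics before the
    network sees them.  Training is plain mini-batch Adam on
    cross-entropy and is deterministic for a fixed ``random_state``.

    Attributes (after ``fit``)
    --------------------------
    classes_ : sorted unique training labels
    channel_mean_, channel_scale_ : normalization statistics
    net_ : the fitted network
    loss_history_ : mean cross-entropy per epoch
    """

    def __init__(
        self,
        conv1_maps: int = 8,
        conv2_maps: int = 16,
        dense_units: int = 32,
        kernel_size: int = 5,
        pool_size: int = 2,
        epochs: int = 50,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        random_state: int | None = None,
    ):
        self.conv1_maps = conv1_maps
        self.conv2_maps = conv2_maps
        self.dense_units = dense_units
        self.kernel_size = kernel_size
        self.pool_size = pool_size
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state

    def _validate_X(self, X: np.ndarray, fitting: bool) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError(f"X must be (n, time, channels), got shape {X.shape}")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        if not fitting:
            check_is_fitted(self, "net_")
            if X.shape[1:] != self.input_shape_:
                raise ValueError(
                    f"X windows have shape {X.shape[1:]}, model was fitted on "
                    f"{self.input_shape_} (sensor subset mismatch?)"
                )
        return X

    def fit(self, X: np.ndarray, y: np.ndarray) -> "WindowCNNClassifier":
        X = self._validate_X(X, fitting=True)
        y = np.asarray(y, dtype=int)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("training set must contain at least 2 classes")
        self.input_shape_ = X.shape[1:]

        norm = ChannelNormalizer().fit(X)
        self.channel_mean_ = norm.mean_
        self.channel_scale_ = norm.scale_
        Xn = norm.transform(X)
        y_idx = np.searchsorted(self.classes_, y)

        rng = np.random.default_rng(self.random_state)
        self.net_ = SmallCNN(
            input_len=X.shape[1],
            in_channels=X.shape[2],
            n_classes=int(self.classes_.size),
            conv1_maps=self.conv1_maps,
            conv2_maps=self.conv2_maps,
            dense_units=self.dense_units,
            kernel_size=self.kernel_size,
            pool_size=self.pool_size,
            rng=rng,
        )
        self.loss_history_ = self.net_.fit(
            Xn, y_idx, epochs=self.epochs, batch_size=self.batch_size,
            lr=self.learning_rate, rng=rng,
        )
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = self._validate_X(X, fitting=False)
        Xn = (X - self.channel_mean_) / self.channel_scale_
        return self.net_.predict_proba(Xn)

    def predict(self, X: np.ndarray) -> np.ndarray:
        # argmax ties resolve to the lowest class index
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y, dtype=int)))


@dataclasses.dataclass
class TrainedRecognizer:
    """A fitted recognizer plus the metadata needed to apply it.

    ``classes`` is the list the model can emit; ``predict_proba``
    embeds the network's outputs into a full five-class vector (zeros
    for classes absent from training).
    """

    estimator: WindowCNNClassifier
    subset: SensorSubset
    classes: list[ExerciseClass]
    config: CNNConfig
    fingerprint: str

    @property
    def normalization(self) -> tuple[np.ndarray, np.ndarray]:
        return self.estimator.channel_mean_, self.estimator.channel_scale_


def _fingerprint(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()[:16]


def train_recognizer(
    windows: Sequence[Window], subset: SensorSubset, config: CNNConfig | None = None
) -> TrainedRecognizer:
    """Train the CNN on labeled windows for one sensor subset."""
    config = config or CNNConfig()
    X, y = windows_to_tensor(windows, subset)
    est = WindowCNNClassifier(
        conv1_maps=config.conv1_maps,
        conv2_maps=config.conv2_maps,
        dense_units=config.dense_units,
        kernel_size=config.kernel_size,
        pool_size=config.pool_size,
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        random_state=config.seed,
    ).fit(X, y)
    return TrainedRecognizer(
        estimator=est,
        subset=subset,
        classes=[ExerciseClass(c) for c in est.classes_],
        config=config,
        fingerprint=_fingerprint(X, y),
    )


def predict(
    model: TrainedRecognizer, window: Window
) -> tuple[np.ndarray, ExerciseClass]:
    """Class probabilities (full 5-vector) and argmax class for one window."""
    tensor = build_window_tensor(window, model.subset)[None, :, :]
    probs_model = model.estimator.predict_proba(tensor)[0]
    full = np.zeros(len(ExerciseClass))
    for p, cls in zip(probs_model, model.classes):
        full[int(cls)] = p
    return full, ExerciseClass(int(np.argmax(full)))


def predict_windows(
    model: TrainedRecognizer, windows: Sequence[Window]
) -> list[ExerciseClass]:
    """Vectorized argmax prediction for many windows."""
    X = np.stack([build_window_tensor(w, model.subset) for w in windows])
    labels = model.estimator.predict(X)
    return [ExerciseClass(int(v)) for v in labels]


def save_recognizer(model: TrainedRecognizer, directory: str | Path) -> Path:
    """Persist a model as a directory: weights.npz + metadata.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "weights.npz", **model.estimator.net_.get_weights())
    meta = {
        "subset": model.subset.name,
        "classes": [c.name for c in model.classes],
        "channel_mean": model.estimator.channel_mean_.tolist(),
        "channel_scale": model.estimator.channel_scale_.tolist(),
        "input_shape": list(model.estimator.input_shape_),
        "config": dataclasses.asdict(model.config),
        "fingerprint": model.fingerprint,
    }
    (directory / "metadata.json").write_text(json.dumps(meta, indent=2))
    return directory


def load_recognizer(directory: str | Path) -> TrainedRecognizer:
    directory = Path(directory)
    meta = json.loads((directory / "metadata.json").read_text())
    config = CNNConfig(**meta["config"])
    subset = SensorSubset[meta["subset"]]
    classes = [ExerciseClass[n] for n in meta["classes"]]
    est = WindowCNNClassifier(
        conv1_maps=config.conv1_maps,
        conv2_maps=config.conv2_maps,
        dense_units=config.dense_units,
        kernel_size=config.kernel_size,
        pool_size=config.pool_size,
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        random_state=config.seed,
    )
    input_shape = tuple(meta["input_shape"])
    est.classes_ = np.array([int(c) for c in classes])
    est.input_shape_ = input_shape
    est.channel_mean_ = np.array(meta["channel_mean"])
    est.channel_scale_ = np.array(meta["channel_scale"])
    est.net_ = SmallCNN(
        input_len=input_shape[0],
        in_channels=input_shape[1],
        n_classes=len(classes),
        conv1_maps=config.conv1_maps,
        conv2_maps=config.conv2_maps,
        dense_units=config.dense_units,
        kernel_size=config.kernel_size,
        pool_size=config.pool_size,
        rng=np.random.default_rng(0),
    )
    with np.load(directory / "weights.npz") as npz:
        est.net_.set_weights({k: npz[k] for k in npz.files})
    est.loss_history_ = []
    return TrainedRecognizer(
        estimator=est, subset=subset, classes=classes, config=config,
        fingerprint=meta["fingerprint"],
    )
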