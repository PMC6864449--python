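"""The recurrent classifier and the classical baselines.

The recurrent architecture is::

    Input (782 x 1) -> LSTM(64, sequences) -> Dropout
                    -> LSTM(32, final state) -> Dropout
                    -> Dense(3) -> Softmax

trained with categorical cross-entropy.  Baselines share a common
fit/predict interface: decision tree, random forest and linear SVC
(scikit-learn) plus 6- and 16-layer dense feed-forward networks built
from the same numpy layer substrate as the LSTM model.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .nn import LSTM, Dense, Dropout, SequentialNet, cross_entropy, softmax

__all__ = [
    "RNNSpec",
    "TrainConfig",
    "RNNClassifier",
    "MLPBaseline",
    "SklearnBaseline",
    "build_rnn",
    "build_baseline",
    "train_model",
    "predict",
    "softmax",
    "BASELINE_KINDS",
]

BASELINE_KINDS = ("dt", "rf", "lsvc", "mlp6", "mlp16")


@dataclass(frozen=True)
class RNNSpec:
    """Architecture description of the recurrent classifier."""

    input_len: int = 782
    lstm1_units: int = 64
    lstm2_units: int = 32
    dropout_rate: float = 0.35
    n_classes: int = 3

    def __post_init__(self):
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters (categorical cross-entropy loss throughout).

    ``lr_decay`` multiplies the learning rate once per epoch.  When
    ``val_fraction`` > 0 and no explicit validation set is supplied, that
    fraction of the training data is carved off (stratified) to monitor
    generalisation, and with ``restore_best`` the epoch with the best
    validation accuracy is the one whose weights are kept — long
    recurrent runs can destabilise late.
    """

    optimizer: str = "adam"
    learning_rate: float = 1e-3
    lr_decay: float = 1.0
    epochs: int = 50
    batch_size: int = 32
    split_ratio: float = 0.70
    clip_norm: float = 5.0
    val_fraction: float = 0.15
    restore_best: bool = True
    #: train-time cyclic time-shift of each sequence batch (sequence
    #: models only).  Framing tiles recordings cyclically, so a circular
    #: shift is the same recording started at a different instant —
    #: injecting the time-translation invariance the labels obey.
    cyclic_shift_augment: bool = True
    #: tail fraction of epochs whose weights are averaged (stochastic
    #: weight averaging); kept only if the average validates at least as
    #: well as the best single epoch.  0 disables.
    swa_fraction: float = 0.0
    seed: int = 0

    @property
    def swa_start(self) -> int | None:
        if self.swa_fraction <= 0.0:
            return None
        return max(0, int(np.ceil(self.epochs * (1.0 - self.swa_fraction))))

    def __post_init__(self):
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError("split_ratio must be in (0, 1)")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def _cyclic_shift(batch: np.ndarray, rng) -> np.ndarray:
    """Roll each (T, features) sequence by an independent random offset."""
    out = np.empty_like(batch)
    T = batch.shape[1]
    for k in range(len(batch)):
        out[k] = np.roll(batch[k], int(rng.integers(T)), axis=0)
    return out


def _carve_validation(X, y, cfg: TrainConfig):
    """Split (train, validation) per cfg; no-op when validation is off."""
    if cfg.val_fraction <= 0.0:
        return X, y, None
    from .evaluation import split_train_test

    tr, va = split_train_test(y, 1.0 - cfg.val_fraction, seed=cfg.seed)
    return X[tr], y[tr], (X[va], y[va])


class RNNClassifier:
    """LSTM-based sequence classifier over length-``input_len`` feature
    vectors (fed to the recurrence as one scalar per timestep)."""

    kind = "rnn"

    def __init__(self, spec: RNNSpec, *, init_seed: int = 0):
        self.spec = spec
        # set at fit time: inputs are divided by the training set's global
        # RMS so typical amplitudes reach the gates' responsive range (a
        # single scalar, equivalent to rescaling the input weights)
        self.input_scale: float = 1.0
        rng = np.random.default_rng(init_seed)
        self.net = SequentialNet(
            [
                LSTM(1, spec.lstm1_units, return_sequences=True,
                     input_init="fan_in", rng=rng),
                Dropout(spec.dropout_rate),
                LSTM(spec.lstm1_units, spec.lstm2_units, rng=rng),
                Dropout(spec.dropout_rate),
                Dense(spec.lstm2_units, spec.n_classes, rng=rng),
            ]
        )

    @property
    def history(self):
        return self.net.history

    def _to_sequences(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != self.spec.input_len:
            raise ValueError(
                f"expected features of shape (n, {self.spec.input_len}), "
                f"got {X.shape}"
            )
        return X[:, :, None].astype(np.float32)

    def forward_shapes(self, x_row: np.ndarray) -> list[tuple[int, ...]]:
        """Per-layer output shapes for a single feature vector (the
        architecture audit)."""
        x = self._to_sequences(x_row[None, :])
        shapes = []
        for layer in self.net.layers:
            x = layer.forward(x)
            shapes.append(x.shape[1:])
        return shapes

    def fit(self, X, y, cfg: TrainConfig = TrainConfig(), *, validation=None,
            verbose: bool = False):
        X = np.asarray(X)
        y = np.asarray(y, dtype=np.int64)
        if validation is None:
            X, y, validation = _carve_validation(X, y, cfg)
        rms = float(np.sqrt(np.mean(np.square(X))))
        self.input_scale = rms if rms > 0 else 1.0
        Xs = self._to_sequences(X / self.input_scale)
        if validation is not None:
            validation = (
                self._to_sequences(np.asarray(validation[0]) / self.input_scale),
                validation[1],
            )
        augment = _cyclic_shift if cfg.cyclic_shift_augment else None
        self.net.fit(
            Xs,
            y,
            epochs=cfg.epochs,
            batch_size=cfg.batch_size,
            optimizer=cfg.optimizer,
            learning_rate=cfg.learning_rate,
            lr_decay=cfg.lr_decay,
            clip_norm=cfg.clip_norm,
            seed=cfg.seed,
            validation=validation,
            restore_best=cfg.restore_best,
            swa_start=cfg.swa_start,
            augment=augment,
            verbose=verbose,
        )
        return self

    def predict_proba(self, X) -> np.ndarray:
        return self.net.predict_proba(
            self._to_sequences(np.asarray(X) / self.input_scale)
        )

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)

    def evaluate_loss(self, X, y) -> float:
        return cross_entropy(self.predict_proba(X), np.asarray(y, dtype=np.int64))

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> Path:
        """Save weights (npz) plus a JSON sidecar with the architecture."""
        path = Path(path)
        arrays = {}
        for i, layer in enumerate(self.net.layers):
            for k, v in layer.params.items():
                arrays[f"layer{i}_{k}"] = v
        np.savez(path.with_suffix(".npz"), **arrays)
        sidecar = {
            "kind": self.kind,
            "spec": asdict(self.spec),
            "input_scale": self.input_scale,
            "label_encoding": ["normal", "murmur", "extrasystole"],
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
        return path.with_suffix(".npz")

    @classmethod
    def load(cls, path: str | Path) -> "RNNClassifier":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        model = cls(RNNSpec(**sidecar["spec"]))
        model.input_scale = float(sidecar.get("input_scale", 1.0))
        with np.load(path.with_suffix(".npz")) as data:
            for i, layer in enumerate(model.net.layers):
                for k in layer.params:
                    layer.params[k] = data[f"layer{i}_{k}"]
        return model


class MLPBaseline:
    """Dense feed-forward stack of ``n_layers`` trainable layers.

    Layer counting follows the trainable (Dense) layers: ``n_layers - 1``
    hidden Dense(64)+ReLU layers, each followed by dropout, then a final
    3-unit Dense feeding the softmax.
    """

    def __init__(self, n_layers: int, *, input_len: int = 782, n_classes: int = 3,
                 hidden_units: int = 64, dropout_rate: float = 0.35,
                 init_seed: int = 0):
        if n_layers < 2:
            raise ValueError("an MLP needs at least 2 trainable layers")
        self.kind = f"mlp{n_layers}"
        self.n_layers = n_layers
        self.input_scale: float = 1.0  # training-set RMS, set at fit time
        rng = np.random.default_rng(init_seed)
        layers = []
        d = input_len
        for _ in range(n_layers - 1):
            layers.append(Dense(d, hidden_units, relu=True, rng=rng))
            layers.append(Dropout(dropout_rate))
            d = hidden_units
        layers.append(Dense(d, n_classes, rng=rng))
        self.net = SequentialNet(layers)

    @property
    def trainable_layers(self) -> int:
        return sum(1 for l in self.net.layers if l.params)

    @property
    def history(self):
        return self.net.history

    def fit(self, X, y, cfg: TrainConfig = TrainConfig(), *, validation=None,
            verbose: bool = False):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.int64)
        if validation is None:
            X, y, validation = _carve_validation(X, y, cfg)
        rms = float(np.sqrt(np.mean(np.square(X))))
        self.input_scale = rms if rms > 0 else 1.0
        if validation is not None:
            validation = (
                np.asarray(validation[0], dtype=np.float32) / self.input_scale,
                validation[1],
            )
        self.net.fit(
            X / self.input_scale,
            y,
            epochs=cfg.epochs,
            batch_size=cfg.batch_size,
            optimizer=cfg.optimizer,
            learning_rate=cfg.learning_rate,
            lr_decay=cfg.lr_decay,
            clip_norm=cfg.clip_norm,
            seed=cfg.seed,
            validation=validation,
            restore_best=cfg.restore_best,
            swa_start=cfg.swa_start,
            verbose=verbose,
        )
        return self

    def predict_proba(self, X) -> np.ndarray:
        return self.net.predict_proba(
            np.asarray(X, dtype=np.float32) / self.input_scale
        )

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)

    def evaluate_loss(self, X, y) -> float:
        return cross_entropy(self.predict_proba(X), np.asarray(y, dtype=np.int64))


class SklearnBaseline:
    """Uniform wrapper for the scikit-learn baselines (dt / rf / lsvc)."""

    _FACTORIES = {
        "dt": lambda seed: DecisionTreeClassifier(random_state=seed),
        "rf": lambda seed: RandomForestClassifier(
            n_estimators=100, random_state=seed
        ),
        "lsvc": lambda seed: LinearSVC(random_state=seed),
    }

    def __init__(self, kind: str, *, init_seed: int = 0):
        self.kind = kind
        self.estimator = self._FACTORIES[kind](init_seed)
        self.history: list[dict[str, float]] = []

    def fit(self, X, y, cfg: TrainConfig = TrainConfig(), *, validation=None,
            verbose: bool = False):
        self.estimator.fit(X, y)
        acc = float(np.mean(self.estimator.predict(X) == y))
        self.history.append({"epoch": 1, "loss": float("nan"), "accuracy": acc})
        return self

    def predict_proba(self, X) -> np.ndarray:
        if hasattr(self.estimator, "predict_proba"):
            return self.estimator.predict_proba(X)
        # LinearSVC: hard decisions as one-hot rows (still sum to 1)
        pred = self.estimator.predict(X)
        n_classes = len(self.estimator.classes_)
        out = np.zeros((len(pred), n_classes))
        out[np.arange(len(pred)), pred] = 1.0
        return out

    def predict(self, X) -> np.ndarray:
        return self.estimator.predict(X)

    def evaluate_loss(self, X, y) -> float:
        return cross_entropy(self.predict_proba(X), np.asarray(y, dtype=np.int64))


def build_rnn(spec: RNNSpec = RNNSpec(), *, init_seed: int = 0) -> RNNClassifier:
    """Construct the (untrained) recurrent classifier."""
    return RNNClassifier(spec, init_seed=init_seed)


def build_baseline(kind: str, *, input_len: int = 782, init_seed: int = 0,
                   dropout_rate: float = 0.35):
    """Construct an untrained baseline: ``dt``, ``rf``, ``lsvc``, ``mlp6``
    or ``mlp16``."""
    if kind in ("dt", "rf", "lsvc"):
        return SklearnBaseline(kind, init_seed=init_seed)
    if kind in ("mlp6", "mlp16"):
        return MLPBaseline(
            int(kind[3:]),
            input_len=input_len,
            dropout_rate=dropout_rate,
            init_seed=init_seed,
        )
    raise ValueError(f"unknown baseline kind {kind!r}; choose from {BASELINE_KINDS}")


def build_model(kind: str, *, input_len: int = 782, dropout_rate: float = 0.35,
                init_seed: int = 0):
    """Construct any model by name (``rnn`` or a baseline kind)."""
    if kind == "rnn":
        return build_rnn(
            RNNSpec(input_len=input_len, dropout_rate=dropout_rate),
            init_seed=init_seed,
        )
    return build_baseline(
        kind, input_len=input_len, init_seed=init_seed, dropout_rate=dropout_rate
    )


def train_model(model, X, y, cfg: TrainConfig = TrainConfig(), *, validation=None,
                verbose: bool = False):
    """Train any model through the shared fit interface."""
    return model.fit(X, y, cfg, validation=validation, verbose=verbose)


def predict(model, X) -> tuple[np.ndarray, np.ndarray]:
    """Per-class probability rows plus argmax labels (ties break toward
    the lowest class index)."""
    probs = model.predict_proba(X)
    return probs, np.argmax(probs, axis=1)
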