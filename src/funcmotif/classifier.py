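"""Train and evaluate a small convolutional enhancer classifier.

The model maps a one-hot encoded window (L x 4) to a probability that it is
an active enhancer: two valid-mode convolution + ReLU + max-pool blocks, a
flatten, and a dense layer to a single sigmoid output, trained with binary
cross-entropy and Adam. Model selection is by validation auROC with early
stopping; the parameters returned are those of the best validation epoch.
"""

from __future__ import annotations

import hashlib
import json
import pickle
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import roc_auc_score

from .dataset import LabelledExample, encode_batch
from .nn import Adam, Conv1D, Dense, Flatten, MaxPool1D, Network, ReLU, sigmoid


class TrainingError(RuntimeError):
    pass


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ClassifierConfig:
    """Architecture and optimisation settings.

    ``pool_widths`` entries give the max-pool window after each conv block;
    ``-1`` means a global max pool over the remaining length, which makes
    the head translation-invariant — motifs occur at arbitrary offsets, so
    the final block pools globally by default.
    """

    window_length: int = 300
    conv_layers: Tuple[Tuple[int, int], ...] = ((32, 12), (32, 8))  # (filters, width)
    pool_widths: Tuple[int, ...] = (4, -1)
    learning_rate: float = 3e-3
    batch_size: int = 64
    epochs: int = 50
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conv_layers) != len(self.pool_widths):
            raise ValueError("need one pool width per conv layer")


def build_network(config: ClassifierConfig) -> Network:
    rng = np.random.default_rng(config.seed)
    layers = []
    length, channels = config.window_length, 4
    for (n_filters, width), pool in zip(config.conv_layers, config.pool_widths):
        layers.append(Conv1D(channels, n_filters, width, rng))
        layers.append(ReLU())
        conv_len = length - width + 1
        if pool == -1:
            pool = conv_len
        layers.append(MaxPool1D(pool))
        length = conv_len // pool
        channels = n_filters
        if length < 1:
            raise ValueError("window too short for the architecture")
    layers.append(Flatten())
    layers.append(Dense(length * channels, 1, rng))
    return Network(layers)


def _config_hash(config: ClassifierConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True).encode()
    ).hexdigest()[:16]


@dataclass
class TrainedClassifier:
    """A frozen network plus its config and training history."""

    config: ClassifierConfig
    network: Network
    history: List[Dict[str, float]] = field(default_factory=list)

    @property
    def config_hash(self) -> str:
        return _config_hash(self.config)

    def predict(self, sequences: Sequence[str],
                batch_size: int = 256) -> np.ndarray:
        """One probability in [0,1] per input sequence."""
        L = self.config.window_length
        for s in sequences:
            if len(s) != L:
                raise ValueError(f"sequence length {len(s)} != {L}")
        out = []
        for i in range(0, len(sequences), batch_size):
            x = encode_batch(sequences[i : i + batch_size])
            out.append(self.network.predict_proba(x))
        return np.concatenate(out) if out else np.empty(0)

    def save(self, path) -> None:
        payload = {
            "config": asdict(self.config),
            "params": self.network.get_params(),
            "history": self.history,
            "config_hash": self.config_hash,
        }
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "TrainedClassifier":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        cfg_dict = payload["config"]
        cfg_dict["conv_layers"] = tuple(map(tuple, cfg_dict["conv_layers"]))
        cfg_dict["pool_widths"] = tuple(cfg_dict["pool_widths"])
        config = ClassifierConfig(**cfg_dict)
        model = cls(config=config, network=build_network(config))
        model.network.set_params(payload["params"])
        model.history = payload["history"]
        return model


def _xy(examples: Sequence[LabelledExample]) -> Tuple[np.ndarray, np.ndarray]:
    x = encode_batch([ex.sequence for ex in examples])
    y = np.array([ex.label for ex in examples], dtype=float)
    return x, y


def train(
    train_examples: Sequence[LabelledExample],
    validation_examples: Sequence[LabelledExample],
    config: ClassifierConfig = ClassifierConfig(),
) -> TrainedClassifier:
    """Fit the classifier; return the best-validation-auROC parameter set."""
    if not train_examples or not validation_examples:
        raise TrainingError("both train and validation splits must be non-empty")
    x_train, y_train = _xy(train_examples)
    if len(np.unique(y_train)) < 2:
        raise TrainingError("training set contains a single class")
    x_val, y_val = _xy(validation_examples)

    network = build_network(config)
    optimiser = Adam(network, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    n = x_train.shape[0]
    best_auroc, best_params, best_epoch = -np.inf, network.get_params(), -1
    history: List[Dict[str, float]] = []

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            logit, caches = network.forward(xb, with_caches=True)
            p = sigmoid(logit)
            eps = 1e-12
            losses.append(
                -np.mean(yb * np.log(p + eps) + (1 - yb) * np.log(1 - p + eps))
            )
            dlogit = (p - yb) / len(yb)  # d BCE / d logit
            optimiser.step(network.backward(dlogit, caches))
        val_scores = sigmoid(network.forward(x_val))
        if len(np.unique(y_val)) < 2:
            val_auroc = float("nan")
        else:
            val_auroc = float(roc_auc_score(y_val, val_scores))
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)),
             "val_auroc": val_auroc}
        )
        if np.isfinite(val_auroc) and val_auroc > best_auroc:
            best_auroc, best_params, best_epoch = val_auroc, network.get_params(), epoch
        if epoch - best_epoch >= config.patience:
            break

    network.set_params(best_params)
    return TrainedClassifier(config=config, network=network, history=history)


def evaluate_auroc(
    model: TrainedClassifier, test_examples: Sequence[LabelledExample]
) -> float:
    """Rank-based area under the ROC curve (midrank tie handling)."""
    y = np.array([ex.label for ex in test_examples])
    if len(np.unique(y)) < 2:
        raise EvaluationError("test set contains a single class")
    scores = model.predict([ex.sequence for ex in test_examples])
    return float(roc_auc_score(y, scores))
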