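"""Training regime and the scikit-learn estimator wrapping the network.

The reference regime is a constant learning rate of 1e-4, SGD with momentum
0.9, L2 regularization 5e-4, mini-batches of 128, and 30 epochs; with 680
training segments an epoch is ceil(680/128) = 6 iterations.  Data are
shuffled once per epoch under the run seed, so a (data, seed) pair fixes the
entire trajectory.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .errors import ShapeError, TrainingError
from .network import Network, SGDMomentum, _DTYPE
from .topology import (
    TopologySpec,
    build_compact_topology,
    build_reference_topology,
)


@dataclass
class TrainConfig:
    """Hyperparameters of the SGD regime (defaults = the reference values)."""

    learning_rate: float = 0.0001
    momentum: float = 0.9
    l2_regularization: float = 0.0005
    mini_batch_size: int = 128
    epochs: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        if self.l2_regularization < 0:
            raise ValueError("l2_regularization must be nonnegative")
        if self.mini_batch_size < 1 or self.epochs < 1:
            raise ValueError("mini_batch_size and epochs must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)


def iterations_per_epoch(n_train: int, batch: int) -> int:
    """Mini-batch iterations needed to pass the training set once."""
    if n_train < 1 or batch < 1:
        raise ValueError("n_train and batch must be >= 1")
    return math.ceil(n_train / batch)


@dataclass
class TrainedModel:
    """A trained network with its topology, config and per-epoch log."""

    topology: TopologySpec
    network: Network
    training_log: list[dict]
    config: TrainConfig
    classes: np.ndarray


class CNNClassifier(ClassifierMixin, BaseEstimator):
    """Convolutional classifier over raw segment matrices.

    Accepts ``X`` of shape ``(n_segments, n_channels, n_samples)`` — the raw
    amplitude matrices, no feature extraction — and integer or string class
    labels ``y``.

    Parameters
    ----------
    topology : TopologySpec, "reference", or "auto"
        "reference" builds the reference nine-layer network (63 x 1000 inputs);
        "auto" (default) builds it when the input matches 63 x 1000 and
        otherwise a compact variant sized to the input.
    learning_rate, momentum, l2_regularization, batch_size, epochs
        The SGD regime; defaults follow :class:`TrainConfig`.
    random_state : int
        Seeds weight initialization and the per-epoch shuffle.
    """

    def __init__(
        self,
        topology="auto",
        learning_rate: float = 0.0001,
        momentum: float = 0.9,
        l2_regularization: float = 0.0005,
        batch_size: int = 128,
        epochs: int = 30,
        random_state: int = 0,
    ):
        self.topology = topology
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.l2_regularization = l2_regularization
        self.batch_size = batch_size
        self.epochs = epochs
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------

    def _resolve_topology(self, h: int, w: int) -> TopologySpec:
        if isinstance(self.topology, TopologySpec):
            return self.topology
        if self.topology == "reference":
            return build_reference_topology()
        if self.topology == "auto":
            if (h, w) == (63, 1000):
                return build_reference_topology()
            return build_compact_topology((h, w))
        raise ValueError(f"topology must be a TopologySpec, 'reference' or 'auto'; "
                         f"got {self.topology!r}")

    @staticmethod
    def _as_blocks(X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 3:
            raise ShapeError(
                f"X must be (n_segments, n_channels, n_samples), got {X.shape}"
            )
        return X[..., None].astype(_DTYPE)

    # -- estimator API ----------------------------------------------------

    def fit(self, X, y):
        blocks = self._as_blocks(X)
        y = np.asarray(y)
        if y.shape[0] != blocks.shape[0]:
            raise ShapeError("X and y length mismatch")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise TrainingError("training data contains a single class")
        spec = self._resolve_topology(blocks.shape[1], blocks.shape[2])
        if (spec.input_shape.h, spec.input_shape.w) != blocks.shape[1:3]:
            raise ShapeError(
                f"segments of shape {blocks.shape[1:3]} do not match topology "
                f"input {spec.input_shape}"
            )
        if spec.num_classes != len(self.classes_):
            raise TrainingError(
                f"topology has {spec.num_classes} outputs but data has "
                f"{len(self.classes_)} classes"
            )
        rng = np.random.default_rng(self.random_state)
        net = Network(spec, rng)
        optimizer = SGDMomentum(net.parameters(), self.learning_rate,
                                self.momentum)
        n = blocks.shape[0]
        log: list[dict] = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            correct = 0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                loss, probs = net.train_step(blocks[idx], y_idx[idx],
                                             self.l2_regularization)
                optimizer.step()
                epoch_loss += loss * len(idx)
                correct += int((probs.argmax(axis=1) == y_idx[idx]).sum())
            log.append({
                "epoch": epoch + 1,
                "loss": float(epoch_loss / n),
                "train_accuracy": 100.0 * correct / n,
                "weight_norm": net.weight_norm(),
            })
        self.topology_ = spec
        self.network_ = net
        self.training_log_ = log
        self.n_features_in_ = blocks.shape[1] * blocks.shape[2]
        return self

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        blocks = self._as_blocks(X)
        if (self.topology_.input_shape.h,
                self.topology_.input_shape.w) != blocks.shape[1:3]:
            raise ShapeError(
                f"segments of shape {blocks.shape[1:3]} do not match topology "
                f"input {self.topology_.input_shape}"
            )
        return self.network_.predict_proba(blocks)

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def _check_fitted(self):
        if not hasattr(self, "network_"):
            raise TrainingError("classifier is not fitted; call fit first")

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.two_d_array = False
        return tags


def desk_scale_classifier(random_state: int = 0, n_channels: int = 19,
                          n_samples: int = 128) -> CNNClassifier:
    """The desk-scale training configuration used for fast end-to-end runs.

    A compact three-filter variant of the reference topology with a shorter,
    hotter SGD regime (learning rate 0.02, batch 32, 12 epochs) suited to the
    reduced cohort geometry (19 retained channels at 128 Hz, ten one-second
    segments per subject).
    """
    return CNNClassifier(
        topology=build_compact_topology((n_channels, n_samples)),
        learning_rate=0.02,
        momentum=0.9,
        l2_regularization=0.0005,
        batch_size=32,
        epochs=12,
        random_state=random_state,
    )


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------

def train(spec: TopologySpec, segments, labels, cfg: TrainConfig) -> TrainedModel:
    """Train the network described by ``spec`` on labeled segment matrices.

    ``segments`` may be a list of :class:`~eegtbi.data.Segment` or a 3-D
    array ``(n, h, w)``; ``labels`` may be omitted (None) when Segments carry
    class labels.
    """
    X, y = _coerce_segments(segments, labels)
    clf = CNNClassifier(
        topology=spec,
        learning_rate=cfg.learning_rate,
        momentum=cfg.momentum,
        l2_regularization=cfg.l2_regularization,
        batch_size=cfg.mini_batch_size,
        epochs=cfg.epochs,
        random_state=cfg.seed,
    ).fit(X, y)
    return TrainedModel(
        topology=clf.topology_,
        network=clf.network_,
        training_log=clf.training_log_,
        config=cfg,
        classes=clf.classes_,
    )


def predict(model: TrainedModel, segments) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment class probabilities and labels from a trained model."""
    X, _ = _coerce_segments(segments, labels=False)
    blocks = np.asarray(X)[..., None].astype(_DTYPE)
    if (model.topology.input_shape.h,
            model.topology.input_shape.w) != blocks.shape[1:3]:
        raise ShapeError(
            f"segments of shape {blocks.shape[1:3]} do not match topology "
            f"input {model.topology.input_shape}"
        )
    probs = model.network.predict_proba(blocks)
    return probs, model.classes[probs.argmax(axis=1)]


def _coerce_segments(segments, labels):
    from .data import Segment

    if len(segments) and isinstance(segments[0], Segment):
        X = np.stack([s.matrix for s in segments])
        if labels is None:
            labels = np.asarray([s.class_label for s in segments])
    else:
        X = np.asarray(segments)
    if labels is False:
        return X, None
    return X, np.asarray(labels)
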