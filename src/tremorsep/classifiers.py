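"""Model zoo: the conv-biLSTM, the conv-LSTM baseline, KNN and Gaussian NB.

The two neural models consume raw 50-sample IMF windows; the two classical
baselines consume the four hand-crafted features (z-scored with training
statistics). Training follows the stated recipe: plain SGD, learning rate
0.01, binary cross-entropy, batch size 64, 100 epochs by default, decision
threshold 0.5 with ties going to the positive (tremulous) class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier

from .nn import ConvRecurrentNet, DivergenceError


@dataclass(frozen=True)
class ConvLayerSpec:
    filters: int = 30
    kernel: int = 20
    stride: int = 1
    activation: str = "relu"


@dataclass(frozen=True)
class ClassifierSpec:
    """Architecture hyperparameters of the convolutional bi-directional LSTM."""

    input_len: int = 50
    conv1: ConvLayerSpec = field(default_factory=lambda: ConvLayerSpec(kernel=20))
    pool1: int = 2
    conv2: ConvLayerSpec = field(default_factory=lambda: ConvLayerSpec(kernel=10))
    pool2: int = 2
    fc_units: int = 1
    lstm_cells: int = 64
    post_lstm_activation: str = "tanh"
    padding_mode: str = "same"

    def __post_init__(self):
        if min(self.conv1.filters, self.conv1.kernel, self.conv2.filters,
               self.conv2.kernel, self.pool1, self.pool2, self.fc_units,
               self.lstm_cells, self.input_len) < 1:
            raise ValueError("all ClassifierSpec sizes must be positive")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.01
    epochs: int = 100
    batch_size: int = 64
    seed: int = 0
    decision_threshold: float = 0.5

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def build_conv_bilstm(spec: ClassifierSpec = ClassifierSpec(),
                      seed: int = 0) -> ConvRecurrentNet:
    """The proposed model: conv front-end + bi-directional 64-cell LSTM."""
    return ConvRecurrentNet(
        input_len=spec.input_len,
        conv1_filters=spec.conv1.filters, conv1_kernel=spec.conv1.kernel,
        conv2_filters=spec.conv2.filters, conv2_kernel=spec.conv2.kernel,
        pool=spec.pool1, fc_units=spec.fc_units, lstm_cells=spec.lstm_cells,
        bidirectional=True, padding=spec.padding_mode,
        post_lstm_tanh=spec.post_lstm_activation == "tanh", seed=seed)


def build_conv_lstm(spec: ClassifierSpec = ClassifierSpec(),
                    seed: int = 0) -> ConvRecurrentNet:
    """Baseline: identical front-end, uni-directional LSTM."""
    return ConvRecurrentNet(
        input_len=spec.input_len,
        conv1_filters=spec.conv1.filters, conv1_kernel=spec.conv1.kernel,
        conv2_filters=spec.conv2.filters, conv2_kernel=spec.conv2.kernel,
        pool=spec.pool1, fc_units=spec.fc_units, lstm_cells=spec.lstm_cells,
        bidirectional=False, padding=spec.padding_mode,
        post_lstm_tanh=spec.post_lstm_activation == "tanh", seed=seed)


def train_model(model: ConvRecurrentNet, X: np.ndarray, y: np.ndarray,
                cfg: TrainConfig = TrainConfig()) -> list[float]:
    """Mini-batch SGD training; returns the per-epoch mean loss history.

    The training set must contain both classes. Raises
    :class:`DivergenceError` if the loss goes non-finite.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if len(set(np.unique(y)) & {0.0, 1.0}) < 2:
        raise ValueError("training set must contain both classes")
    rng = np.random.default_rng(cfg.seed)
    n = X.shape[0]
    history: list[float] = []
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = perm[start: start + cfg.batch_size]
            loss = model.sgd_step(X[idx], y[idx], cfg.learning_rate)
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite loss {loss} at epoch {epoch}, batch "
                    f"{start // cfg.batch_size}")
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return history


def predict(model: ConvRecurrentNet, X: np.ndarray,
            threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic forward pass: (scores in (0,1), labels at threshold).

    A score exactly at the threshold is labeled positive (>= convention).
    """
    scores = model.predict_proba(X)
    return scores, (scores >= threshold).astype(int)


def _standardize(train_F: np.ndarray, test_F: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    mu = train_F.mean(axis=0)
    sd = train_F.std(axis=0)
    sd[sd == 0] = 1.0
    return (train_F - mu) / sd, (test_F - mu) / sd


def knn_baseline(train_F: np.ndarray, train_y: np.ndarray,
                 test_F: np.ndarray, k: int = 3) -> np.ndarray:
    """K-nearest-neighbors (Euclidean, k=3) on z-scored features."""
    train_y = np.asarray(train_y, int)
    if k > train_F.shape[0]:
        raise ValueError(f"k={k} exceeds training-set size {train_F.shape[0]}")
    tr, te = _standardize(np.asarray(train_F, float), np.asarray(test_F, float))
    clf = KNeighborsClassifier(n_neighbors=k, metric="euclidean",
                               algorithm="brute")
    clf.fit(tr, train_y)
    return clf.predict(te).astype(int)


def knn_scores(train_F: np.ndarray, train_y: np.ndarray,
               test_F: np.ndarray, k: int = 3) -> np.ndarray:
    """Positive-class vote fraction (for ROC curves)."""
    tr, te = _standardize(np.asarray(train_F, float), np.asarray(test_F, float))
    clf = KNeighborsClassifier(n_neighbors=k, metric="euclidean",
                               algorithm="brute")
    clf.fit(tr, np.asarray(train_y, int))
    return clf.predict_proba(te)[:, list(clf.classes_).index(1)]


def gnb_baseline(train_F: np.ndarray, train_y: np.ndarray,
                 test_F: np.ndarray,
                 return_proba: bool = False):
    """Gaussian Naive Bayes on z-scored features.

    Posterior ties are resolved toward the positive class (labels are
    1 iff P(tremulous) >= 0.5). Requires both classes in training.
    """
    train_y = np.asarray(train_y, int)
    if np.unique(train_y).size < 2:
        raise ValueError("Gaussian NB requires both classes in training")
    tr, te = _standardize(np.asarray(train_F, float), np.asarray(test_F, float))
    clf = GaussianNB(var_smoothing=1e-9)
    clf.fit(tr, train_y)
    proba = clf.predict_proba(te)
    p_pos = proba[:, list(clf.classes_).index(1)]
    # the >= 0.5 tie rule, with one-ulp slack so exactly symmetric
    # posteriors (0.5 up to logsumexp rounding) land on the positive side
    labels = (p_pos >= 0.5 - 1e-12).astype(int)
    if return_proba:
        return labels, p_pos
    return labels
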