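"""Multi-class classifiers over weak labels.

Two heads share one decision rule:

* :class:`OvRModel` — one independent binary linear model (L2 logistic
  regression or linear SVM with Platt-scaled margins) per subcategory.
  With balancing on, each binary problem's samples are weighted by the
  one-versus-rest class-weight formula, so minority-positive problems are
  not swamped by negatives.
* :class:`NNClassifier` — a single linear layer with sigmoid outputs (one
  per subcategory), Xavier-initialized and trained by minibatch gradient
  descent under the weighted binary cross-entropy; imbalance is corrected
  by the per-label rescaling weights W_n.

Decision rule: among labels whose positive probability reaches the
threshold (default 0.5), the most probable wins (ties: lowest label
index); if none reaches it, the fallback label is predicted. A multi-label
mode returning every above-threshold label is available on both heads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

from .balancing import nn_class_weights, ovr_class_weight, weighted_bce

__all__ = [
    "OvRConfig",
    "OvRModel",
    "train_ovr",
    "predict",
    "NNConfig",
    "NNClassifier",
    "train_nn",
    "predict_nn",
    "nn_weights_from_counts",
]

FALLBACK_LABEL = "General or Other"


# ---------------------------------------------------------------------------
# one-versus-rest linear models
# ---------------------------------------------------------------------------


@dataclass
class OvRConfig:
    learner: str = "logistic"        # "logistic" | "linear-svm"
    balanced: bool = True
    C: float = 1.0                   # logistic regularization strength
    svm_C: float = 3.0               # hinge-loss regularization
    tol: float = 1e-6
    max_iter: int = 1000
    threshold: float = 0.5
    fallback_label: str = FALLBACK_LABEL
    seed: int = 0

    def __post_init__(self):
        if self.learner not in ("logistic", "linear-svm"):
            raise ValueError(f"unknown learner {self.learner!r}")


@dataclass
class _PlattScaler:
    """Sigmoid map from SVM margins to probabilities (1-D logistic fit)."""

    a: float
    b: float

    def prob(self, margin: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-(self.a * margin + self.b)))


@dataclass
class OvRModel:
    labels: list[str]
    estimators: list
    platt: list[_PlattScaler | None]
    config: OvRConfig
    n_features: int
    class_weights: dict[str, tuple[float, float]] = field(default_factory=dict)

    def probabilities(self, X) -> np.ndarray:
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimension {X.shape[1]} != model's {self.n_features}"
            )
        out = np.empty((X.shape[0], len(self.labels)))
        for j, est in enumerate(self.estimators):
            if self.platt[j] is not None:
                out[:, j] = self.platt[j].prob(est.decision_function(X))
            else:
                out[:, j] = est.predict_proba(X)[:, 1]
        return out


def train_ovr(X, y: list[str], config: OvRConfig | None = None,
              labels: list[str] | None = None) -> OvRModel:
    """Fit one binary linear model per label.

    ``labels`` fixes the label index (default: sorted unique labels in
    ``y``). Every label must have at least one positive instance. With
    ``config.balanced``, the per-class weights of each binary problem are
    applied as sample weights.
    """
    config = config or OvRConfig()
    y = np.asarray(y, dtype=object)
    if labels is None:
        labels = sorted(set(y))
    if len(labels) < 2:
        raise ValueError("need at least 2 distinct labels")
    missing = [lbl for lbl in labels if not np.any(y == lbl)]
    if missing:
        raise ValueError(f"labels with zero positive instances: {missing}")

    estimators, platts = [], []
    class_weights: dict[str, tuple[float, float]] = {}
    n = len(y)
    for lbl in labels:
        yb = (y == lbl).astype(int)
        sample_weight = None
        if config.balanced:
            counts = [int((yb == 0).sum()), int(yb.sum())]
            w = ovr_class_weight(n, 2, counts)
            class_weights[lbl] = w.weights
            sample_weight = w.sample_weights(yb)
        if config.learner == "logistic":
            est = LogisticRegression(
                solver="lbfgs", C=config.C, tol=config.tol,
                max_iter=config.max_iter,
            )
            est.fit(X, yb, sample_weight=sample_weight)
            platt = None
        else:
            est = LinearSVC(
                C=config.svm_C, loss="hinge", tol=config.tol,
                max_iter=max(config.max_iter, 10000),
                random_state=config.seed,
            )
            est.fit(X, yb, sample_weight=sample_weight)
            platt = _fit_platt(est.decision_function(X), yb, sample_weight)
        estimators.append(est)
        platts.append(platt)
    return OvRModel(list(labels), estimators, platts, config, X.shape[1],
                    class_weights)


def _fit_platt(margins: np.ndarray, yb: np.ndarray,
               sample_weight: np.ndarray | None) -> _PlattScaler:
    lr = LogisticRegression(solver="lbfgs", C=1e6, tol=1e-8, max_iter=1000)
    lr.fit(margins.reshape(-1, 1), yb, sample_weight=sample_weight)
    return _PlattScaler(a=float(lr.coef_[0, 0]), b=float(lr.intercept_[0]))


def _decide(probs: np.ndarray, labels: list[str], threshold: float,
            fallback: str, multi_label: bool):
    if multi_label:
        return [
            [labels[j] for j in np.nonzero(row >= threshold)[0]] or [fallback]
            for row in probs
        ]
    out = []
    for row in probs:
        eligible = row >= threshold
        if not eligible.any():
            out.append(fallback)
        else:
            masked = np.where(eligible, row, -np.inf)
            out.append(labels[int(np.argmax(masked))])  # argmax: lowest index wins ties
    return out


def predict(model: OvRModel, X, multi_label: bool = False):
    """Per-sentence (label, probability vector); see module decision rule."""
    probs = model.probabilities(X)
    decisions = _decide(probs, model.labels, model.config.threshold,
                        model.config.fallback_label, multi_label)
    return decisions, probs


# ---------------------------------------------------------------------------
# neural head
# ---------------------------------------------------------------------------


@dataclass
class NNConfig:
    batch_size: int = 32
    epochs: int = 5
    learning_rate: float = 20.0
    threshold: float = 0.5
    fallback_label: str = FALLBACK_LABEL
    seed: int = 0
    scale_value: float = 3.0


@dataclass
class NNClassifier:
    labels: list[str]
    W: np.ndarray                    # (n_features, n_labels)
    b: np.ndarray                    # (n_labels,)
    config: NNConfig
    loss_history: list[float] = field(default_factory=list)  # per batch
    epoch_losses: list[float] = field(default_factory=list)

    def probabilities(self, X) -> np.ndarray:
        if X.shape[1] != self.W.shape[0]:
            raise ValueError(
                f"feature dimension {X.shape[1]} != model's {self.W.shape[0]}"
            )
        # clip away float under/overflow so outputs stay in the open (0, 1)
        return np.clip(expit(X @ self.W + self.b), 1e-12, 1.0 - 1e-12)


def _one_hot(y: list[str], labels: list[str]) -> np.ndarray:
    index = {lbl: j for j, lbl in enumerate(labels)}
    Y = np.zeros((len(y), len(labels)))
    for i, lbl in enumerate(y):
        Y[i, index[lbl]] = 1.0
    return Y


def train_nn(X, y: list[str], class_weights: np.ndarray | None = None,
             config: NNConfig | None = None,
             labels: list[str] | None = None) -> NNClassifier:
    """Minibatch gradient descent on the weighted BCE.

    ``class_weights`` is the length-N vector of rescaling weights W_n
    (None = unweighted; a vector of ones gives a parameter trajectory
    bit-identical to the unweighted run under the same seed). The loss of
    every batch is recorded in ``loss_history``.
    """
    config = config or NNConfig()
    if labels is None:
        labels = sorted(set(y))
    Y = _one_hot(y, labels)
    n, d = X.shape[0], X.shape[1]
    N = len(labels)
    if class_weights is not None:
        class_weights = np.asarray(class_weights, dtype=float)
        if class_weights.shape != (N,):
            raise ValueError(f"class_weights must have shape ({N},)")

    rng = np.random.default_rng(config.seed)
    # Xavier/Glorot uniform initialization of the single linear layer
    limit = np.sqrt(6.0 / (d + N))
    W = rng.uniform(-limit, limit, size=(d, N))
    b = np.zeros(N)
    model = NNClassifier(list(labels), W, b, config)

    w_eff = np.ones(N) if class_weights is None else class_weights
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            Xb = X[idx]
            if sp.issparse(Xb):
                Xb = Xb.toarray()
            Yb = Y[idx]
            P = expit(Xb @ W + b)
            loss = weighted_bce(P, Yb, w_eff).mean
            if not np.isfinite(loss):
                raise FloatingPointError(
                    "non-finite loss; lower the learning rate"
                )
            model.loss_history.append(loss)
            epoch_loss.append(loss)
            # d(mean over batch and labels of l_n)/dz = w_n (P - Y) / (B N)
            G = w_eff * (P - Yb) / (len(idx) * N)
            W -= config.learning_rate * (Xb.T @ G)
            b -= config.learning_rate * G.sum(axis=0)
        model.epoch_losses.append(float(np.mean(epoch_loss)))
    return model


def nn_weights_from_counts(y: list[str], labels: list[str],
                           SV: float = 3.0) -> np.ndarray:
    """Convenience: W_n vector from label counts in the training data."""
    counts = [sum(1 for v in y if v == lbl) for lbl in labels]
    return nn_class_weights(counts, SV)


def predict_nn(model: NNClassifier, X, multi_label: bool = False):
    """Same decision rule as the one-versus-rest head."""
    probs = model.probabilities(X)
    decisions = _decide(probs, model.labels, model.config.threshold,
                        model.config.fallback_label, multi_label)
    return decisions, probs
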