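"""Cost-sensitive class weighting and the weighted binary cross-entropy.

Two weighting schemes address label imbalance:

* the one-versus-rest scheme weights each class of a binary problem by
  ``weight_i = n_samples / (n_classes * bincount_i)``, so that
  ``weight_i * bincount_i`` is the same for every class — a balanced
  problem gets unit weights;

* the neural-head scheme assigns label ``n`` with ``K`` training instances
  the rescaling weight ``W_n = (T + K * SV) / (N * K)`` where ``T`` is the
  total sample count, ``N`` the number of labels and ``SV`` a scale value
  (default 3). Minority labels (small ``K``) get strictly larger weights,
  and at uniform class sizes ``K = T/N`` the weight reduces to
  ``1 + SV/N`` — close to 1, so the correction vanishes as imbalance
  vanishes. (The algebraically distinct literal reading
  ``T + SV/N``, which is independent of ``K``, is available behind the
  ``literal`` flag for auditability.)

The loss is a per-label weighted binary cross-entropy over sigmoid outputs,

    l_n = -W_n * (Y_n * log(X_n) + (1 - Y_n) * log(1 - X_n)),
    L = mean(l_1 .. l_N),

with probabilities clipped to keep the loss finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OvRWeights",
    "ovr_class_weight",
    "nn_class_weight",
    "nn_class_weights",
    "LossValue",
    "weighted_bce",
]

DEFAULT_SCALE_VALUE = 3.0
CLIP_EPS = 1e-12


@dataclass(frozen=True)
class OvRWeights:
    """Per-class weights for one binary (one-versus-rest) problem."""

    weights: tuple[float, ...]
    n_samples: int
    n_classes: int
    bincount: tuple[int, ...]

    def sample_weights(self, y: np.ndarray) -> np.ndarray:
        """Per-sample weight vector for integer class labels ``y``."""
        return np.asarray(self.weights)[np.asarray(y, dtype=int)]


def ovr_class_weight(
    n_samples: int, n_classes: int, bincount: list[int] | np.ndarray
) -> OvRWeights:
    """weight_i = n_samples / (n_classes * bincount_i).

    Requires every class to be present (a zero bincount means the label is
    absent from the training fold, which is an error, not a weight of
    infinity).
    """
    bincount = [int(b) for b in bincount]
    if len(bincount) != n_classes:
        raise ValueError("bincount length must equal n_classes")
    if any(b <= 0 for b in bincount):
        raise ValueError(f"zero bincount in {bincount}: a class is absent")
    if sum(bincount) != n_samples:
        raise ValueError("bincount must sum to n_samples")
    weights = tuple(n_samples / (n_classes * b) for b in bincount)
    return OvRWeights(weights, n_samples, n_classes, tuple(bincount))


def nn_class_weight(T: int, K: int, N: int,
                    SV: float = DEFAULT_SCALE_VALUE,
                    literal: bool = False) -> float:
    """Rescaling weight W_n for one label with K of T samples, N labels."""
    if K <= 0:
        raise ValueError("K must be positive (label absent from training)")
    if K > T or N < 1 or SV <= 0:
        raise ValueError("require 0 < K <= T, N >= 1, SV > 0")
    if literal:
        return T + (K * SV) / (N * K)
    return (T + K * SV) / (N * K)


def nn_class_weights(counts: list[int] | np.ndarray,
                     SV: float = DEFAULT_SCALE_VALUE) -> np.ndarray:
    """Vector of W_n for all N labels from their per-label counts."""
    counts = np.asarray(counts, dtype=float)
    T = counts.sum()
    N = len(counts)
    return np.array([nn_class_weight(int(T), int(k), N, SV) for k in counts])


@dataclass(frozen=True)
class LossValue:
    """Per-label losses and their mean."""

    per_label: np.ndarray
    mean: float


def weighted_bce(
    X: np.ndarray,
    Y: np.ndarray,
    W: np.ndarray | None = None,
    eps: float = CLIP_EPS,
) -> LossValue:
    """Weighted binary cross-entropy over N labels.

    ``X`` are sigmoid outputs and ``Y`` binary targets, shape ``(N,)`` for a
    single instance or ``(batch, N)`` for a minibatch; ``W`` is the length-N
    weight vector (default all ones). For batches the per-label loss is the
    mean over instances, and the scalar loss the mean over labels.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError(f"shape mismatch: X {X.shape} vs Y {Y.shape}")
    n_labels = X.shape[-1]
    if W is None:
        W = np.ones(n_labels)
    W = np.asarray(W, dtype=float)
    if W.shape != (n_labels,):
        raise ValueError(f"weights must have shape ({n_labels},), got {W.shape}")
    Xc = np.clip(X, eps, 1.0 - eps)
    ln = -W * (Y * np.log(Xc) + (1.0 - Y) * np.log1p(-Xc))
    if ln.ndim == 2:
        ln = ln.mean(axis=0)
    return LossValue(per_label=ln, mean=float(ln.mean()))
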