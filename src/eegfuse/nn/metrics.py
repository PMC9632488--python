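"""Classification contracts: softmax, cross-entropy loss, accuracy, confusion.

These are the quantities the training loop optimizes and reports; they are
kept as small standalone functions so their closed forms can be checked
directly (uniform binary prediction -> ln 2; perfect prediction -> 0;
accuracy = trace/sum of the confusion matrix).
"""

from __future__ import annotations

import numpy as np

#: probability clamp applied inside the log of the cross-entropy
EPS = 1e-12


def softmax_probabilities(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max-shift for overflow stability.

    Accepts a length-k vector or an (n, k) matrix; components are positive
    and each row sums to 1 (within machine tolerance), invariant to adding
    a constant to all logits of a row.
    """
    z = np.asarray(logits, dtype=np.float64)
    if not np.isfinite(z).all():
        raise ValueError("logits must be finite")
    squeeze = z.ndim == 1
    if squeeze:
        z = z[None, :]
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    return p[0] if squeeze else p


def cross_entropy_loss(probabilities: np.ndarray, onehot_labels: np.ndarray) -> float:
    """Mean negative log-likelihood of the true classes.

    ``loss = -(1/n) sum_i sum_c y_ic log p_ic``; zero iff every sample puts
    probability 1 on its true class.  Probabilities are clamped at ``EPS``
    before the log so a confident wrong prediction yields a large finite loss.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(onehot_labels, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: probabilities {p.shape} vs labels {y.shape}")
    return float(-(y * np.log(np.maximum(p, EPS))).sum() / p.shape[0])


def accuracy_score(predicted: np.ndarray, true: np.ndarray) -> float:
    """Fraction of correct label predictions; equals (TP+TN)/(TP+TN+FP+FN) for k=2."""
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.shape != true.shape:
        raise ValueError(f"length mismatch: {predicted.shape} vs {true.shape}")
    if predicted.size == 0:
        raise ValueError("need at least one prediction")
    return float((predicted == true).mean())


def confusion_matrix(true: np.ndarray, predicted: np.ndarray, n_classes: int) -> np.ndarray:
    """k x k integer matrix, rows = true class, columns = predicted class."""
    true = np.asarray(true, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if true.shape != predicted.shape:
        raise ValueError("true and predicted must have equal length")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (true, predicted), 1)
    return cm


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    out = np.zeros((labels.size, n_classes), dtype=np.float64)
    out[np.arange(labels.size), labels] = 1.0
    return out
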