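"""Probabilistic neural network (Parzen-window) classifier.

A PNN has no iterative training: the pattern layer stores one Gaussian
kernel per training example, the summation layer averages kernel
activations within each class, and the output layer picks the class with
the highest activation. With kernel width ``sigma -> 0`` the decision
converges to 1-nearest-neighbor; with ``sigma -> inf`` all classes tie
and the first declared class wins by the tie-break rule.

Feature dimensions are z-scored with the training mean/SD before kernel
evaluation (GLCM features span orders of magnitude, so raw Euclidean
distance would be dominated by a single dimension). Per-class averaging
``(1/n_c) * sum_i exp(-||x - p_i||^2 / (2 sigma^2))`` makes scores
insensitive to class imbalance in the training set.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PNNModel",
    "ClassificationResult",
    "train",
    "classify",
    "classify_batch",
    "accuracy",
    "loo_sigma_search",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class PNNModel:
    """Stored (standardized) training patterns plus kernel width."""

    patterns: np.ndarray  # (n, P) standardized feature vectors
    labels: np.ndarray  # (n,) class labels
    classes: tuple  # ordered label set; order defines the tie-break
    sigma: float
    feature_mean: np.ndarray  # (P,)
    feature_std: np.ndarray  # (P,)

    @property
    def input_dim(self) -> int:
        return self.patterns.shape[1]

    def standardize(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=np.float64) - self.feature_mean) / self.feature_std


@dataclass(frozen=True)
class ClassificationResult:
    """Predicted label with per-class activations and 1/0 decisions."""

    label: object
    scores: dict
    decision: dict


def _as_matrix(features: Sequence) -> np.ndarray:
    X = np.asarray(
        [list(f.values()) if isinstance(f, dict) else list(f) for f in features],
        dtype=np.float64,
    )
    if X.ndim != 2:
        raise ValueError("features must be a list of equal-length vectors")
    return X


def train(
    features: Sequence,
    labels: Sequence,
    sigma: float = 0.5,
    classes: Sequence | None = None,
) -> PNNModel:
    """Build a PNN by storing standardized patterns (no optimization).

    ``classes`` fixes the class order used for tie-breaking; when omitted
    it is the order of first appearance in ``labels``. Every class must
    have at least one training example. A zero-variance feature dimension
    gets SD 1 with a warning so standardization stays finite.
    """
    X = _as_matrix(features)
    y = np.asarray(list(labels))
    if len(y) != X.shape[0]:
        raise ValueError(
            f"features ({X.shape[0]}) and labels ({len(y)}) lengths differ"
        )
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if classes is None:
        seen: dict = {}
        for lab in y:
            seen.setdefault(lab, None)
        classes = tuple(seen)
    else:
        classes = tuple(classes)
    for c in classes:
        if not np.any(y == c):
            raise ValueError(f"class {c!r} has no training examples")
    unknown = set(y.tolist()) - set(classes)
    if unknown:
        raise ValueError(f"labels {unknown} not in declared classes {classes}")

    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=0)
    zero = std == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} feature dimension(s) have zero variance; "
            "their SD is set to 1",
            stacklevel=2,
        )
        std = np.where(zero, 1.0, std)
    return PNNModel(
        patterns=(X - mean) / std,
        labels=y,
        classes=classes,
        sigma=float(sigma),
        feature_mean=mean,
        feature_std=std,
    )


def _scores(model: PNNModel, x: np.ndarray) -> tuple[dict, dict]:
    """Absolute and shift-normalized per-class mean kernel activations.

    At very small sigma every absolute kernel value underflows to zero,
    so the decision uses activations rescaled by ``exp(d2_min/(2 sigma^2))``
    — a positive constant that preserves the argmax in exact arithmetic
    while keeping the nearest pattern's kernel representable.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (model.input_dim,):
        raise ValueError(
            f"input dimension {x.shape} does not match model P={model.input_dim}"
        )
    z = model.standardize(x)
    d2 = np.sum((model.patterns - z) ** 2, axis=1)
    shift = float(d2.min())
    k_rel = np.exp(-(d2 - shift) / (2.0 * model.sigma**2))
    scale = math.exp(-shift / (2.0 * model.sigma**2))  # underflows to 0.0 harmlessly
    relative = {c: float(k_rel[model.labels == c].mean()) for c in model.classes}
    absolute = {c: relative[c] * scale for c in model.classes}
    return absolute, relative


def classify(model: PNNModel, x: Sequence | np.ndarray) -> ClassificationResult:
    """Assign the class with the highest mean kernel activation.

    Ties are broken by class order in ``model.classes``; the ``decision``
    field carries the 1-of-K coding (1 for the chosen class, 0 otherwise).
    """
    if isinstance(x, dict):
        x = list(x.values())
    scores, relative = _scores(model, np.asarray(x, dtype=np.float64))
    # scores within a hair of the maximum are treated as exact ties so the
    # declared class order decides; with a very wide kernel all activations
    # agree to ~1e-12 and the first class must win deterministically
    top = max(relative.values())
    best = next(c for c in model.classes if relative[c] >= top * (1.0 - 1e-9))
    return ClassificationResult(
        label=best,
        scores=scores,
        decision={c: int(c == best) for c in model.classes},
    )


def classify_batch(model: PNNModel, features: Sequence) -> list[ClassificationResult]:
    return [classify(model, f) for f in features]


def accuracy(model: PNNModel, features: Sequence, labels: Sequence) -> float:
    """Percentage of correct classifications: 100 * correct / total."""
    y = list(labels)
    if len(y) == 0:
        raise ValueError("accuracy requires a non-empty test set")
    X = _as_matrix(features)
    if X.shape[0] != len(y):
        raise ValueError("features and labels lengths differ")
    correct = sum(
        classify(model, X[i]).label == y[i] for i in range(len(y))
    )
    return 100.0 * correct / len(y)


def loo_sigma_search(
    features: Sequence,
    labels: Sequence,
    grid: Sequence[float] | None = None,
    classes: Sequence | None = None,
) -> float:
    """Pick sigma by leave-one-out accuracy over a log-spaced grid.

    Returns the smallest grid value attaining the best LOO accuracy.
    """
    if grid is None:
        grid = np.logspace(-2, 1, 20)
    X = _as_matrix(features)
    y = list(labels)
    n = len(y)
    best_sigma, best_acc = None, -1.0
    for s in grid:
        correct = 0
        for i in range(n):
            keep = [j for j in range(n) if j != i]
            try:
                m = train([X[j] for j in keep], [y[j] for j in keep], sigma=float(s), classes=classes)
            except ValueError:  # a class vanished from the fold
                continue
            correct += classify(m, X[i]).label == y[i]
        acc = correct / n
        if acc > best_acc:
            best_sigma, best_acc = float(s), acc
    return best_sigma


def save_model(model: PNNModel, path: str | Path) -> None:
    """Serialize the model to a single portable JSON file."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "sigma": model.sigma,
        "classes": list(model.classes),
        "labels": model.labels.tolist(),
        "patterns": model.patterns.tolist(),
        "feature_mean": model.feature_mean.tolist(),
        "feature_std": model.feature_std.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> PNNModel:
    payload = json.loads(Path(path).read_text())
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {version!r}")
    return PNNModel(
        patterns=np.asarray(payload["patterns"], dtype=np.float64),
        labels=np.asarray(payload["labels"]),
        classes=tuple(payload["classes"]),
        sigma=float(payload["sigma"]),
        feature_mean=np.asarray(payload["feature_mean"], dtype=np.float64),
        feature_std=np.asarray(payload["feature_std"], dtype=np.float64),
    )
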