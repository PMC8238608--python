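"""Probabilistic neural network (PNN) classifier.

A PNN is a Parzen-window kernel density classifier organized as four layers:
the input layer takes a feature vector, the pattern layer holds one Gaussian
kernel per stored training example, the summation layer averages the kernel
activations within each class,

    S_c(q) = (1/n_c) sum_{i in c} exp(-||q - p_i||^2 / (2 sigma^2)),

and the output layer picks the class with the largest normalized score.
Training is pure storage: patterns are standardized per feature (zero-
variance features are dropped with a warning) and kept verbatim, so the
model is deterministic and needs no iterative optimization.  Class sums are
averaged so unbalanced classes do not dominate.  As sigma -> 0 the decision
rule converges to 1-nearest-neighbor.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp


@dataclass
class PNNModel:
    patterns: np.ndarray          # n x d, standardized
    labels: np.ndarray            # n
    classes: list                 # ordered class list (ties break to first)
    sigma: float
    feature_means: np.ndarray     # d (original scale)
    feature_stds: np.ndarray      # d
    feature_names: list = field(default_factory=list)


def pnn_train(features, labels, sigma: float = 0.5,
              feature_names=None) -> PNNModel:
    """Store standardized training patterns.

    ``features`` may be a DataFrame (numeric columns become features) or an
    n x d array.  Requires >= 2 classes with >= 1 example each; features
    with zero variance across training are dropped with a warning.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if isinstance(features, pd.DataFrame):
        feature_names = list(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        feature_names = list(feature_names or range(X.shape[1]))
    y = np.asarray(labels)
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for c in classes:
        if not (y == c).any():
            raise ValueError(f"class {c!r} has no training examples")

    means = X.mean(axis=0)
    stds = X.std(axis=0)
    keep = stds > 0
    if not keep.all():
        dropped = [feature_names[i] for i in np.flatnonzero(~keep)]
        warnings.warn(f"dropping zero-variance feature(s): {dropped}")
    X = (X[:, keep] - means[keep]) / stds[keep]
    return PNNModel(
        patterns=X, labels=y, classes=classes, sigma=float(sigma),
        feature_means=means[keep], feature_stds=stds[keep],
        feature_names=[feature_names[i] for i in np.flatnonzero(keep)],
    )


def _standardize_query(model: PNNModel, query) -> np.ndarray:
    q = np.asarray(query, dtype=float).ravel()
    if q.size != model.patterns.shape[1]:
        raise ValueError(
            f"query dimension {q.size} != model dimension "
            f"{model.patterns.shape[1]}"
        )
    return (q - model.feature_means) / model.feature_stds


def pnn_scores(model: PNNModel, query, raw: bool = False) -> dict:
    """Per-class posteriors (summing to 1), log-sum-exp stabilized.

    ``raw=True`` expects an already standardized query (used internally for
    leave-one-out over stored patterns).
    """
    q = np.asarray(query, dtype=float).ravel() if raw else _standardize_query(model, query)
    d2 = ((model.patterns - q[None, :]) ** 2).sum(axis=1)
    log_kernel = -d2 / (2.0 * model.sigma**2)
    log_s = np.empty(len(model.classes))
    for idx, c in enumerate(model.classes):
        sel = model.labels == c
        if not sel.any():  # class absent (e.g. left out): zero score
            log_s[idx] = -np.inf
            continue
        log_s[idx] = logsumexp(log_kernel[sel]) - np.log(sel.sum())
    log_post = log_s - logsumexp(log_s)
    post = np.exp(log_post)
    return {c: float(p) for c, p in zip(model.classes, post)}


def pnn_predict(model: PNNModel, query, raw: bool = False):
    """Argmax-posterior label (ties -> first class in model.classes order)."""
    post = pnn_scores(model, query, raw=raw)
    best_c, best_p = None, -np.inf
    for c in model.classes:  # fixed order => deterministic tie-break
        if post[c] > best_p:
            best_c, best_p = c, post[c]
    return best_c, post


def loo_predictions(model: PNNModel):
    """Leave-one-out predictions over the stored training patterns."""
    preds = []
    posteriors = []
    for i in range(model.patterns.shape[0]):
        sub = PNNModel(
            patterns=np.delete(model.patterns, i, axis=0),
            labels=np.delete(model.labels, i),
            classes=model.classes,
            sigma=model.sigma,
            feature_means=model.feature_means,
            feature_stds=model.feature_stds,
            feature_names=model.feature_names,
        )
        label, post = pnn_predict(sub, model.patterns[i], raw=True)
        preds.append(label)
        posteriors.append(post)
    return preds, posteriors


def tune_sigma(features, labels, grid=None):
    """Pick sigma by leave-one-out accuracy over a grid (first best wins)."""
    grid = grid if grid is not None else np.geomspace(0.05, 5.0, 15)
    best_sigma, best_acc = None, -1.0
    y = np.asarray(labels)
    for s in grid:
        model = pnn_train(features, labels, sigma=float(s))
        preds, _ = loo_predictions(model)
        acc = float(np.mean(np.asarray(preds) == y))
        if acc > best_acc:
            best_sigma, best_acc = float(s), acc
    return best_sigma, best_acc


def save_model(model: PNNModel, path) -> None:
    payload = {
        "patterns": model.patterns.tolist(),
        "labels": np.asarray(model.labels).tolist(),
        "classes": list(model.classes),
        "sigma": model.sigma,
        "feature_means": model.feature_means.tolist(),
        "feature_stds": model.feature_stds.tolist(),
        "feature_names": list(model.feature_names),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> PNNModel:
    with open(path) as fh:
        payload = json.load(fh)
    return PNNModel(
        patterns=np.asarray(payload["patterns"], dtype=float),
        labels=np.asarray(payload["labels"]),
        classes=payload["classes"],
        sigma=float(payload["sigma"]),
        feature_means=np.asarray(payload["feature_means"], dtype=float),
        feature_stds=np.asarray(payload["feature_stds"], dtype=float),
        feature_names=payload["feature_names"],
    )


__all__ = [
    "PNNModel", "pnn_train", "pnn_scores", "pnn_predict",
    "loo_predictions", "tune_sigma", "save_model", "load_model",
]
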