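"""Classifiers and confusion-matrix accounting.

Three supervised learners are used across the pipeline, all implemented
in-repo so every numerical choice is explicit:

* logistic regression fitted by iteratively reweighted least squares with a
  tiny L2 ridge (guards against perfect separation);
* Gaussian naive Bayes with log-space likelihood accumulation;
* k-nearest neighbours with exhaustive Euclidean search.

The binding class (1) is always the class of interest, so every tie —
equal posteriors, even split of a KNN vote — resolves to class 1: missing a
true binder costs more than flagging a spurious one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_model import DescriptorTable

__all__ = [
    "LogisticModel",
    "GaussianNBModel",
    "ConfusionCounts",
    "fit_logistic",
    "predict_logistic",
    "fit_gaussian_nb",
    "predict_gaussian_nb",
    "knn_predict",
    "confusion_counts",
    "metrics",
]


def _standardizer(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mean, sd


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogisticModel:
    """log(p / (1-p)) = intercept + weights . features (standardised scale)."""

    feature_names: tuple[str, ...]
    intercept: float
    weights: np.ndarray
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    converged: bool = True
    loglik_path: tuple[float, ...] = field(default=(), repr=False)


def fit_logistic(
    train: DescriptorTable,
    max_iter: int = 100,
    tol: float = 1e-8,
    ridge: float = 1e-6,
) -> LogisticModel:
    """Maximum-likelihood logistic fit via IRLS with an L2 ridge.

    Features are standardised internally (train mean/SD), which both
    conditions the IRLS system and makes the ridge scale-free.  Step-halving
    enforces a non-decreasing penalised log-likelihood; with the ridge the
    optimum exists even under perfect separation.
    """
    y = train.labels.astype(float)
    if y.min() == y.max():
        raise ValueError("logistic regression needs both classes in training data")
    mean, sd = _standardizer(train.values)
    x = (train.values - mean) / sd
    n, p = x.shape
    design = np.hstack([np.ones((n, 1)), x])
    beta = np.zeros(p + 1)
    penalty = np.full(p + 1, ridge)
    penalty[0] = 0.0  # never shrink the intercept

    def pen_loglik(b: np.ndarray) -> float:
        eta = design @ b
        # log-likelihood via logaddexp for numerical safety
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        return ll - 0.5 * float(penalty @ (b * b))

    ll = pen_loglik(beta)
    path = [ll]
    converged = False
    for _ in range(max_iter):
        eta = design @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        grad = design.T @ (y - mu) - penalty * beta
        hess = (design.T * w) @ design + np.diag(penalty)
        step = np.linalg.solve(hess, grad)
        # damped Newton: halve until the penalised likelihood does not drop
        scale = 1.0
        new_ll = pen_loglik(beta + step)
        while new_ll < ll and scale > 1e-8:
            scale *= 0.5
            new_ll = pen_loglik(beta + scale * step)
        beta = beta + scale * step
        path.append(new_ll)
        if abs(new_ll - ll) < tol * (abs(ll) + 1.0):
            converged = True
            ll = new_ll
            break
        ll = new_ll
    if not converged:
        warnings.warn("logistic IRLS did not converge; returning best iterate")
    return LogisticModel(
        feature_names=train.feature_names,
        intercept=float(beta[0]),
        weights=beta[1:],
        feature_mean=mean,
        feature_sd=sd,
        converged=converged,
        loglik_path=tuple(path),
    )


def predict_logistic(
    model: LogisticModel, table: DescriptorTable, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Return (P(class 1), binary predictions); predict 1 iff p >= threshold."""
    if table.feature_names != model.feature_names:
        raise ValueError("feature names do not match the fitted model")
    x = (table.values - model.feature_mean) / model.feature_sd
    eta = model.intercept + x @ model.weights
    prob = 1.0 / (1.0 + np.exp(-eta))
    return prob, (prob >= threshold).astype(int)


# ---------------------------------------------------------------------------
# Gaussian naive Bayes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianNBModel:
    feature_names: tuple[str, ...]
    log_priors: np.ndarray  # (2,)
    means: np.ndarray  # (2, p)
    variances: np.ndarray  # (2, p), floored


def fit_gaussian_nb(train: DescriptorTable, var_floor_frac: float = 1e-9) -> GaussianNBModel:
    """Empirical per-class Gaussian likelihoods on raw (unscaled) descriptors.

    Variances are floored at ``var_floor_frac`` times the mean overall
    feature variance so a descriptor that is constant within a class cannot
    produce a degenerate likelihood.
    """
    y = train.labels
    if y.min() == y.max():
        raise ValueError("Gaussian NB needs both classes in training data")
    x = train.values
    floor = var_floor_frac * float(x.var(axis=0).mean())
    floor = max(floor, 1e-300)
    means = np.stack([x[y == c].mean(axis=0) for c in (0, 1)])
    variances = np.stack([x[y == c].var(axis=0) for c in (0, 1)])
    variances = np.maximum(variances, floor)
    priors = np.array([(y == 0).mean(), (y == 1).mean()])
    return GaussianNBModel(train.feature_names, np.log(priors), means, variances)


def predict_gaussian_nb(
    model: GaussianNBModel, table: DescriptorTable
) -> tuple[np.ndarray, np.ndarray]:
    """Return (posterior matrix (n, 2), predictions); posterior ties -> class 1."""
    if table.feature_names != model.feature_names:
        raise ValueError("feature names do not match the fitted model")
    x = table.values
    log_post = np.empty((x.shape[0], 2))
    for c in (0, 1):
        z = (x - model.means[c]) ** 2 / model.variances[c]
        log_lik = -0.5 * (np.log(2.0 * np.pi * model.variances[c]) + z).sum(axis=1)
        log_post[:, c] = model.log_priors[c] + log_lik
    log_post -= log_post.max(axis=1, keepdims=True)
    post = np.exp(log_post)
    post /= post.sum(axis=1, keepdims=True)
    pred = (post[:, 1] >= post[:, 0]).astype(int)
    return post, pred


# ---------------------------------------------------------------------------
# K-nearest neighbours
# ---------------------------------------------------------------------------

def knn_predict(
    train: DescriptorTable, query: DescriptorTable, k: int = 5
) -> np.ndarray:
    """Majority vote of the k Euclidean-nearest training conformations.

    Features are standardised with train-set statistics so no single
    large-scale descriptor (e.g. mass vs. a unitless ratio) dominates the
    metric.  Distance ties resolve by training-row order (stable sort); an
    even vote resolves to the binding class.
    """
    if train.feature_names != query.feature_names:
        raise ValueError("feature names do not match between train and query")
    if not 1 <= k <= train.n_conformations:
        raise ValueError("k must be in 1..n_train")
    mean, sd = _standardizer(train.values)
    xt = (train.values - mean) / sd
    xq = (query.values - mean) / sd
    # ||q - t||^2 expanded; exhaustive search
    d2 = (
        (xq * xq).sum(axis=1)[:, None]
        + (xt * xt).sum(axis=1)[None, :]
        - 2.0 * (xq @ xt.T)
    )
    nearest = np.argsort(d2, axis=1, kind="stable")[:, :k]
    votes = train.labels[nearest].sum(axis=1)
    return (2 * votes >= k).astype(int)


# ---------------------------------------------------------------------------
# Confusion matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(labels: np.ndarray, predictions: np.ndarray) -> ConfusionCounts:
    """Count TP/TN/FP/FN with class 1 = binding."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    if not (np.isin(labels, (0, 1)).all() and np.isin(predictions, (0, 1)).all()):
        raise ValueError("labels and predictions must be binary 0/1")
    return ConfusionCounts(
        tp=int(np.sum((labels == 1) & (predictions == 1))),
        tn=int(np.sum((labels == 0) & (predictions == 0))),
        fp=int(np.sum((labels == 0) & (predictions == 1))),
        fn=int(np.sum((labels == 1) & (predictions == 0))),
    )


def metrics(counts: ConfusionCounts) -> dict[str, float | None]:
    """Sensitivity, specificity, accuracy, precision; undefined -> None."""

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return {
        "sensitivity": ratio(counts.tp, counts.tp + counts.fn),
        "specificity": ratio(counts.tn, counts.tn + counts.fp),
        "accuracy": ratio(counts.tp + counts.tn, counts.n),
        "precision": ratio(counts.tp, counts.tp + counts.fp),
    }
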