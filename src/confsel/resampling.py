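"""Two-stage rebalancing of severely imbalanced training sets.

Binding conformations are rare (5-28% of an ensemble), so classifiers
trained naively default to "non-binding".  The remedy used here keeps the
training-set *size* fixed while equalising the class masses:

1. a logistic model scores every negative; the negatives the model is most
   confident about are discarded first, keeping the ambiguous boundary
   region populated (LR-guided undersampling);
2. the minority (binding) class is grown with SMOTE: each synthetic binder
   is a random convex combination of a real binder and one of its k nearest
   binding neighbours.

The rebuilt training set has the same number of rows as the original and a
class split within one row of 50/50.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import substream
from .classification import fit_logistic, predict_logistic
from .data_model import DescriptorTable

__all__ = ["ResamplingPlan", "smote", "lr_guided_undersample", "two_stage_resample"]


@dataclass(frozen=True)
class ResamplingPlan:
    smote_k: int = 5
    target_total: int | None = None  # None -> original training size
    undersample_strategy: str = "lr_confidence"  # or "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.smote_k < 1:
            raise ValueError("smote_k must be >= 1")
        if self.undersample_strategy not in ("lr_confidence", "uniform"):
            raise ValueError(f"unknown strategy {self.undersample_strategy!r}")


def smote(
    minority: np.ndarray,
    k: int,
    n_synthetic: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Generate ``n_synthetic`` points by minority-neighbour interpolation.

    Base points cycle through the minority set (uniform coverage); for each,
    one of its k nearest minority neighbours (Euclidean, on features
    standardised over the minority set) is drawn uniformly and the synthetic
    point is x + w (x_nn - x) with w ~ Uniform(0, 1).
    """
    minority = np.asarray(minority, dtype=float)
    n_min = minority.shape[0]
    if n_min < 2:
        raise ValueError("SMOTE needs at least 2 minority samples")
    if not 1 <= k <= n_min - 1:
        raise ValueError("smote_k must be in 1..n_minority-1")
    if n_synthetic == 0:
        return np.empty((0, minority.shape[1]))
    sd = minority.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    z = (minority - minority.mean(axis=0)) / sd
    sq = (z * z).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (z @ z.T)
    np.fill_diagonal(d2, np.inf)
    neighbours = np.argsort(d2, axis=1, kind="stable")[:, :k]

    base = np.arange(n_synthetic) % n_min
    pick = rng.integers(0, k, size=n_synthetic)
    weights = rng.uniform(0.0, 1.0, size=n_synthetic)
    nn = neighbours[base, pick]
    x = minority[base]
    return x + weights[:, None] * (minority[nn] - x)


def lr_guided_undersample(
    train: DescriptorTable,
    class0_probabilities: np.ndarray,
    n_keep: int,
    strategy: str = "lr_confidence",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Indices of the class-0 rows to keep (class-1 rows are never dropped).

    ``lr_confidence`` keeps the ``n_keep`` negatives the logistic model is
    *least* sure about (lowest P(class 0)) — the boundary-region negatives —
    discarding confidently-negative rows first.  ``uniform`` keeps a simple
    random subset.
    """
    neg = np.flatnonzero(train.labels == 0)
    if n_keep <= 0:
        raise ValueError("n_keep must be positive")
    if n_keep > len(neg):
        raise ValueError(f"n_keep={n_keep} exceeds the {len(neg)} class-0 rows")
    p0 = np.asarray(class0_probabilities, dtype=float)
    if p0.shape != (train.n_conformations,):
        raise ValueError("need one class-0 probability per training row")
    if strategy == "lr_confidence":
        order = np.argsort(p0[neg], kind="stable")  # ascending confidence
        return np.sort(neg[order[:n_keep]])
    if rng is None:
        raise ValueError("uniform strategy requires an rng")
    return np.sort(rng.choice(neg, size=n_keep, replace=False))


def two_stage_resample(train: DescriptorTable, plan: ResamplingPlan) -> DescriptorTable:
    """LR-guided undersampling of negatives + SMOTE oversampling of positives.

    The output has exactly ``target_total`` rows (default: the input size)
    split ceil/floor between class 0 and class 1, shuffled.  Synthetic
    binders get fresh conformation ids (``smote####``).
    """
    total = plan.target_total if plan.target_total is not None else train.n_conformations
    if total < 2:
        raise ValueError("target_total must be >= 2")
    labels = train.labels
    n1 = int(labels.sum())
    n0 = train.n_conformations - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("two-stage resampling needs both classes")
    n0_target = -(-total // 2)  # ceil
    n1_target = total // 2

    rng = substream(plan.seed, "resample")

    # stage 1: score negatives with LR, drop the confident ones
    model = fit_logistic(train)
    prob1, _ = predict_logistic(model, train)
    p0 = 1.0 - prob1
    if n0 >= n0_target:
        keep0 = lr_guided_undersample(
            train, p0, n0_target, plan.undersample_strategy, rng
        )
    else:  # negatives already scarcer than the target: keep them all
        keep0 = np.flatnonzero(labels == 0)
        n1_target = total - len(keep0)

    # stage 2: SMOTE the minority up to its target
    pos_idx = np.flatnonzero(labels == 1)
    if n1 >= n1_target:
        keep1 = np.sort(rng.choice(pos_idx, size=n1_target, replace=False))
        synthetic = np.empty((0, train.n_features))
    else:
        keep1 = pos_idx
        if n1 < plan.smote_k + 1:
            raise ValueError(
                f"class 1 has {n1} rows; SMOTE with k={plan.smote_k} needs "
                f"at least {plan.smote_k + 1}"
            )
        synthetic = smote(train.values[pos_idx], plan.smote_k, n1_target - n1, rng)

    real_idx = np.concatenate([keep0, keep1])
    ids = [train.conformation_ids[i] for i in real_idx]
    ids += [f"smote{i:04d}" for i in range(len(synthetic))]
    values = np.vstack([train.values[real_idx], synthetic])
    new_labels = np.concatenate(
        [labels[real_idx], np.ones(len(synthetic), dtype=int)]
    )
    perm = rng.permutation(len(ids))
    return DescriptorTable(
        conformation_ids=tuple(ids[i] for i in perm),
        feature_names=train.feature_names,
        values=values[perm],
        labels=new_labels[perm],
    )
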