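"""Feature ranking and cross-method feature scoring.

Three complementary rankings identify which physico-chemical descriptors
separate binding from non-binding conformations:

* **ANOVA F** — two-group one-way F statistic per descriptor; measures the
  linear class separation of each descriptor's mean.
* **Mutual information** — plug-in MI (in bits) between an equal-frequency
  discretisation of the descriptor and the binary label; captures arbitrary
  (non-linear) dependence.
* **Recurrence entropy (ENTR)** — Shannon entropy of the diagonal-line
  length distribution of each descriptor's recurrence plot along the
  conformation (trajectory) order; measures the complexity of the
  descriptor's temporal dynamics rather than its label association.

A *feature score* in {0,1,2,3} counts how many of the three methods retain
the descriptor in their top-K.  Descriptors with high scores in several
proteins are candidates for protein-independent determinants of
conformational selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import DescriptorTable

__all__ = [
    "FeatureRanking",
    "FeatureScoreTable",
    "anova_f_scores",
    "mutual_information",
    "rqa_entropy",
    "rqa_scores",
    "feature_score_table",
    "select_features",
    "common_features",
]


@dataclass(frozen=True)
class FeatureRanking:
    """Per-feature scores for one method, with deterministic top-K."""

    method: str  # "anova" | "mi" | "rqa"
    feature_names: tuple[str, ...]
    scores: np.ndarray  # higher = more informative
    k: int

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.shape != (len(self.feature_names),):
            raise ValueError("one score per feature required")
        if not np.all(np.isfinite(scores)):
            raise ValueError("scores must be finite")
        if not 1 <= self.k <= len(self.feature_names):
            raise ValueError("k must be in 1..n_features")

    @property
    def ranks(self) -> np.ndarray:
        """1 = best; ties broken by column order (stable sort)."""
        order = np.argsort(-self.scores, kind="stable")
        ranks = np.empty(len(order), dtype=int)
        ranks[order] = np.arange(1, len(order) + 1)
        return ranks

    @property
    def top_k_set(self) -> frozenset[str]:
        order = np.argsort(-self.scores, kind="stable")[: self.k]
        return frozenset(self.feature_names[i] for i in order)


@dataclass(frozen=True)
class FeatureScoreTable:
    feature_names: tuple[str, ...]
    scores: dict[str, int]  # feature -> 0..3

    def selected(self, min_score: int) -> frozenset[str]:
        return frozenset(f for f in self.feature_names if self.scores[f] >= min_score)


def anova_f_scores(table: DescriptorTable, k: int = 10) -> FeatureRanking:
    """Two-group one-way ANOVA F per descriptor.

    F = (between-group SS / 1) / (within-group SS / (n - 2)).  A descriptor
    with zero within-class variance but distinct class means is perfectly
    separating; its (infinite) F is replaced by the largest finite F plus
    one so it ranks first while keeping the score vector finite.
    """
    y = table.labels
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("ANOVA needs >= 2 samples in each class")
    x = table.values
    n = x.shape[0]
    m0 = x[y == 0].mean(axis=0)
    m1 = x[y == 1].mean(axis=0)
    n0, n1 = (y == 0).sum(), (y == 1).sum()
    grand = x.mean(axis=0)
    ss_between = n0 * (m0 - grand) ** 2 + n1 * (m1 - grand) ** 2
    ss_within = ((x[y == 0] - m0) ** 2).sum(axis=0) + ((x[y == 1] - m1) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ss_between / (ss_within / (n - 2))
    # constant-within, distinct-means columns: perfect separators
    separating = (ss_within == 0) & (ss_between > 0)
    constant = (ss_within == 0) & (ss_between == 0)
    f[constant] = 0.0
    if separating.any():
        finite_max = f[np.isfinite(f) & ~separating].max(initial=0.0)
        f[separating] = finite_max + 1.0
    return FeatureRanking("anova", table.feature_names, f, k)


def _equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretise to 0..n_bins-1 by empirical quantiles (duplicate edges merged)."""
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(np.unique(edges), x, side="right")


def binned_mutual_information(x_binned: np.ndarray, y: np.ndarray) -> float:
    """Plug-in MI (bits) between two discrete vectors: I = H(X) - H(X|Y)."""
    xs = np.unique(x_binned)
    ys = np.unique(y)
    n = len(y)
    joint = np.zeros((len(xs), len(ys)))
    for i, xv in enumerate(xs):
        for j, yv in enumerate(ys):
            joint[i, j] = np.sum((x_binned == xv) & (y == yv)) / n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    mi = 0.0
    for i in range(len(xs)):
        for j in range(len(ys)):
            if joint[i, j] > 0:
                mi += joint[i, j] * np.log2(joint[i, j] / (px[i] * py[j]))
    return max(mi, 0.0)


def mutual_information(table: DescriptorTable, n_bins: int = 10, k: int = 10) -> FeatureRanking:
    """MI (bits) between each discretised descriptor and the binding label.

    Continuous descriptors are reduced to ``n_bins`` equal-frequency bins; a
    constant descriptor occupies a single bin and scores 0.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    y = table.labels
    scores = np.array(
        [
            binned_mutual_information(_equal_frequency_bins(table.values[:, j], n_bins), y)
            for j in range(table.n_features)
        ]
    )
    return FeatureRanking("mi", table.feature_names, scores, k)


def rqa_entropy(series: np.ndarray, epsilon: float, l_min: int = 2) -> float:
    """Diagonal-line entropy (ENTR, nats) of a 1-D recurrence plot.

    Two time points recur when their values differ by at most ``epsilon``
    (no embedding: dimension 1, delay 1; the main diagonal is excluded).
    Maximal diagonal runs of recurrences of length >= ``l_min`` in the upper
    triangle form a line-length histogram p(l); ENTR = -sum p(l) ln p(l).
    Returns 0 when no line exists or all lines share one length.
    """
    series = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(series)):
        raise ValueError("series contains non-finite values")
    n = len(series)
    if l_min < 2:
        raise ValueError("l_min must be >= 2")
    if n < l_min:
        raise ValueError("series shorter than l_min")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    recur = np.abs(series[:, None] - series[None, :]) <= epsilon
    lengths = _diagonal_line_lengths(recur, l_min)
    return _line_entropy(lengths)


def _diagonal_line_lengths(recur: np.ndarray, l_min: int) -> np.ndarray:
    """Maximal diagonal run lengths (>= l_min) in the strict upper triangle.

    Dynamic programme along rows: L[i, j] = (L[i-1, j-1] + 1) if recur[i, j];
    a run's length is read off at its last cell (the next diagonal cell is
    off-matrix or non-recurrent).
    """
    n = recur.shape[0]
    upper = np.triu(recur, k=1)
    run = np.zeros(n, dtype=np.int64)
    lengths: list[np.ndarray] = []
    for i in range(n):
        row = upper[i]
        prev = np.concatenate(([0], run[:-1]))  # L[i-1, j-1]
        run = np.where(row, prev + 1, 0)
        if i + 1 < n:
            nxt = np.concatenate((upper[i + 1][1:], [False]))  # recur[i+1, j+1]
            ended = row & ~nxt
        else:
            ended = row.copy()
        ends = run[ended]
        if ends.size:
            lengths.append(ends[ends >= l_min])
    if not lengths:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(lengths)


def _line_entropy(lengths: np.ndarray) -> float:
    if lengths.size == 0:
        return 0.0
    _, counts = np.unique(lengths, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def rqa_scores(
    table: DescriptorTable,
    epsilon_quantile: float = 0.10,
    l_min: int = 2,
    k: int = 10,
) -> FeatureRanking:
    """ENTR per descriptor, thresholded at a per-feature distance quantile.

    Rows are assumed to be in trajectory order.  For each descriptor the
    recurrence threshold is the ``epsilon_quantile``-th quantile of its
    pairwise absolute value differences, so the recurrence rate is roughly
    matched across descriptors of different scales.  Ranking is by
    descending ENTR, ties broken by column order.
    """
    if not 0.0 < epsilon_quantile <= 1.0:
        raise ValueError("epsilon_quantile must lie in (0, 1]")
    scores = np.empty(table.n_features)
    iu = np.triu_indices(table.n_conformations, k=1)  # shared across features
    for j in range(table.n_features):
        x = table.values[:, j]
        dist = x[:, None] - x[None, :]
        np.abs(dist, out=dist)
        offdiag = dist[iu]
        eps = float(np.quantile(offdiag, epsilon_quantile))
        if eps <= 0:  # heavily tied series: smallest positive distance
            positive = offdiag[offdiag > 0]
            eps = float(positive.min()) if positive.size else 1.0
        recur = dist <= eps
        scores[j] = _line_entropy(_diagonal_line_lengths(recur, l_min))
    return FeatureRanking("rqa", table.feature_names, scores, k)


def feature_score_table(
    rankings: tuple[FeatureRanking, FeatureRanking, FeatureRanking]
) -> FeatureScoreTable:
    """Score each feature by how many methods place it in their top-K."""
    names = rankings[0].feature_names
    for r in rankings[1:]:
        if set(r.feature_names) != set(names):
            raise ValueError("rankings must cover identical feature sets")
    tops = [r.top_k_set for r in rankings]
    scores = {f: sum(f in t for t in tops) for f in names}
    return FeatureScoreTable(names, scores)


def select_features(
    table: DescriptorTable, scores: FeatureScoreTable, min_score: int = 3
) -> DescriptorTable:
    """Restrict the table to features with score >= min_score (order kept)."""
    if min_score not in (1, 2, 3):
        raise ValueError("min_score must be 1, 2 or 3")
    keep = [f for f in table.feature_names if scores.scores.get(f, 0) >= min_score]
    if not keep:
        raise ValueError(
            "no feature reaches the requested score; lower min_score or raise K"
        )
    return table.select_features(keep)


def common_features(
    scores_a: FeatureScoreTable, scores_b: FeatureScoreTable, min_score: int = 3
) -> frozenset[str]:
    """Features selected (score >= min_score) in both proteins."""
    return scores_a.selected(min_score) & scores_b.selected(min_score)
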