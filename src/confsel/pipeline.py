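"""End-to-end orchestration of the conformational-selection analysis.

Stage order (one run, one seed):

1. rank all descriptors by ANOVA F, mutual information and recurrence
   entropy on the full dataset;
2. build the feature-score table and, from it, a feature-selected copy of
   the dataset (both the original and the feature-selected *arms* are
   carried through the rest of the pipeline);
3. split 30/70 (stratified) into train and test;
4. fit logistic regression on the training partition (its test predictions
   are recorded, and its training scores drive the undersampling);
5. rebuild the training set with the two-stage resampler (LR-guided
   undersampling + SMOTE);
6. fit KNN and Gaussian NB on the rebalanced training set and predict the
   held-out 70%;
7. pool the test predictions and compute the enrichment grid: 4 energy
   filters x the configured percentages, for each classifier and each arm.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from ._rng import substream
from .classification import (
    ConfusionCounts,
    confusion_counts,
    fit_gaussian_nb,
    fit_logistic,
    knn_predict,
    metrics,
    predict_gaussian_nb,
    predict_logistic,
)
from .data_model import DescriptorTable, EnergyMatrix, RunConfig, split_train_test
from .enrichment import (
    EnrichmentResult,
    baseline_ratio,
    build_pool,
    filter_a,
    filter_b,
    filter_c,
    filter_d,
)
from .feature_selection import (
    FeatureScoreTable,
    anova_f_scores,
    feature_score_table,
    mutual_information,
    rqa_scores,
    select_features,
)
from .resampling import ResamplingPlan, two_stage_resample

__all__ = ["ArmReport", "PipelineReport", "run_pipeline", "summarize"]

CLASSIFIER_TAGS = ("LR+SMOTE-KNN", "LR+SMOTE-GB")
FILTERS = ("A", "B", "C", "D")


@dataclass(frozen=True)
class ClassifierReport:
    tag: str
    confusion: ConfusionCounts
    metrics: dict[str, float | None]
    pool_size: int
    grid: tuple[EnrichmentResult, ...]


@dataclass(frozen=True)
class ArmReport:
    arm: str  # "original" | "feature_selected"
    feature_names: tuple[str, ...]
    n_train: int
    n_test: int
    lr_confusion: ConfusionCounts
    lr_metrics: dict[str, float | None]
    classifiers: tuple[ClassifierReport, ...]


@dataclass(frozen=True)
class PipelineReport:
    config: RunConfig
    baseline: float
    feature_scores: FeatureScoreTable
    arms: tuple[ArmReport, ...]
    notes: tuple[str, ...] = field(default=())

    def arm(self, name: str) -> ArmReport:
        for a in self.arms:
            if a.arm == name:
                return a
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "config": asdict(self.config),
            "baseline": self.baseline,
            "feature_scores": dict(self.feature_scores.scores),
            "notes": list(self.notes),
            "arms": [
                {
                    "arm": a.arm,
                    "feature_names": list(a.feature_names),
                    "n_train": a.n_train,
                    "n_test": a.n_test,
                    "lr_confusion": asdict(a.lr_confusion),
                    "lr_metrics": a.lr_metrics,
                    "classifiers": [
                        {
                            "tag": c.tag,
                            "confusion": asdict(c.confusion),
                            "metrics": c.metrics,
                            "pool_size": c.pool_size,
                            "grid": [asdict(cell) for cell in c.grid],
                        }
                        for c in a.classifiers
                    ],
                }
                for a in self.arms
            ],
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)


def _enrichment_grid(
    tag: str,
    ids: tuple[str, ...],
    true_labels: np.ndarray,
    predictions: np.ndarray,
    energies: EnergyMatrix,
    baseline: float,
    config: RunConfig,
    arm: str,
) -> tuple[int, tuple[EnrichmentResult, ...]]:
    pool = build_pool(ids, true_labels, predictions, energies, config.pool_mode)
    cells: list[EnrichmentResult] = []
    for pct in config.filter_percents:
        if len(pool) == 0:
            for f in FILTERS:
                cells.append(EnrichmentResult(tag, f, pct, 0, baseline, None, None))
            continue
        cells.append(
            EnrichmentResult.from_subset(tag, "A", pct, filter_a(pool, pct), baseline)
        )
        rng_b = substream(config.seed, f"filter_b/{arm}/{tag}/{pct}")
        cells.append(
            EnrichmentResult.from_subset(
                tag, "B", pct,
                filter_b(pool, config.filter_b_y_percent, pct, rng_b), baseline,
            )
        )
        subset_c, cutoff = filter_c(pool, pct)
        cells.append(EnrichmentResult.from_subset(tag, "C", pct, subset_c, baseline))
        cells.append(
            EnrichmentResult.from_subset(
                tag, "D", pct, filter_d(pool, cutoff), baseline
            )
        )
    return len(pool), tuple(cells)


def _run_arm(
    arm: str,
    table: DescriptorTable,
    energies: EnergyMatrix,
    baseline: float,
    config: RunConfig,
) -> ArmReport:
    (train, _), (test, e_test) = split_train_test(table, energies, config.split_spec())

    lr = fit_logistic(train)
    _, lr_pred = predict_logistic(lr, test)
    lr_conf = confusion_counts(test.labels, lr_pred)

    plan = ResamplingPlan(
        smote_k=config.smote_k,
        target_total=None,
        undersample_strategy=config.undersample_strategy,
        seed=config.seed,
    )
    balanced = two_stage_resample(train, plan)

    knn_pred = knn_predict(balanced, test, config.knn_k)
    gnb = fit_gaussian_nb(balanced)
    _, gnb_pred = predict_gaussian_nb(gnb, test)

    classifiers = []
    for tag, pred in ((CLASSIFIER_TAGS[0], knn_pred), (CLASSIFIER_TAGS[1], gnb_pred)):
        conf = confusion_counts(test.labels, pred)
        pool_size, grid = _enrichment_grid(
            tag, test.conformation_ids, test.labels, pred, e_test,
            baseline, config, arm,
        )
        classifiers.append(
            ClassifierReport(tag, conf, metrics(conf), pool_size, grid)
        )

    return ArmReport(
        arm=arm,
        feature_names=table.feature_names,
        n_train=train.n_conformations,
        n_test=test.n_conformations,
        lr_confusion=lr_conf,
        lr_metrics=metrics(lr_conf),
        classifiers=tuple(classifiers),
    )


def run_pipeline(
    descriptors: DescriptorTable,
    energies: EnergyMatrix,
    config: RunConfig | None = None,
) -> PipelineReport:
    """Run every stage on both arms; deterministic for a fixed config+seed."""
    config = config or RunConfig()
    if energies.conformation_ids != descriptors.conformation_ids:
        raise ValueError("energy matrix rows are not aligned with descriptors")

    rankings = (
        anova_f_scores(descriptors, config.k_top),
        mutual_information(descriptors, config.mi_bins, config.k_top),
        rqa_scores(
            descriptors, config.rqa_epsilon_quantile, config.rqa_l_min, config.k_top
        ),
    )
    scores = feature_score_table(rankings)

    baseline = baseline_ratio(descriptors.n_binding, descriptors.n_conformations)

    notes: list[str] = []
    arms = [_run_arm("original", descriptors, energies, baseline, config)]
    try:
        selected = select_features(descriptors, scores, config.min_feature_score)
        arms.append(
            _run_arm("feature_selected", selected, energies, baseline, config)
        )
    except ValueError as exc:
        notes.append(f"feature-selected arm skipped: {exc}")

    return PipelineReport(
        config=config,
        baseline=baseline,
        feature_scores=scores,
        arms=tuple(arms),
        notes=tuple(notes),
    )


def summarize(report: PipelineReport) -> list[dict]:
    """Maxima/minima of the final enrichment ratio per (arm, classifier).

    Ties resolve lexicographically by (filter, percent), matching the
    deterministic reporting convention used throughout.
    """
    rows = []
    for arm in report.arms:
        for clf in arm.classifiers:
            defined = [c for c in clf.grid if c.final is not None]
            if not defined:
                continue
            key = lambda c: (c.filter_id, c.percent_used)  # noqa: E731
            best = max(sorted(defined, key=key), key=lambda c: c.final)
            worst = min(sorted(defined, key=key), key=lambda c: c.final)
            rows.append(
                {
                    "arm": arm.arm,
                    "classifier": clf.tag,
                    "maxima": best.final,
                    "maxima_filter": best.filter_id,
                    "maxima_percent": best.percent_used,
                    "minima": worst.final,
                    "minima_filter": worst.filter_id,
                    "minima_percent": worst.percent_used,
                }
            )
    return rows
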