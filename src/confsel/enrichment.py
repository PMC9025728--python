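"""Energy-filtered enrichment-ratio validation.

A classifier's predictions define a *pool* of candidate binding
conformations.  Because the classifiers output labels rather than scores,
subsets of the pool are selected by docking energy (lower = stronger
binding) through four filters:

* **A** — rank conformations by their best (minimum over ligands) energy and
  keep the lowest X%.
* **B** — draw a random Y% of the pool first, then apply Filter A with X%.
* **C** — flatten all (conformation, ligand) complex energies, keep the
  lowest X% of complexes, and return the distinct conformations among them
  (also exposing the selection's maximum energy as a cutoff).
* **D** — keep every conformation with at least one complex energy at or
  below a cutoff (normally Filter C's).

Enrichment is measured as

    baseline ratio = known binders / all conformations
    ML ratio       = true binders in the filtered subset / subset size
    final ratio    = ML ratio / baseline ratio

so final ratio = 1 means the pipeline does no better than picking
conformations at random, and its ceiling is 1 / baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import EnergyMatrix

__all__ = [
    "PredictionPool",
    "EnrichmentResult",
    "build_pool",
    "baseline_ratio",
    "filter_a",
    "filter_b",
    "filter_c",
    "filter_d",
    "ml_ratio",
    "final_ratio",
]


@dataclass(frozen=True)
class PredictionPool:
    """Conformations entering the enrichment calculation.

    ``predicted_positive`` pools everything the classifier calls binding
    (TP + FP); ``tp_fn_literal`` pools everything truly binding (TP + FN).
    """

    conformation_ids: tuple[str, ...]
    true_labels: np.ndarray
    predicted_labels: np.ndarray
    energies: np.ndarray  # (n_pool, n_ligands)
    pool_mode: str

    def __post_init__(self) -> None:
        n = len(self.conformation_ids)
        if not (
            len(self.true_labels) == len(self.predicted_labels) == n
            and self.energies.shape[0] == n
        ):
            raise ValueError("pool fields must be aligned")

    def __len__(self) -> int:
        return len(self.conformation_ids)

    @property
    def is_tp(self) -> np.ndarray:
        return (np.asarray(self.true_labels) == 1) & (
            np.asarray(self.predicted_labels) == 1
        )

    def subset(self, index: np.ndarray) -> "PredictionPool":
        index = np.asarray(index)
        return PredictionPool(
            conformation_ids=tuple(self.conformation_ids[i] for i in index),
            true_labels=np.asarray(self.true_labels)[index],
            predicted_labels=np.asarray(self.predicted_labels)[index],
            energies=self.energies[index],
            pool_mode=self.pool_mode,
        )


@dataclass(frozen=True)
class EnrichmentResult:
    classifier_tag: str
    filter_id: str  # A | B | C | D
    percent_used: float
    subset_size: int
    baseline: float
    ml: float | None  # None when the subset is empty
    final: float | None

    @staticmethod
    def from_subset(
        classifier_tag: str,
        filter_id: str,
        percent_used: float,
        subset: PredictionPool,
        baseline: float,
    ) -> "EnrichmentResult":
        ml = ml_ratio(subset) if len(subset) else None
        return EnrichmentResult(
            classifier_tag=classifier_tag,
            filter_id=filter_id,
            percent_used=percent_used,
            subset_size=len(subset),
            baseline=baseline,
            ml=ml,
            final=final_ratio(ml, baseline) if ml is not None else None,
        )


def build_pool(
    conformation_ids: tuple[str, ...],
    true_labels: np.ndarray,
    predicted_labels: np.ndarray,
    energies: EnergyMatrix,
    pool_mode: str = "predicted_positive",
) -> PredictionPool:
    """Assemble the enrichment pool from aligned test-set predictions."""
    if energies.conformation_ids != tuple(conformation_ids):
        raise ValueError("energy rows are not aligned with predictions")
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if pool_mode == "predicted_positive":
        member = predicted_labels == 1
    elif pool_mode == "tp_fn_literal":
        member = true_labels == 1
    else:
        raise ValueError(f"unknown pool_mode {pool_mode!r}")
    idx = np.flatnonzero(member)
    return PredictionPool(
        conformation_ids=tuple(conformation_ids[i] for i in idx),
        true_labels=true_labels[idx],
        predicted_labels=predicted_labels[idx],
        energies=energies.energies[idx],
        pool_mode=pool_mode,
    )


def baseline_ratio(n_binding: int, n_total: int) -> float:
    """Fraction of known binders in the whole ensemble (random-pick rate)."""
    if not 0 < n_binding <= n_total:
        raise ValueError("need 0 < n_binding <= n_total")
    return n_binding / n_total


def _count(percent: float, n: int) -> int:
    if not 0.0 < percent <= 100.0:
        raise ValueError("percent must lie in (0, 100]")
    return int(-(-(percent / 100.0 * n) // 1))  # ceil: X > 0 never yields 0


def _lex_order(scores: np.ndarray, ids: tuple[str, ...]) -> np.ndarray:
    """Ascending by score; ties broken by conformation id."""
    return np.lexsort((np.array(ids), scores))


def filter_a(pool: PredictionPool, x_percent: float) -> PredictionPool:
    """Lowest-X% conformations by per-conformation minimum energy."""
    if len(pool) == 0:
        raise ValueError("empty pool")
    n_keep = _count(x_percent, len(pool))
    best = pool.energies.min(axis=1)
    order = _lex_order(best, pool.conformation_ids)
    return pool.subset(np.sort(order[:n_keep]))


def filter_b(
    pool: PredictionPool, y_percent: float, x_percent: float, rng: np.random.Generator
) -> PredictionPool:
    """Random Y% of the pool, then Filter A with X% on that sample."""
    if len(pool) == 0:
        raise ValueError("empty pool")
    n_sample = _count(y_percent, len(pool))
    picked = np.sort(rng.choice(len(pool), size=n_sample, replace=False))
    return filter_a(pool.subset(picked), x_percent)


def filter_c(pool: PredictionPool, x_percent: float) -> tuple[PredictionPool, float]:
    """Lowest-X% of all (conformation, ligand) complexes; returns the distinct
    conformations among them and the selection's maximum energy (the cutoff
    consumed by Filter D)."""
    if len(pool) == 0:
        raise ValueError("empty pool")
    n_conf, n_lig = pool.energies.shape
    flat = pool.energies.ravel()
    n_keep = _count(x_percent, flat.size)
    # complexes tie-broken by (conformation id, ligand index)
    ids_rep = np.repeat(np.array(pool.conformation_ids), n_lig)
    lig_rep = np.tile(np.arange(n_lig), n_conf)
    order = np.lexsort((lig_rep, ids_rep, flat))[:n_keep]
    cutoff = float(flat[order].max())
    rows = np.unique(order // n_lig)
    return pool.subset(rows), cutoff


def filter_d(
    pool: PredictionPool, cutoff_energy: float, strict: bool = False
) -> PredictionPool:
    """Conformations with at least one complex energy at/below the cutoff.

    ``strict=True`` uses strictly-below instead of at-or-below.
    """
    if not np.isfinite(cutoff_energy):
        raise ValueError("cutoff must be finite")
    best = pool.energies.min(axis=1)
    keep = best < cutoff_energy if strict else best <= cutoff_energy
    return pool.subset(np.flatnonzero(keep))


def ml_ratio(subset: PredictionPool) -> float:
    """Fraction of the filtered subset that is truly binding and predicted so."""
    if len(subset) == 0:
        raise ValueError("ML ratio is undefined for an empty subset")
    return float(subset.is_tp.sum()) / len(subset)


def final_ratio(ml: float, baseline: float) -> float:
    """Fold enrichment of the ML-filtered selection over random picking."""
    if baseline <= 0:
        raise ValueError("baseline ratio must be positive")
    return ml / baseline
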