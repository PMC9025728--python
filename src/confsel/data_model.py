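"""Core domain types and CSV persistence.

The unit of analysis is a protein *conformation*: a snapshot of the protein
backbone/side-chain geometry described by a vector of global physico-chemical
descriptors (mass, accessible surface areas, dipole moments, patch areas, ...).
A binary label marks whether the conformation is statistically capable of
binding ligands (class 1 = binding, class 0 = non-binding).  Alongside the
descriptor table, each conformation carries a row of predicted protein:ligand
interaction energies, one per docked ligand; lower energy = stronger binding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from ._rng import substream

__all__ = [
    "DescriptorTable",
    "EnergyMatrix",
    "SplitSpec",
    "RunConfig",
    "read_descriptor_table",
    "write_descriptor_table",
    "read_energy_matrix",
    "write_energy_matrix",
    "split_train_test",
    "load_run_config",
]

# %.17g round-trips IEEE doubles exactly and keeps files diff-able.
_FLOAT_FMT = "%.17g"


@dataclass(frozen=True)
class DescriptorTable:
    """Conformations x named real-valued descriptors, with binding labels."""

    conformation_ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    values: np.ndarray  # (n_conformations, n_features) float64
    labels: np.ndarray  # (n_conformations,) int, 1 = binding

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)
        n, p = values.shape if values.ndim == 2 else (len(values), -1)
        if values.ndim != 2:
            raise ValueError("descriptor values must be a 2-D matrix")
        if p == 0:
            raise ValueError("descriptor table must have at least one feature")
        if n < 2:
            raise ValueError("descriptor table needs at least 2 conformations")
        if len(self.conformation_ids) != n or len(self.feature_names) != p:
            raise ValueError("ids/feature names do not match value matrix shape")
        if len(set(self.conformation_ids)) != n:
            dupes = _first_duplicate(self.conformation_ids)
            raise ValueError(f"duplicate conformation id: {dupes!r}")
        if len(set(self.feature_names)) != p:
            dupes = _first_duplicate(self.feature_names)
            raise ValueError(f"duplicate feature name: {dupes!r}")
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite descriptor value at row {self.conformation_ids[i]!r}, "
                f"column {self.feature_names[j]!r}"
            )
        if labels.shape != (n,) or not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be a 0/1 vector, one per conformation")

    @property
    def n_conformations(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_binding(self) -> int:
        return int(self.labels.sum())

    def select_rows(self, index: np.ndarray) -> "DescriptorTable":
        index = np.asarray(index)
        return DescriptorTable(
            conformation_ids=tuple(self.conformation_ids[i] for i in index),
            feature_names=self.feature_names,
            values=self.values[index],
            labels=self.labels[index],
        )

    def select_features(self, names: Sequence[str]) -> "DescriptorTable":
        name_set = set(names)
        keep = [j for j, f in enumerate(self.feature_names) if f in name_set]
        missing = name_set - set(self.feature_names)
        if missing:
            raise KeyError(f"unknown feature names: {sorted(missing)}")
        return DescriptorTable(
            conformation_ids=self.conformation_ids,
            feature_names=tuple(self.feature_names[j] for j in keep),
            values=self.values[:, keep],
            labels=self.labels,
        )

    def equals(self, other: "DescriptorTable", rtol: float = 1e-12) -> bool:
        return (
            self.conformation_ids == other.conformation_ids
            and self.feature_names == other.feature_names
            and np.array_equal(self.labels, other.labels)
            and np.allclose(self.values, other.values, rtol=rtol, atol=0.0)
        )


@dataclass(frozen=True)
class EnergyMatrix:
    """Conformations x ligands interaction energies; lower = stronger binding."""

    conformation_ids: tuple[str, ...]
    ligand_ids: tuple[str, ...]
    energies: np.ndarray  # (n_conformations, n_ligands) float64

    def __post_init__(self) -> None:
        energies = np.asarray(self.energies, dtype=float)
        object.__setattr__(self, "energies", energies)
        if energies.ndim != 2:
            raise ValueError("energies must be a 2-D matrix")
        n, m = energies.shape
        if len(self.conformation_ids) != n or len(self.ligand_ids) != m:
            raise ValueError("ids do not match energy matrix shape")
        if not np.all(np.isfinite(energies)):
            i, j = np.argwhere(~np.isfinite(energies))[0]
            raise ValueError(
                f"non-finite energy at row {self.conformation_ids[i]!r}, "
                f"ligand {self.ligand_ids[j]!r}"
            )

    def select_rows(self, index: np.ndarray) -> "EnergyMatrix":
        index = np.asarray(index)
        return EnergyMatrix(
            conformation_ids=tuple(self.conformation_ids[i] for i in index),
            ligand_ids=self.ligand_ids,
            energies=self.energies[index],
        )


@dataclass(frozen=True)
class SplitSpec:
    """Train/test partition rule.

    The framework trains on a small fraction (default 30%) and validates on
    the large remainder, mirroring the scarcity of labelled conformations in
    practice.
    """

    train_fraction: float = 0.30
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class RunConfig:
    """Tunable parameters of the full pipeline.

    k_top
        Number of top-ranked features each selection method retains.
    min_feature_score
        Minimum number of methods (out of 3) that must retain a feature for
        it to enter the feature-selected dataset.
    mi_bins
        Equal-frequency bins used to discretise continuous descriptors for
        the mutual-information estimator.
    rqa_epsilon_quantile / rqa_l_min
        Recurrence threshold (as a quantile of within-feature pairwise
        distances) and the minimum diagonal-line length counted by the
        recurrence-entropy measure.
    pool_mode
        Which predictions form the enrichment pool: "predicted_positive"
        (all conformations the classifier calls binding) or "tp_fn_literal"
        (all truly binding conformations, however predicted).
    filter_b_y_percent
        The random pre-sampling percentage Y of the two-parameter energy
        filter (Filter B); the grid percentage supplies X.
    """

    k_top: int = 10
    min_feature_score: int = 3
    smote_k: int = 5
    knn_k: int = 5
    mi_bins: int = 10
    rqa_epsilon_quantile: float = 0.10
    rqa_l_min: int = 2
    pool_mode: str = "predicted_positive"
    filter_percents: tuple[float, ...] = (0.5, 1.0, 5.0, 10.0)
    filter_b_y_percent: float = 50.0
    train_fraction: float = 0.30
    stratified: bool = True
    undersample_strategy: str = "lr_confidence"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("k_top", "smote_k", "knn_k", "mi_bins", "rqa_l_min"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        if not 0 <= self.min_feature_score <= 3:
            raise ValueError("min_feature_score must be in 0..3")
        if not 0.0 < self.rqa_epsilon_quantile <= 1.0:
            raise ValueError("rqa_epsilon_quantile must be in (0, 1]")
        if self.pool_mode not in ("predicted_positive", "tp_fn_literal"):
            raise ValueError(f"unknown pool_mode {self.pool_mode!r}")
        if self.undersample_strategy not in ("lr_confidence", "uniform"):
            raise ValueError(f"unknown undersample_strategy {self.undersample_strategy!r}")
        for pct in tuple(self.filter_percents) + (self.filter_b_y_percent,):
            if not 0.0 < pct <= 100.0:
                raise ValueError("filter percentages must lie in (0, 100]")

    def split_spec(self) -> SplitSpec:
        return SplitSpec(self.train_fraction, self.stratified, self.seed)


def _first_duplicate(items: Sequence[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""


# ---------------------------------------------------------------------------
# CSV persistence
# ---------------------------------------------------------------------------

def read_descriptor_table(path: str | Path, label_column: str = "label") -> DescriptorTable:
    """Read a descriptor CSV (first column = conformation id).

    Raises ``ValueError`` naming the offending column/row for a missing label
    column, a non-numeric or missing descriptor cell, or duplicate ids.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise ValueError("descriptor CSV needs an id column, >=1 feature and a label")
    id_col = df.columns[0]
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in {path}")
    ids = tuple(df[id_col].astype(str))
    feature_names = tuple(c for c in df.columns if c not in (id_col, label_column))
    values = np.empty((len(df), len(feature_names)))
    for j, col in enumerate(feature_names):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(parsed.isna().to_numpy())
        if bad.size:
            raise ValueError(
                f"non-numeric value {df[col].iloc[bad[0]]!r} in column {col!r}, "
                f"row {ids[bad[0]]!r}"
            )
        values[:, j] = parsed.to_numpy(dtype=float)
    labels = pd.to_numeric(df[label_column], errors="coerce")
    if labels.isna().any() or not np.isin(labels.to_numpy(), (0, 1)).all():
        raise ValueError(f"label column {label_column!r} must contain only 0/1")
    return DescriptorTable(ids, feature_names, values, labels.to_numpy(dtype=int))


def write_descriptor_table(table: DescriptorTable, path: str | Path,
                           label_column: str = "label") -> None:
    """Write a descriptor table as CSV; ``read . write`` is the identity.

    Floats are printed with 17 significant digits so the byte output for a
    fixed table is deterministic and values round-trip exactly.
    """
    df = pd.DataFrame(table.values, columns=list(table.feature_names))
    df.insert(0, "conformation_id", list(table.conformation_ids))
    df[label_column] = table.labels
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def read_energy_matrix(path: str | Path) -> EnergyMatrix:
    """Read an energy CSV (first column = conformation id, rest = ligands)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("energy CSV needs an id column and >=1 ligand column")
    id_col = df.columns[0]
    ids = tuple(df[id_col].astype(str))
    ligands = tuple(str(c) for c in df.columns[1:])
    energies = df[df.columns[1:]].to_numpy(dtype=float)
    return EnergyMatrix(ids, ligands, energies)


def write_energy_matrix(matrix: EnergyMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.energies, columns=list(matrix.ligand_ids))
    df.insert(0, "conformation_id", list(matrix.conformation_ids))
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


# ---------------------------------------------------------------------------
# Train/test partitioning
# ---------------------------------------------------------------------------

def split_train_test(
    table: DescriptorTable,
    energies: EnergyMatrix | None,
    spec: SplitSpec,
) -> tuple[tuple[DescriptorTable, EnergyMatrix | None],
           tuple[DescriptorTable, EnergyMatrix | None]]:
    """Partition conformations into disjoint, exhaustive train/test sets.

    With ``stratified=True`` each class contributes ``round(f * n_class)``
    training rows (within 1 sample of the exact fraction), which protects
    low-prevalence datasets from empty-class training partitions.  The energy
    matrix, when given, is partitioned with the identical row selection.
    """
    labels = table.labels
    n = len(labels)
    if energies is not None and energies.conformation_ids != table.conformation_ids:
        raise ValueError("energy matrix rows are not aligned with the descriptor table")
    rng = substream(spec.seed, "split")
    if spec.stratified:
        train_idx_parts = []
        for cls in (0, 1):
            members = np.flatnonzero(labels == cls)
            if len(members) < 2:
                raise ValueError(
                    f"class {cls} has {len(members)} member(s); stratified split "
                    "needs at least 2 per class"
                )
            n_train = int(round(spec.train_fraction * len(members)))
            n_train = min(max(n_train, 1), len(members) - 1)
            train_idx_parts.append(rng.permutation(members)[:n_train])
        train_idx = np.sort(np.concatenate(train_idx_parts))
    else:
        n_train = int(round(spec.train_fraction * n))
        n_train = min(max(n_train, 1), n - 1)
        train_idx = np.sort(rng.permutation(n)[:n_train])
    test_idx = np.setdiff1d(np.arange(n), train_idx)
    train = table.select_rows(train_idx)
    test = table.select_rows(test_idx)
    e_train = energies.select_rows(train_idx) if energies is not None else None
    e_test = energies.select_rows(test_idx) if energies is not None else None
    return (train, e_train), (test, e_test)


# ---------------------------------------------------------------------------
# Configuration files
# ---------------------------------------------------------------------------

def load_run_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML or JSON; unknown keys are rejected."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "filter_percents" in data:
        data["filter_percents"] = tuple(float(x) for x in data["filter_percents"])
    return RunConfig(**data)
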