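"""Synthetic conformational-ensemble generator.

The real descriptor tables behind this analysis (GPCR conformational
ensembles with docked ligand libraries) are not redistributable, so this
module generates datasets with the statistical structure the pipeline
assumes:

* a few *informative* descriptors whose class-conditional means differ by a
  configurable effect size (in feature-SD units), the rest pure noise;
* each descriptor series evolves smoothly along the conformation
  (trajectory) order as an AR(1) process, giving the recurrence-analysis
  stage realistic temporal structure;
* per-conformation x per-ligand interaction energies in which true binders
  sit, on average, ``energy_gap`` energy-SDs below non-binders.

Presets mirror the shapes of three published GPCR benchmarks: an adenosine
receptor set (n=2998, 851 binders, 50 descriptors), a beta-2 adrenoceptor
set (n=2565, 156 binders, 51 descriptors) and a kappa-opioid receptor set
(n=2998, 138 binders, 50 descriptors).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._rng import substream
from .data_model import DescriptorTable, EnergyMatrix

__all__ = ["SyntheticConfig", "preset", "PRESET_NAMES", "generate_dataset"]

PRESET_NAMES = ("ADORA2A_like", "ADRB2_like", "OPRK1_like")


@dataclass(frozen=True)
class SyntheticConfig:
    n_conformations: int = 2998
    n_features: int = 50
    n_informative: int = 8
    prevalence: float = 851 / 2998
    effect_size: float = 1.5  # class-mean shift, units of feature SD
    ar_coefficient: float = 0.8  # lag-1 smoothness along conformation order
    n_ligands: int = 50
    energy_gap: float = 1.0  # binder mean below non-binder mean, energy-SD units
    energy_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conformations < 2:
            raise ValueError("need at least 2 conformations")
        if not 0 < self.n_informative <= self.n_features:
            raise ValueError("n_informative must be in 1..n_features")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.effect_size < 0 or self.energy_gap < 0:
            raise ValueError("effect_size and energy_gap must be >= 0")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must lie in [0, 1)")
        if self.n_ligands < 1:
            raise ValueError("need at least one ligand")
        if self.energy_sd <= 0:
            raise ValueError("energy_sd must be positive")

    @property
    def n_binding(self) -> int:
        return int(round(self.prevalence * self.n_conformations))


def preset(name: str, seed: int = 0) -> SyntheticConfig:
    """Return the configuration emulating one of the three benchmark shapes."""
    shapes = {
        "ADORA2A_like": (2998, 851, 50),
        "ADRB2_like": (2565, 156, 51),
        "OPRK1_like": (2998, 138, 50),
    }
    if name not in shapes:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    n, n_pos, n_feat = shapes[name]
    return SyntheticConfig(
        n_conformations=n, n_features=n_feat, prevalence=n_pos / n, seed=seed
    )


def _ar1(rng: np.random.Generator, n: int, p: int, rho: float) -> np.ndarray:
    """n x p matrix of independent AR(1) columns with unit marginal variance."""
    innov = rng.standard_normal((n, p))
    if rho == 0.0:
        return innov
    out = np.empty((n, p))
    out[0] = innov[0]
    scale = np.sqrt(1.0 - rho * rho)
    for t in range(1, n):
        out[t] = rho * out[t - 1] + scale * innov[t]
    return out


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[DescriptorTable, EnergyMatrix, dict]:
    """Generate (descriptors, energies, ground-truth record).

    Label allocation is deterministic (exactly ``round(prevalence * n)``
    binders) and then shuffled over conformation order; the same seed always
    reproduces the same dataset bit-for-bit.
    """
    n, p = config.n_conformations, config.n_features
    rng_labels = substream(config.seed, "synthetic/labels")
    rng_feat = substream(config.seed, "synthetic/features")
    rng_energy = substream(config.seed, "synthetic/energies")

    labels = np.zeros(n, dtype=int)
    labels[: config.n_binding] = 1
    rng_labels.shuffle(labels)

    values = _ar1(rng_feat, n, p, config.ar_coefficient)
    informative = list(range(config.n_informative))
    values[np.ix_(labels == 1, informative)] += config.effect_size

    base = -7.0  # arbitrary energy origin; only differences matter
    mean = base - config.energy_gap * config.energy_sd * labels
    energies = mean[:, None] + config.energy_sd * rng_energy.standard_normal(
        (n, config.n_ligands)
    )

    width = len(str(n))
    ids = tuple(f"conf{str(i).zfill(width)}" for i in range(n))
    feature_names = tuple(f"f{str(j + 1).zfill(3)}" for j in range(p))
    ligand_ids = tuple(f"lig{str(j + 1).zfill(3)}" for j in range(config.n_ligands))

    table = DescriptorTable(ids, feature_names, values, labels)
    matrix = EnergyMatrix(ids, ligand_ids, energies)
    truth = {
        "informative_features": [feature_names[j] for j in informative],
        "n_binding": int(labels.sum()),
        "config": {k: getattr(config, k) for k in config.__dataclass_fields__},
    }
    return table, matrix, truth


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2) + "\n")
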