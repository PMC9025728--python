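import numpy as np
import pytest

from confsel.data_model import DescriptorTable, EnergyMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


def make_table(values, labels, ids=None, feature_names=None) -> DescriptorTable:
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return DescriptorTable(
        conformation_ids=tuple(ids) if ids else tuple(f"c{i:03d}" for i in range(n)),
        feature_names=tuple(feature_names) if feature_names
        else tuple(f"f{j:03d}" for j in range(p)),
        values=values,
        labels=np.asarray(labels, dtype=int),
    )


def random_table(rng, n=30, p=4, prevalence=0.5) -> DescriptorTable:
    labels = (rng.uniform(size=n) < prevalence).astype(int)
    if labels.sum() == 0:
        labels[0] = 1
    if labels.sum() == n:
        labels[0] = 0
    return make_table(rng.standard_normal((n, p)), labels)


def random_energies(rng, table: DescriptorTable, n_ligands=3) -> EnergyMatrix:
    return EnergyMatrix(
        conformation_ids=table.conformation_ids,
        ligand_ids=tuple(f"lig{j}" for j in range(n_ligands)),
        energies=rng.normal(-7.0, 1.0, size=(table.n_conformations, n_ligands)),
    )
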