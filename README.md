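# confsel

Back-engineering protein conformational selection: which global
physico-chemical properties of a protein conformation make it able to bind
its ligands?

A protein ensemble contains thousands of conformations, of which only a
small minority are "binding" conformations — the ones a ligand selects.
`confsel` is an analysis toolkit for descriptor tables of such ensembles
(one row per conformation, columns = descriptors such as `pro_mass`,
`pro_asa_vdw`, `pro_dipole_moment`, plus a binary binding label and a
matrix of per-ligand docking energies). It is aimed at computational
chemists and ML practitioners studying conformational selection or
building conformation-filtering front-ends for docking campaigns.

The pipeline:

1. **Feature scoring** — rank every descriptor by the two-group ANOVA F
   statistic, by mutual information I(X;Y) = H(X) − H(X|Y) with the label
   (equal-frequency binning, bits), and by the recurrence-plot diagonal
   entropy ENTR = −Σ p(l) ln p(l) of the descriptor's series along the
   ensemble; score each descriptor 0–3 by how many methods keep it in
   their top-K.
2. **Imbalance-aware classification** — stratified 30/70 train/test split;
   logistic regression guides undersampling of the abundant non-binders,
   SMOTE interpolation grows the binders, keeping the training size fixed
   and the classes balanced; KNN and Gaussian naive Bayes predict the
   held-out 70%.
3. **Enrichment-ratio validation** — four docking-energy filters (A–D)
   select subsets of the predicted binders; the final enrichment ratio
   ml_ratio / baseline_ratio measures the fold improvement over picking
   conformations at random (baseline = binders / total).

Because the original ensembles are not redistributable, the package ships
a synthetic-data generator that emulates their statistical shape (three
presets matching the published adenosine-A2a, beta-2-adrenoceptor and
kappa-opioid benchmark dimensions), with planted informative descriptors
and a tunable binder/non-binder energy gap.

## Worked example

```python
from confsel import RunConfig, generate_dataset, preset, run_pipeline, summarize
from dataclasses import replace

config = replace(preset("ADRB2_like"), seed=1)   # 2565 conformations, 156 binders
table, energies, truth = generate_dataset(config)
report = run_pipeline(table, energies, RunConfig(seed=1))

print(f"baseline enrichment ratio: {report.baseline:.4f}")
for row in summarize(report):
    print(f"{row['arm']:>16} {row['classifier']:<13}"
          f" maxima {row['maxima']:5.2f} (Filter {row['maxima_filter']},"
          f" {row['maxima_percent']}%)")
knn = report.arm("original").classifiers[0]
print(f"KNN sensitivity: {knn.metrics['sensitivity']:.3f}")
```

prints

```
baseline enrichment ratio: 0.0608
        original LR+SMOTE-KNN  maxima 16.44 (Filter A, 0.5%)
        original LR+SMOTE-GB   maxima 16.44 (Filter A, 0.5%)
KNN sensitivity: 0.927
```

Reading: a random pick of conformations would contain 6.1% binders; the
best cell of the enrichment grid — the 0.5% lowest-energy conformations
among those the rebalanced KNN predicts to bind — is essentially all true
binders, a 16.4-fold enrichment (the ceiling 1/baseline for this
prevalence). The rebalanced KNN recovers 92.7% of the true binders in the
held-out 70% despite the 6% prevalence.

The same analysis is scriptable from the shell:

```sh
confsel simulate --preset ADRB2_like --seed 1 --out data/
confsel pipeline --descriptors data/descriptors.csv \
                 --energies data/energies.csv --seed 1 --out report/
```

which writes `report/report.json`, `enrichment.csv`, `feature_scores.csv`,
`metrics.csv` and `run.log`.

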