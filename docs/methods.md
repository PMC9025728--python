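# Methods

## Problem

Proteins bind their ligands through conformational selection: within a
large ensemble of apo conformations, only a small subset is statistically
capable of binding. Given a table of global physico-chemical descriptors
per conformation (mass, accessible surface areas, dipole and
hydrophobicity moments, surface-patch areas, ...), a binary binding label,
and a matrix of predicted protein:ligand interaction energies, `confsel`
asks three questions:

1. which descriptors carry the binding signal (feature scoring);
2. how well can binding conformations be predicted under severe class
   imbalance (two-stage resampled classification);
3. how strongly do energy-guided selections of the predictions enrich for
   true binders over random picking (enrichment-ratio framework).

## Feature scoring

Three rankings are computed per descriptor, each retaining its top-K
(default K = 10):

* **ANOVA F** — the two-group one-way F statistic,
  `F = SSB / (SSW / (n - 2))`. A descriptor with zero within-class variance
  and distinct class means is a perfect separator; its infinite F is
  replaced by (largest finite F + 1) so ranking stays finite and it ranks
  first.
* **Mutual information** — the plug-in estimate
  `I(X;Y) = H(X) - H(X|Y)` in bits. Continuous descriptors are reduced to
  equal-frequency bins (default 10); equal-frequency binning makes the
  score invariant under monotone transforms and avoids empty bins. A
  constant descriptor occupies one bin and scores 0.
* **Recurrence entropy (ENTR)** — each descriptor's values, in
  conformation (trajectory) order, define a one-dimensional recurrence
  plot (no embedding: dimension 1, delay 1): points *i*, *j* recur when
  their values differ by at most ε. ENTR is the Shannon entropy (nats) of
  the distribution of maximal diagonal-line lengths ≥ `l_min` (default 2)
  in the strict upper triangle. ε is set per descriptor to the 10th
  percentile of its pairwise absolute differences, which roughly equalises
  recurrence rates across descriptors of very different scales. ENTR
  measures the complexity of a descriptor's dynamics along the ensemble,
  not its label association; how to map recurrence analysis onto a static
  descriptor table is genuinely open, so every choice here (no embedding,
  quantile threshold, descending-ENTR ranking, column-order tie-breaks) is
  a configurable package decision.

The **feature score** of a descriptor is the number of methods (0–3) whose
top-K contains it. Scores from two proteins can be intersected
(`common_features`) to look for protein-independent determinants of
binding. A feature-selected copy of the dataset keeps descriptors with
score ≥ `min_feature_score` (default 3, i.e. the three-way intersection);
when no descriptor qualifies, the feature-selected arm of the pipeline is
skipped and reported as such.

## Classification under imbalance

Binding prevalence in the benchmark shapes is 5–28%, so the training set
(a stratified 30% of the data; the remaining 70% is held out for
validation) is rebalanced before the final classifiers see it:

1. **LR-guided undersampling.** A logistic model (IRLS with L2 ridge 1e-6
   on internally standardised features; step-halving keeps the penalised
   log-likelihood non-decreasing) scores every negative. Negatives are
   discarded most-confident-first, keeping the ambiguous boundary-region
   negatives — discarding boundary negatives instead would leave the
   decision region unconstrained exactly where it matters. A `uniform`
   strategy is available for ablation.
2. **SMOTE.** Each synthetic binder is `x + w(x_nn - x)` with `w ~ U(0,1)`,
   where `x` cycles through the real binders and `x_nn` is drawn uniformly
   from its k = 5 nearest binding neighbours (Euclidean, on
   minority-standardised coordinates; interpolation happens in raw
   coordinates, which preserves the convex-combination contract).

The rebuilt training set has exactly the original number of rows, split
ceil/floor between the classes. KNN (k = 5, Euclidean on train-standardised
features) and Gaussian naive Bayes (raw features, per-class empirical
means/variances with a relative variance floor of 1e-9, log-space
accumulation) are then fitted on it and applied to the held-out 70%.
Every tie — posterior ties, even KNN votes, equal distances — resolves
toward the binding class: the framework is deliberately biased toward
detecting binders, because a missed binder is the costly error here.

## Enrichment-ratio framework

The test-set predictions form a pool; by default the pool is everything
the classifier calls binding (TP ∪ FP). The alternative literal pool of
all truly binding conformations (TP ∪ FN) is available as
`pool_mode="tp_fn_literal"`, but note its final ratio is capped at
1/baseline by construction, which makes the predicted-positive pool the
meaningful default for measuring what a practitioner would gain.

Four energy filters select subsets of the pool (percent-to-count mapping
is by ceiling, so a positive percentage never yields an empty subset; all
energy ties break by conformation id):

* **A** — keep the X% of conformations with the lowest minimum-over-ligands
  energy;
* **B** — draw a seeded uniform Y% of the pool (default Y = 50), then apply
  A with X% to the sample — the grid percentage supplies X;
* **C** — keep the X% lowest of all (conformation, ligand) complex
  energies and return the distinct conformations among them, exposing the
  selection's maximum energy as a cutoff;
* **D** — keep every conformation with at least one complex energy at or
  below a cutoff (C's cutoff in the pipeline grid); "at or below" treats
  an energy equal to the cutoff as binding-strong-enough, with a strict
  mode available.

For each subset: `ml_ratio` = fraction of subset members that are true
positives; `baseline` = binders / total in the full ensemble;
`final = ml / baseline`. The pipeline evaluates the full grid of
4 filters × {0.5, 1, 5, 10}% for both classifiers and both arms, and
reports the grid maxima/minima with lexicographic (filter, percent)
tie-breaking.

## Synthetic ensembles

Real descriptor tables for the benchmark proteins are not
redistributable, so the generator emulates their statistical structure:

* exact class counts (`round(prevalence × n)` binders, shuffled);
* descriptors are unit-variance AR(1) series along conformation order
  (coefficient 0.8 by default) so the recurrence stage sees realistic
  smooth dynamics; `n_informative` of them (default 8) get a class-mean
  shift of `effect_size` SDs (default 1.5);
* energies are Gaussian per (conformation, ligand) with SD 1 around a
  class-dependent mean: binders sit `energy_gap` SDs lower (default 1.0).

Presets mirror the three benchmark shapes: 2998 conformations / 851
binders / 50 descriptors; 2565 / 156 / 51; 2998 / 138 / 50.

What the generator does **not** emulate: realistic descriptor ranges and
units, inter-descriptor covariance, non-Gaussian tails, or any physical
relationship between descriptor values and energies beyond the shared
label. Passing tests therefore demonstrate that the pipeline recovers the
signal structure it assumes, not that real ensembles contain that
structure.

## Numerical and study-size choices

* All randomness flows from one integer seed through named CRC32-keyed
  substreams (split, resample, filter B, generator), so stages are
  independently reproducible and a report is byte-identical per seed.
* CSV persistence prints floats with `%.17g` (exact round-trip,
  deterministic bytes).
* The null-calibration study uses 600 conformations × 30 descriptors × 20
  ligands at 25% prevalence with 200 Monte-Carlo replicates; the
  signal-recovery study uses the full 2565-conformation benchmark shape
  with 10 replicates. These sizes give standard errors comfortably inside
  the asserted bands.
* Logistic defaults: threshold 0.5, ridge 1e-6, max 100 IRLS iterations,
  relative tolerance 1e-8. KNN k = 5, SMOTE k = 5 — conventional values,
  all configurable in `RunConfig`.

## Known limitations

* The recurrence-entropy ranking is label-blind; on data where dynamics
  and binding are unrelated, its top-K is effectively arbitrary, and the
  three-way score-3 intersection is then often empty (the pipeline reports
  the skipped arm rather than failing).
* The enrichment maxima reported on synthetic data routinely saturate the
  1/baseline ceiling at the smallest percentages; real ensembles with
  noisier energies would sit below it.
* Filter B's Y percentage is a package default (50%), as published
  summaries fold both of B's percentages into a single reported column.
* Binary labels only; no probability calibration; descriptor computation
  from structures is out of scope.
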