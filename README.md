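# gafs — genetic-algorithm feature selection for regional FDG-PET classification

`gafs` is a wrapper feature-selection toolkit for diagnostic classification of
dementia syndromes (Alzheimer's disease, behavioral-variant frontotemporal
dementia, primary progressive aphasia, healthy controls) from region-level
FDG-PET uptake tables. Each subject is described by the mean normalized
glucose uptake in the 116 regions of the Automatic Anatomical Labeling (AAL)
atlas; the task is to find the *smallest* subset of regions that classifies
diagnoses as accurately as possible. It is aimed at neuroimaging /
machine-learning researchers working with ROI-level PET features, and ships a
synthetic-cohort generator so the whole pipeline is testable without access to
clinical data.

## The method

Exhaustive wrapper selection over N regions would require testing

    C = Σ_{r=1..N} N! / (r!(N−r)!) = 2^N − 1

feature combinations (≈ 8.3 × 10^34 for N = 116), so the search is performed
by a genetic algorithm over variable-length chromosomes:

* a **chromosome** is a duplicate-free list of region indices, any length in
  [1, N]; the initial population draws both size and genes uniformly;
* **fitness** of a chromosome is the number of correct classifications
  ("hits") of a wrapped classifier — 1-nearest-neighbor or Gaussian naive
  Bayes — under stratified k-fold cross-validation restricted to the
  chromosome's regions (k = 5 for datasets of ≥ 100 subjects, else k = 3);
  the fold partition is drawn once per run, so 0 ≤ fitness ≤ M is comparable
  across all candidates;
* parents are chosen by **double tournament selection** (fitness-tournament
  qualifiers, parsimony final), recombined by **one-point crossover** with
  per-parent cut points, perturbed by single-gene **mutation**, with
  **elitism** and replacement of the worst-fit fraction by fresh random
  individuals each generation; duplicate genes created by recombination are
  repaired from the unused-feature pool;
* defaults are 100 generations × population 128, and experiments average 30
  seeded trials.

Solutions are summarized by the **fitness rate** `100·hits/M` and the
**cutting rate** `100·(N−L)/N` (the share of the feature pool discarded by an
L-region solution), and compared against a PCA baseline: the number of
principal components needed to cover a given fraction of variance.

## Worked example

Simulate an AD-vs-HC cohort with ten hypometabolic regions planted in the AD
class (posterior cingulate, inferior parietal, angular, middle temporal,
precuneus — an AD-like pattern) at 1.5 noise-SD effect size, then run three
seeded GA trials with naive-Bayes fitness:

```yaml
# cohort.yaml
class_counts: {AD: 60, HC: 60}
n_regions: 116
planted:
  AD: [66, 67, 34, 35, 60, 61, 64, 65, 84, 85]
effect_size: 1.5
noise_sd: 0.1
seed: 7
```

```yaml
# exp.yaml
data: cohort.csv
task_name: AD_vs_HC
trials: 3
seed: 1
classifier: {kind: gaussian_nb}
ga: {generations: 50, population_size: 64}
out: results
```

```text
$ gafs simulate --spec cohort.yaml --out cohort.csv
$ gafs run --config exp.yaml
INFO task AD_vs_HC: M=120 subjects, N=116 regions, classes=['AD', 'HC'], config=2036233eabd5afde
INFO trial seed=1: fitness 120/120 (100.00%), 10 features (cutting 91.38%)
INFO trial seed=2: fitness 120/120 (100.00%), 11 features (cutting 90.52%)
INFO trial seed=3: fitness 120/120 (100.00%), 10 features (cutting 91.38%)
```

Each trial found a solution classifying all 120 subjects correctly under
5-fold cross-validation while discarding > 90% of the 116 regions. The
selected regions of trial 1 (from `results/trial_1.json`) are mostly the
planted hypometabolic ones:

```text
['Frontal_Sup_R', 'Cingulum_Post_R', 'Calcarine_L', 'Parietal_Inf_L',
 'Angular_L', 'Angular_R', 'Temporal_Mid_L', 'Temporal_Mid_R',
 'Cerebelum_Crus2_L', 'Vermis_4_5']
```

`results/summary.csv` holds the trial-averaged Table-style row
(mean fitness 120.0, fitness rate 100.0%, mean features 10.33, cutting rate
91.09%). The PCA baseline on the same cohort needs far more dimensions than
the GA keeps features:

```text
$ gafs pca-baseline --data cohort.csv --variance 0.88
56 components cover 88.0% of variance (threshold 88.0%)
```

`gafs validate` applies a frozen selected-region model to an external cohort
(columns matched by region name), and `gafs report` aggregates directories of
trial JSONs into one summary CSV. The same functionality is available as a
library (`gafs.evolve`, `gafs.generate_cohort`, `gafs.external_validate`, …).

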