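# Methods

## Problem and model

The package addresses wrapper feature selection on region-level FDG-PET data:
given M subjects × N = 116 AAL-atlas mean-uptake features and a diagnostic
label per subject, find a small region subset whose wrapped classifier
attains maximal cross-validated accuracy. Feature subsets are encoded as
variable-length, duplicate-free integer chromosomes; the objective is the
cross-validated hit count, an integer in [0, M]. The search is single
objective with systematic tie-breaking toward fewer features; there is no
Pareto/multi-objective machinery.

Uptake values are assumed intensity-normalized upstream (global-mean
scaling during image preprocessing), so no rescaling is applied by default.
`zscore_features` provides optional per-feature standardization for cohorts
whose scaling is unknown; both wrapped classifiers are either
scale-insensitive per feature (naive Bayes) or operate on distances whose
scale the user controls, so the default is "accept values as-is".

## Fitness

* The fold partition is **drawn once per run** (stratified; per-class fold
  occupancies differ by ≤ 1) and reused for every evaluation. This makes
  fitness a deterministic function of the chromosome, directly comparable
  across individuals and generations, and (with elitism) makes the
  best-fitness trace provably non-decreasing. The alternative — re-drawing
  folds per evaluation — turns fitness into a noisy estimate and breaks the
  monotone-trace property; it was rejected for that reason.
* Stratification is used even though plain k-fold would be simpler, because
  clinically realistic tasks contain small control groups (e.g. 17 controls
  against 68 patients) for which unstratified folds can lose a class
  entirely from a training split.
* Fold count: 5 for M ≥ 100, else 3 (configurable threshold). Below six
  subjects no 3-fold split with ≥ 2 training subjects per fold exists, so
  that is the hard floor.
* Classifiers: 1-nearest-neighbor (Euclidean) and Gaussian naive Bayes with
  empirical class priors and per-class per-feature variances floored at
  1e-9 (absolute). Predictions are computed directly on numpy arrays so the
  tie-breaking rules are exact and platform-stable: distance ties resolve to
  the lowest training-row index, KNN vote ties to the class of the single
  nearest neighbor, and naive-Bayes posterior ties to the earlier class in
  sorted label order. A training split containing one class predicts that
  class. scikit-learn's KNeighborsClassifier and GaussianNB serve as
  independent cross-checks in the test suite on tie-free data (where all
  implementations must agree), and explicit-loop oracles verify the hit
  counts on hundreds of random small tables.

## Evolutionary loop

Per generation: evaluate all unevaluated individuals → record the trace
(best fitness and the smallest chromosome among best-fitness individuals) →
replace the worst ⌊frac·size⌋ individuals with fresh random ones (ties:
longer first, then higher index; replacements evaluated immediately) → breed
the next population from elites plus offspring. Elites are the
max(1, ⌊elitism_prop·size⌋) best individuals copied unchanged — the lower
bound of one guarantees the monotone best-fitness invariant for any
population size. Offspring come from double tournament selection, one-point
crossover (probability 0.9), and single-gene mutation (probability 0.1).
The reported solution is the best individual over all generations (maximal
fitness, ties to fewest features).

Design choices where the design was genuinely open:

* **Double tournament selection.** Implemented in the bloat-control sense:
  each parent is the winner of a parsimony final between two
  fitness-tournament qualifiers (size-2 tournaments, fitness ties to fewer
  features then lower index); the smaller qualifier wins the final with
  probability `parsimony_prob` (default 1.0; size ties go to the fitter).
  The alternative reading — two plain fitness tournaments yielding the two
  parents — was implemented first and measured: once cross-validated fitness
  saturates, it exerts no pressure toward small subsets (tie-breaks fire
  only on exact fitness equality), and on planted-signal cohorts the
  selected sets stay 3–6× larger than the planted signal. The parsimony
  final restores the stated objective (maximal accuracy with the minimum
  feature set): candidates must first win on fitness, then parsimony
  decides. Setting `parsimony_prob = 0` recovers the plain reading.
* **Variable-length crossover.** One-point crossover with a cut point drawn
  independently per parent, uniform on [1, L−1] (a length-1 parent
  contributes itself as its first section). Children are
  `first(a)+second(b)` / `first(b)+second(a)`; duplicate genes introduced by
  concatenation are repaired by uniform draws from the features the
  chromosome does not contain at all (surplus dropped only when the pool is
  exhausted); an empty child receives one random feature. Independent cut
  points are the simplest rule that handles unequal lengths and lets
  offspring lengths explore the full range.
* **Initial population.** Chromosome length uniform on [1, N], genes a
  uniform draw without replacement — "all possibilities" with no stated
  distribution.
* **Elitism as a proportion** of the population copied unchanged, rather
  than a per-individual probability.
* **Operator rates** (crossover 0.9, mutation 0.1, elitism 0.05, worst
  elimination 0.10, tournament size 2) are conventional values for
  single-objective GAs of this size; all are exposed in `GAConfig` and in
  experiment YAML files, so any setting is reproducible from its config.

## Synthetic cohorts

The generator emulates the structure that matters to wrapper selection and
nothing more: shared positive baseline uptake (default 1.0), class-specific
hypometabolism as a downward mean shift of `effect_size` noise-SDs in small
planted region sets, and Gaussian noise with marginal SD `noise_sd`
(default 0.1, ~10% of baseline) that is either independent (default
ρ = 0), exchangeably correlated, or block-correlated (a crude lobar
structure). Default class sizes (88/81/68/39) mirror a specialist-clinic
referral mix. Classes may share planted regions to emulate the regional
overlap between clinically similar syndromes, which lowers achievable
cutting rates.

Independent noise is the default because it is the analyzable reference
condition: the generator's null calibration (type-I error of a two-sample
test at nominal level) and the planted-recovery effect-size arithmetic
(a δ-SD mean shift is recovered as a δ-SD sample difference) hold exactly,
and a Gaussian-NB wrapper is correctly specified for it. Real regional
uptake is positively correlated; the exchangeable and block options exist
to probe that regime, with the caveat that naive-Bayes fitness degrades as
ρ grows (the per-region signal is partially shared), so recovery results
under high ρ are expected to be weaker than the iid defaults.

What passing tests on these cohorts do **not** show: robustness to
scanner/site effects, non-Gaussian uptake distributions, label noise from
uncertain clinical diagnoses, or age/sex confounding — none of which the
generator models.

## Reported quantities

* fitness rate = 100·hits/M; cutting rate = 100·(N−L)/N. Both are half-up
  rounded to two decimals **at presentation only**; internal computation is
  full precision. Half-up (not banker's) rounding reproduces report-table
  conventions, e.g. 115.11 mean hits of 127 → 90.64%.
* Multi-trial summaries average fitness, fitness rate and feature count
  arithmetically over seeded trials; the mean cutting rate is computed from
  the mean feature count, which equals the mean of per-trial cutting rates
  because the cutting rate is linear in L.
* Confusion metrics (accuracy, precision, sensitivity, specificity, F1) are
  one-vs-rest per class plus macro averages; zero-denominator ratios report
  0.0 and flag the metric name instead of raising.
* PCA baseline: covariance PCA on mean-centered, unscaled columns (the
  common uptake scale is meaningful); a correlation-mode switch standardizes
  first. The component count for threshold 1.0 equals the rank of the
  centered matrix; near-zero trailing eigenvalues (< 1e-12 relative to the
  leading one) are treated as rank deficiency.

## Problem sizes in the checked examples

The planted-recovery study runs five seeded searches of 50 generations ×
population 64 (Gaussian-NB fitness) on a 120-subject, 116-region cohort with
10 planted regions at 1.5 noise-SD — large enough for the selection pressure
and parsimony dynamics to express themselves, and it completes in tens of
seconds. Oracle-equivalence checks use 200 random tables of M ≤ 30, N ≤ 5,
where explicit-loop classifiers are fast and every disagreement is
inspectable by hand. The operator-invariant fuzz applies 10,000 random
operator applications over a 20-feature pool.

## Known limitations

* Fitness is an in-sample model-selection criterion: the reported
  cross-validated rate of the *selected* subset is optimistically biased
  (selection sees the folds), which is why `external_validate` exists for
  honest assessment on held-out cohorts.
* The exhaustive-search count 2^N − 1 is context, not a guarantee: the GA is
  stochastic and offers no optimality certificate; repeated seeded trials
  and their averages are the intended use.
* Only Euclidean 1-NN-style distances and Gaussian likelihoods are wrapped;
  no SVMs, trees, calibration or nested hyperparameter tuning.
* `combination_count` is exact arbitrary-precision arithmetic and will
  happily return astronomically large integers; JSON serialization of such
  values is the caller's concern.
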