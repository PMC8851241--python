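"""Genetic-algorithm search over variable-length feature subsets.

Candidate solutions ("chromosomes") are duplicate-free ordered lists of region
indices of any length from 1 to the full pool. Fitness is the cross-validated
classifier hit count on the chromosome's columns, evaluated on ONE fold
partition drawn at the start of the run so that fitness values are directly
comparable between individuals and across generations.

Each generation: all unevaluated individuals are scored; the best fitness and
the smallest chromosome among best-fitness individuals are traced; the worst
fraction of the population is replaced by fresh random individuals; then the
next population is bred from elites (copied unchanged) plus offspring produced
by double tournament selection, one-point crossover and point mutation. All
fitness ties — in tournaments, elitism and final reporting — break toward
fewer features, mirroring the goal of maximal accuracy with the minimum
feature set.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigError
from .feature_table import FeatureTable
from .fitness import ClassifierSpec, choose_k, kfold_hits, fitness_rate, stratified_folds
from .metrics_report import cutting_rate

__all__ = [
    "Chromosome",
    "Individual",
    "GAConfig",
    "GenerationTrace",
    "SolutionReport",
    "init_population",
    "random_chromosome",
    "tournament_select",
    "double_tournament_select",
    "one_point_crossover",
    "repair_duplicates",
    "mutate",
    "eliminate_worst",
    "evolve",
]

Chromosome = tuple[int, ...]
"""Ordered duplicate-free feature indices; 1 <= len <= pool size."""


@dataclass
class Individual:
    chromosome: Chromosome
    fitness: int | None = None

    @property
    def n_features(self) -> int:
        return len(self.chromosome)


@dataclass(frozen=True)
class GAConfig:
    """Evolutionary and fitness hyperparameters for one run.

    Defaults follow the study configuration (100 generations, population 128)
    with standard operator rates; ``k_threshold`` is the dataset size at which
    5-fold replaces 3-fold cross-validation.
    """

    generations: int = 100
    population_size: int = 128
    crossover_prob: float = 0.9
    mutation_prob: float = 0.1
    elitism_prop: float = 0.05
    worst_elim_frac: float = 0.10
    tournament_size: int = 2
    parsimony_prob: float = 1.0
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    k_threshold: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generations < 1 or self.population_size < 1:
            raise ConfigError("generations and population_size must be >= 1")
        for name in ("crossover_prob", "mutation_prob"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if not (0.0 <= self.elitism_prop < 1.0) or not (0.0 <= self.worst_elim_frac < 1.0):
            raise ConfigError("elitism_prop and worst_elim_frac must be in [0, 1)")
        if self.elitism_prop + self.worst_elim_frac >= 1.0:
            raise ConfigError("elitism_prop + worst_elim_frac must be < 1")
        if self.tournament_size < 1:
            raise ConfigError("tournament_size must be >= 1")
        if not (0.0 <= self.parsimony_prob <= 1.0):
            raise ConfigError("parsimony_prob must be in [0, 1]")


@dataclass(frozen=True)
class GenerationTrace:
    generation: int
    best_fitness: int
    min_features_of_best: int


@dataclass
class SolutionReport:
    """Final selected subset with its rates, plus the per-generation trace."""

    selected_indices: tuple[int, ...]
    selected_regions: tuple[str, ...]
    fitness: int
    fitness_rate: float
    cutting_rate: float
    n_instances: int
    n_regions: int
    classifier_kind: str
    k_folds: int
    seed: int
    traces: list[GenerationTrace] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["selected_indices"] = list(self.selected_indices)
        d["selected_regions"] = list(self.selected_regions)
        d["traces"] = [dataclasses.asdict(t) for t in self.traces]
        return d


def random_chromosome(n_features: int, rng: np.random.Generator) -> Chromosome:
    """Length uniform on [1, n_features]; genes a uniform draw without replacement."""
    length = int(rng.integers(1, n_features + 1))
    return tuple(int(g) for g in rng.choice(n_features, size=length, replace=False))


def init_population(n_features: int, config: GAConfig, rng: np.random.Generator) -> list[Individual]:
    """Random initial population: sizes and features drawn from all possibilities."""
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    return [Individual(random_chromosome(n_features, rng)) for _ in range(config.population_size)]


def tournament_select(
    population: Sequence[Individual], tournament_size: int, rng: np.random.Generator
) -> Individual:
    """One tournament: sample with replacement, keep the best.

    Two independent calls give the two parents of "double tournament"
    selection. Requires an evaluated population.
    """
    if not population:
        raise ValueError("empty population")
    if any(ind.fitness is None for ind in population):
        raise RuntimeError("tournament over unevaluated individuals")
    idx = rng.integers(0, len(population), size=tournament_size)
    winner = min(
        (int(i) for i in idx),
        key=lambda i: (-population[i].fitness, population[i].n_features, i),
    )
    return population[winner]


def double_tournament_select(
    population: Sequence[Individual],
    tournament_size: int,
    parsimony_prob: float,
    rng: np.random.Generator,
) -> Individual:
    """Double tournament: two fitness-tournament qualifiers, then a parsimony
    final.

    Each qualifier is the winner of an independent fitness tournament
    (:func:`tournament_select`); with probability ``parsimony_prob`` the
    qualifier with FEWER features wins the final (size ties go to the fitter,
    then to the first qualifier), otherwise the larger one does. This is the
    classic bloat-control selection scheme and supplies the steady pressure
    toward small feature subsets that fitness tie-breaking alone cannot:
    candidates must first prove competitive accuracy, then parsimony decides.
    ``parsimony_prob = 0`` recovers a plain fitness tournament pair member.
    """
    a = tournament_select(population, tournament_size, rng)
    b = tournament_select(population, tournament_size, rng)
    small, big = (
        (a, b) if (a.n_features, -a.fitness) <= (b.n_features, -b.fitness) else (b, a)
    )
    return small if rng.random() < parsimony_prob else big


def repair_duplicates(genes: Sequence[int], n_features: int, rng: np.random.Generator) -> Chromosome:
    """Replace repeated genes with randomly drawn unused features.

    Keeps the first occurrence of each gene; each later repeat is replaced by
    a uniform draw from the features the chromosome does not use at all
    (neither earlier nor later in the gene list), so length is preserved
    whenever unused features remain. If the pool is exhausted the surplus
    repeats are dropped and the chromosome shrinks.
    """
    used: set[int] = set(int(g) for g in genes)
    seen: set[int] = set()
    out: list[int] = []
    for g in genes:
        g = int(g)
        if g not in seen:
            seen.add(g)
            out.append(g)
        else:
            unused = [f for f in range(n_features) if f not in used]
            if unused:
                pick = int(unused[rng.integers(0, len(unused))])
                used.add(pick)
                out.append(pick)
            # else: no unused feature left -> drop the surplus copy
    return tuple(out)


def _split_point(length: int, rng: np.random.Generator) -> int:
    # a length-1 parent contributes itself as the "first section"
    return 1 if length == 1 else int(rng.integers(1, length))


def one_point_crossover(
    parent_a: Chromosome, parent_b: Chromosome, rng: np.random.Generator, n_features: int
) -> tuple[Chromosome, Chromosome]:
    """One-point crossover for unequal-length parents.

    A cut point is drawn independently for each parent, uniform over its
    interior; child A takes A's first section and B's second, child B the
    reverse. Duplicate genes introduced by the concatenation are repaired, and
    a child that ends up empty receives a single random feature.
    """
    cut_a = _split_point(len(parent_a), rng)
    cut_b = _split_point(len(parent_b), rng)
    raw_a = parent_a[:cut_a] + parent_b[cut_b:]
    raw_b = parent_b[:cut_b] + parent_a[cut_a:]
    child_a = repair_duplicates(raw_a, n_features, rng)
    child_b = repair_duplicates(raw_b, n_features, rng)
    if not child_a:
        child_a = (int(rng.integers(0, n_features)),)
    if not child_b:
        child_b = (int(rng.integers(0, n_features)),)
    return child_a, child_b


def mutate(
    chromosome: Chromosome, n_features: int, mutation_prob: float, rng: np.random.Generator
) -> Chromosome:
    """With probability ``mutation_prob``, swap one gene for an unused feature.

    Length is preserved; a chromosome already containing every feature has no
    replacement available and is returned unchanged (the random draw is still
    consumed, keeping the stream aligned).
    """
    if rng.random() >= mutation_prob:
        return chromosome
    present = set(chromosome)
    unused = [f for f in range(n_features) if f not in present]
    if not unused:
        return chromosome
    pos = int(rng.integers(0, len(chromosome)))
    new_gene = int(unused[rng.integers(0, len(unused))])
    out = list(chromosome)
    out[pos] = new_gene
    return tuple(out)


def eliminate_worst(
    population: list[Individual], frac: float, n_features: int, rng: np.random.Generator
) -> list[Individual]:
    """Replace the floor(frac * size) worst individuals with fresh random ones.

    "Worst" = lowest fitness; ties eliminate the longer chromosome first, then
    the higher population index. Replacements arrive unevaluated; population
    size is preserved.
    """
    if any(ind.fitness is None for ind in population):
        raise RuntimeError("eliminate_worst requires an evaluated population")
    n_out = int(frac * len(population))
    if n_out == 0:
        return list(population)
    # sort ascending by badness: low fitness first, longer first, higher index first
    order = sorted(
        range(len(population)),
        key=lambda i: (population[i].fitness, -population[i].n_features, -i),
    )
    doomed = set(order[:n_out])
    return [
        Individual(random_chromosome(n_features, rng)) if i in doomed else population[i]
        for i in range(len(population))
    ]


def _elite_count(config: GAConfig) -> int:
    if config.elitism_prop == 0.0:
        return 0
    return max(1, int(config.elitism_prop * config.population_size))


def evolve(
    table: FeatureTable, config: GAConfig, trace_callback=None
) -> tuple[SolutionReport, list[GenerationTrace]]:
    """Run the full evolutionary search on one task table.

    The fold partition is drawn once from the run's seed and reused for every
    fitness evaluation. The report contains the best individual observed over
    ALL generations (max fitness, ties to fewest features) with its region
    names, fitness rate and cutting rate.
    """
    labels = set(table.labels)
    if len(labels) < 2:
        raise ValueError("task table needs at least 2 diagnostic classes")
    rng = np.random.default_rng(config.seed)
    k = choose_k(table.n_subjects, config.k_threshold)
    folds = stratified_folds(table.labels, k, rng)
    n = table.n_regions

    def evaluate(pop: list[Individual]) -> None:
        for ind in pop:
            if ind.fitness is None:
                ind.fitness = kfold_hits(table, ind.chromosome, config.classifier, folds)

    population = init_population(n, config, rng)
    best: Individual | None = None
    traces: list[GenerationTrace] = []
    n_elites = _elite_count(config)

    for gen in range(config.generations):
        assert len(population) == config.population_size
        evaluate(population)
        gen_best = min(population, key=lambda ind: (-ind.fitness, ind.n_features))
        min_len = min(
            ind.n_features for ind in population if ind.fitness == gen_best.fitness
        )
        traces.append(GenerationTrace(gen, int(gen_best.fitness), min_len))
        if trace_callback is not None:
            trace_callback(traces[-1])
        if best is None or (-gen_best.fitness, gen_best.n_features) < (
            -best.fitness,
            best.n_features,
        ):
            best = Individual(gen_best.chromosome, gen_best.fitness)

        if gen == config.generations - 1:
            break

        population = eliminate_worst(population, config.worst_elim_frac, n, rng)
        evaluate(population)

        ranked = sorted(
            range(len(population)),
            key=lambda i: (-population[i].fitness, population[i].n_features, i),
        )
        next_pop: list[Individual] = [
            Individual(population[i].chromosome, population[i].fitness)
            for i in ranked[:n_elites]
        ]
        while len(next_pop) < config.population_size:
            pa = double_tournament_select(
                population, config.tournament_size, config.parsimony_prob, rng
            )
            pb = double_tournament_select(
                population, config.tournament_size, config.parsimony_prob, rng
            )
            if rng.random() < config.crossover_prob:
                ca, cb = one_point_crossover(pa.chromosome, pb.chromosome, rng, n)
            else:
                ca, cb = pa.chromosome, pb.chromosome
            for child in (ca, cb):
                if len(next_pop) >= config.population_size:
                    break
                child = mutate(child, n, config.mutation_prob, rng)
                next_pop.append(Individual(child))
        population = next_pop

    assert best is not None and best.fitness is not None
    report = SolutionReport(
        selected_indices=tuple(sorted(best.chromosome)),
        selected_regions=tuple(table.atlas.names[i] for i in sorted(best.chromosome)),
        fitness=int(best.fitness),
        fitness_rate=fitness_rate(best.fitness, table.n_subjects),
        cutting_rate=cutting_rate(best.n_features, n),
        n_instances=table.n_subjects,
        n_regions=n,
        classifier_kind=config.classifier.kind,
        k_folds=k,
        seed=config.seed,
        traces=traces,
    )
    return report, traces
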