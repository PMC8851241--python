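import json

import numpy as np
import pytest

from gafs.errors import ConfigError
from gafs.fitness import ClassifierSpec, kfold_hits, stratified_folds
from gafs.ga_engine import (
    GAConfig,
    Individual,
    double_tournament_select,
    eliminate_worst,
    evolve,
    init_population,
    mutate,
    one_point_crossover,
    repair_duplicates,
    tournament_select,
)
from gafs.synthetic_cohort import CohortSpec, generate_cohort


def cfg(**kw):
    base = dict(generations=5, population_size=8, seed=0)
    base.update(kw)
    return GAConfig(**base)


class TestConfig:
    def test_elitism_plus_elimination_bound(self):
        with pytest.raises(ConfigError):
            cfg(elitism_prop=0.5, worst_elim_frac=0.5)

    @pytest.mark.parametrize("kw", [
        dict(crossover_prob=1.2), dict(mutation_prob=-0.1),
        dict(tournament_size=0), dict(generations=0), dict(parsimony_prob=2.0),
    ])
    def test_invalid_fields(self, kw):
        with pytest.raises(ConfigError):
            cfg(**kw)


class TestInitPopulation:
    def test_single_feature_pool(self):
        pop = init_population(1, cfg(), np.random.default_rng(0))
        assert all(ind.chromosome == (0,) for ind in pop)

    def test_defaults_shape(self):
        pop = init_population(116, cfg(population_size=128), np.random.default_rng(1))
        assert len(pop) == 128
        for ind in pop:
            assert 1 <= ind.n_features <= 116
            assert len(set(ind.chromosome)) == ind.n_features
            assert ind.fitness is None

    def test_seeded_determinism(self):
        p1 = init_population(20, cfg(), np.random.default_rng(9))
        p2 = init_population(20, cfg(), np.random.default_rng(9))
        assert [i.chromosome for i in p1] == [i.chromosome for i in p2]

    def test_lengths_cover_range(self):
        pop = init_population(10, cfg(population_size=500), np.random.default_rng(2))
        lengths = {ind.n_features for ind in pop}
        assert lengths == set(range(1, 11))


class TestTournament:
    def test_singleton_population(self):
        ind = Individual((0, 1), fitness=3)
        assert tournament_select([ind], 2, np.random.default_rng(0)) is ind

    def test_higher_fitness_wins(self):
        pop = [Individual((0,), 5), Individual((1,), 10)]
        for seed in range(20):
            w = tournament_select(pop, 4, np.random.default_rng(seed))
            assert w.fitness == 10

    def test_tie_breaks_to_fewer_features_all_orderings(self, queued_rng):
        short, long_ = Individual((0, 1, 2), 7), Individual(tuple(range(7)), 7)
        # rig the sample so the tournament contains both contenders, in every
        # draw order and population ordering
        for ordering in ([short, long_], [long_, short]):
            for draw in ([0, 1], [1, 0]):
                w = tournament_select(ordering, 2, queued_rng(integers=draw))
                assert w is short

    def test_unevaluated_population_is_state_error(self):
        with pytest.raises(RuntimeError):
            tournament_select([Individual((0,))], 2, np.random.default_rng(0))

    def test_double_tournament_parsimony_final(self, queued_rng):
        # qualifier 1 = index 0 (4 genes), qualifier 2 = index 1 (1 gene):
        # the parsimony final keeps the smaller when parsimony_prob applies
        pop = [Individual((0, 1, 2, 3), 9), Individual((4,), 8)]
        rng = queued_rng(integers=[0, 0, 1, 1], randoms=[0.0])
        w = double_tournament_select(pop, 2, 1.0, rng)
        assert w.chromosome == (4,)
        # with parsimony disabled the larger (here fitter) qualifier survives
        rng = queued_rng(integers=[0, 0, 1, 1], randoms=[0.99])
        w = double_tournament_select(pop, 2, 0.0, rng)
        assert w.chromosome == (0, 1, 2, 3)


class TestCrossover:
    def test_forced_cut_points(self, queued_rng):
        rng = queued_rng(integers=[2, 1])  # cut a after 2 genes, b after 1
        ca, cb = one_point_crossover((1, 2, 3, 4), (5, 6, 7), rng, n_features=10)
        assert ca == (1, 2, 6, 7)
        assert cb == (5, 3, 4)

    def test_duplicate_from_concatenation_is_repaired(self, queued_rng):
        # a=[2,5] cut 1, b=[9,2] cut 1 -> raw child_a=[2,2]; repair picks index 0
        # of the unused pool for the second 2
        rng = queued_rng(integers=[1, 1, 0, 0])
        ca, cb = one_point_crossover((2, 5), (9, 2), rng, n_features=10)
        assert ca[0] == 2 and len(ca) == 2 and len(set(ca)) == 2 and ca[1] != 2
        assert cb[0] == 9 and len(set(cb)) == len(cb)

    def test_length_one_parents(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            ca, cb = one_point_crossover((3,), (8,), rng, n_features=9)
            assert len(set(ca)) == len(ca) >= 1
            assert len(set(cb)) == len(cb) >= 1

    def test_children_always_valid(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            n = int(rng.integers(2, 12))
            a = tuple(int(x) for x in rng.choice(n, rng.integers(1, n + 1), replace=False))
            b = tuple(int(x) for x in rng.choice(n, rng.integers(1, n + 1), replace=False))
            for child in one_point_crossover(a, b, rng, n):
                assert 1 <= len(child) <= n
                assert len(set(child)) == len(child)
                assert all(0 <= g < n for g in child)


class TestRepairDuplicates:
    def test_duplicate_replaced_by_unused(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            out = repair_duplicates([3, 3, 7], 10, rng)
            assert out[0] == 3 and out[2] == 7
            assert len(out) == 3 and out[1] not in (3, 7)

    def test_duplicate_free_input_unchanged(self):
        assert repair_duplicates([4, 1, 9], 10, np.random.default_rng(0)) == (4, 1, 9)

    def test_exhausted_pool_drops_surplus(self):
        assert repair_duplicates([0, 1, 0, 1], 2, np.random.default_rng(0)) == (0, 1)


class TestMutate:
    def test_zero_probability_is_identity(self):
        assert mutate((1, 2, 3), 10, 0.0, np.random.default_rng(0)) == (1, 2, 3)

    def test_forced_mutation_replaces_one_gene(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            out = mutate((4,), 5, 1.0, rng)
            assert len(out) == 1 and out[0] in {0, 1, 2, 3}

    def test_saturated_chromosome_unchanged(self):
        full = tuple(range(6))
        assert mutate(full, 6, 1.0, np.random.default_rng(0)) == full

    def test_preserves_length_and_uniqueness(self):
        rng = np.random.default_rng(2)
        chrom = (0, 3, 7, 9)
        for _ in range(100):
            chrom = mutate(chrom, 12, 0.8, rng)
            assert len(chrom) == 4 and len(set(chrom)) == 4


class TestEliminateWorst:
    def make_pop(self, fits_lengths):
        return [Individual(tuple(range(l)), f) for f, l in fits_lengths]

    def test_zero_fraction_is_identity(self):
        pop = self.make_pop([(3, 2), (1, 2)])
        assert eliminate_worst(pop, 0.0, 5, np.random.default_rng(0)) == pop

    def test_two_worst_removed(self):
        pop = self.make_pop([(f, 3) for f in [9, 1, 8, 2, 7, 6, 5, 4, 3, 10]])
        out = eliminate_worst(pop, 0.2, 12, np.random.default_rng(0))
        assert len(out) == 10
        survivors = {ind.fitness for ind in out if ind.fitness is not None}
        assert 1 not in survivors and 2 not in survivors
        assert sum(ind.fitness is None for ind in out) == 2

    def test_tie_eliminates_longer_first(self):
        pop = self.make_pop([(5, 5), (5, 9), (8, 1), (9, 1)])
        out = eliminate_worst(pop, 0.25, 12, np.random.default_rng(0))
        kept = [ind for ind in out if ind.fitness is not None]
        assert any(ind.fitness == 5 and ind.n_features == 5 for ind in kept)
        assert not any(ind.fitness == 5 and ind.n_features == 9 for ind in kept)


class TestEvolve:
    @pytest.fixture
    def separable_table(self):
        spec = CohortSpec(
            class_counts={"D": 15, "HC": 15},
            n_regions=8,
            planted={"D": frozenset({3})},
            effect_size=6.0,
            seed=5,
        )
        table, _ = generate_cohort(spec)
        return table

    def test_finds_perfectly_separating_feature(self, separable_table):
        """A single 6-SD-shifted region separates the classes; the search must
        reach the maximal hit count and keep that region."""
        # independent check that feature 3 alone is perfect under CV
        rng = np.random.default_rng(0)
        folds = stratified_folds(separable_table.labels, 3, rng)
        assert kfold_hits(separable_table, [3], ClassifierSpec(kind="knn"), folds) == 30

        config = cfg(generations=15, population_size=16, seed=2)
        report, traces = evolve(separable_table, config)
        assert report.fitness == 30
        assert 3 in report.selected_indices

    def test_seeded_determinism(self, separable_table):
        config = cfg(generations=6, population_size=10, seed=13)
        r1, t1 = evolve(separable_table, config)
        r2, t2 = evolve(separable_table, config)
        assert json.dumps(r1.to_dict()) == json.dumps(r2.to_dict())
        assert t1 == t2

    def test_best_fitness_trace_monotone_with_elitism(self, separable_table):
        for seed in range(5):
            config = cfg(generations=12, population_size=12, seed=seed, elitism_prop=0.1)
            _, traces = evolve(separable_table, config)
            best = [t.best_fitness for t in traces]
            assert all(b2 >= b1 for b1, b2 in zip(best, best[1:]))

    def test_report_rates_consistent(self, separable_table):
        report, _ = evolve(separable_table, cfg(generations=4, seed=1))
        n_sel = len(report.selected_indices)
        assert report.cutting_rate == pytest.approx(round(100 * (8 - n_sel) / 8, 2), abs=0.01)
        assert report.selected_regions == tuple(
            separable_table.atlas.names[i] for i in report.selected_indices
        )
        assert report.k_folds == 3

    def test_single_class_table_rejected(self, table_factory):
        import numpy as np
        t = table_factory(np.ones((10, 2)), ["A"] * 10)
        with pytest.raises(ValueError):
            evolve(t, cfg())
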