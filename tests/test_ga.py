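"""Evolutionary operators and the full calibration loop."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mrmcal import abm, fitness as fit, ga, mrm


def cand(genome, fitness=None, viable=True, bioplausible=False):
    return fit.Candidate(
        genome=np.asarray(genome, dtype=float),
        fitness=fitness,
        viable=viable,
        bioplausible=bioplausible,
    )


class TestConfig:
    def test_defaults_match_study_constants(self):
        cfg = ga.GAConfig()
        assert cfg.tournament_size == 2
        assert cfg.elite_fraction == 0.10
        assert cfg.mutation_base == 0.01
        assert cfg.mutation_increment == 0.002
        assert (cfg.gene_min, cfg.gene_max) == (-2.0, 2.0)

    def test_full_scale_constants(self):
        cfg = ga.GAConfig.full_scale()
        assert cfg.population_size == 1024
        assert cfg.max_generations == 250
        assert cfg.replicates_per_candidate == 50

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ga.GAConfig(population_size=7)
        with pytest.raises(ValueError):
            ga.GAConfig(elite_fraction=1.5)
        with pytest.raises(ValueError):
            ga.GAConfig(tournament_size=1)


class TestInitializePopulation:
    def test_size_bounds_and_mean(self):
        cfg = ga.GAConfig(population_size=256)
        rng = np.random.default_rng(0)
        pop = ga.initialize_population(cfg, 50, rng)
        assert len(pop) == 256
        genes = np.concatenate([c.genome for c in pop])
        assert genes.min() >= -2.0 and genes.max() <= 2.0
        # uniform(-2, 2): mean 0, sd 4/sqrt(12); n = 256*50 draws
        se = (4.0 / np.sqrt(12.0)) / np.sqrt(genes.size)
        assert abs(genes.mean()) < 4 * se


class TestTournament:
    def test_lower_fitness_wins_pair(self):
        pop = [cand([0.0], 3.0), cand([1.0], 5.0)]
        rng = np.random.default_rng(0)
        pool = ga.tournament_select(pop, rng, pool_size=20)
        assert all(c.fitness == 3.0 for c in pool)

    def test_tie_broken_by_seeded_coin_flip(self):
        pop = [cand([0.0], 3.0), cand([1.0], 3.0)]
        pool = ga.tournament_select(pop, np.random.default_rng(1), pool_size=200)
        first = sum(c.genome[0] == 0.0 for c in pool)
        assert 0 < first < 200  # both tied members get picked sometimes
        again = ga.tournament_select(pop, np.random.default_rng(1), pool_size=200)
        assert [c.genome[0] for c in pool] == [c.genome[0] for c in again]

    def test_selection_pressure_lowers_mean_fitness(self):
        rng = np.random.default_rng(2)
        pop = [cand([i], float(f)) for i, f in enumerate(rng.uniform(0, 10, 64))]
        pool = ga.tournament_select(pop, np.random.default_rng(3))
        assert np.mean([c.fitness for c in pool]) <= np.mean(
            [c.fitness for c in pop]
        )

    def test_unevaluated_candidate_rejected(self):
        with pytest.raises(ValueError, match="evaluated"):
            ga.tournament_select([cand([0.0])], np.random.default_rng(0))


class TestElitism:
    @pytest.mark.parametrize("size,expected", [(64, 6), (1024, 102)])
    def test_replacement_count_is_floor(self, size, expected):
        prev = [cand([i], float(i)) for i in range(size)]
        pool = [cand([i], float(i + size)) for i in range(size)]
        out = ga.apply_elitism(pool, prev, 0.10)
        assert len(out) == size
        carried = [c for c in out if c.fitness < size]
        assert len(carried) == expected

    def test_best_previous_is_preserved(self):
        prev = [cand([1.0], 1.0), cand([9.0], 9.0)]
        pool = [cand([5.0], 5.0), cand([7.0], 7.0)]
        out = ga.apply_elitism(pool, prev, 0.5)
        assert min(c.fitness for c in out) == 1.0


class TestCrossover:
    def test_identity_when_beta_one(self):
        class FixedRng:
            def random(self, n=None):
                return np.ones(n) if n is not None else 1.0

        p1, p2 = np.array([1.0, -1.0]), np.array([0.5, 0.5])
        c1, c2 = ga.crossover(p1, p2, FixedRng())
        assert np.array_equal(c1, p1) and np.array_equal(c2, p2)

    def test_midpoint_when_beta_half(self):
        class HalfRng:
            def random(self, n=None):
                return np.full(n, 0.5) if n is not None else 0.5

        p1, p2 = np.array([1.0, -1.0]), np.array([0.0, 1.0])
        c1, c2 = ga.crossover(p1, p2, HalfRng())
        assert np.array_equal(c1, c2)
        assert c1.tolist() == [0.5, 0.0]

    def test_conservation_over_many_matings(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p1 = rng.uniform(-2, 2, 30)
            p2 = rng.uniform(-2, 2, 30)
            c1, c2 = ga.crossover(p1, p2, rng)
            assert np.allclose(c1 + c2, p1 + p2, atol=1e-12)
            assert np.all(c1 >= -2) and np.all(c1 <= 2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lengths"):
            ga.crossover(np.zeros(3), np.zeros(4), np.random.default_rng(0))


class TestMutation:
    def test_schedule_values(self):
        assert ga.mutation_rate(0) == pytest.approx(0.01)
        assert ga.mutation_rate(100) == pytest.approx(0.21)
        assert ga.mutation_rate(1000) == 1.0  # capped

    def test_at_most_one_gene_changes(self):
        rng = np.random.default_rng(0)
        g = np.zeros(20)
        changed_counts = set()
        for _ in range(500):
            out = ga.mutate(g, 200, rng)  # r_m = 0.41
            changed_counts.add(int((out != g).sum()))
        assert changed_counts <= {0, 1}
        assert 1 in changed_counts

    def test_mutated_gene_within_bounds(self):
        rng = np.random.default_rng(1)
        g = np.zeros(5)
        for _ in range(300):
            out = ga.mutate(g, 495, rng)  # r_m capped at 1 -> always mutates
            assert out.min() >= -2.0 and out.max() <= 2.0

    def test_observed_frequency_matches_schedule(self):
        rng = np.random.default_rng(2)
        g = np.zeros(4)
        g_n = 45  # r_m = 0.1
        n = 20000
        hits = sum((ga.mutate(g, g_n, rng) != g).any() for _ in range(n))
        p = ga.mutation_rate(g_n)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 4 * se


class TestDiversity:
    def test_identical_population_zero(self):
        pop = [cand(np.full(10, 0.3), 1.0) for _ in range(5)]
        assert ga.population_diversity(pop).total == 0.0

    def test_antipodal_pair_full_range(self):
        pop = [cand(np.full(432, -2.0), 1.0), cand(np.full(432, 2.0), 2.0)]
        assert ga.population_diversity(pop).total == pytest.approx(4.0 * 432)

    @given(st.integers(2, 12), st.integers(1, 30))
    def test_bounded_by_gene_width_times_length(self, n_pop, n_genes):
        rng = np.random.default_rng(n_pop * 100 + n_genes)
        pop = [cand(rng.uniform(-2, 2, n_genes), 0.0) for _ in range(n_pop)]
        entry = ga.population_diversity(pop)
        assert 0.0 <= entry.total <= 4.0 * n_genes


class TestArchive:
    def test_only_bioplausible_accepted(self):
        archive = ga.EnsembleArchive()
        with pytest.raises(ValueError, match="bioplausible"):
            archive.add(cand([0.0], 1.0, bioplausible=False), 0)

    def test_duplicates_stored_once(self):
        archive = ga.EnsembleArchive()
        c = cand([0.5, -0.5], 1.0, bioplausible=True)
        assert archive.add(c, 0)
        assert not archive.add(c, 3)
        assert len(archive) == 1


def stub_evaluator(targets_best=None):
    """Cheap deterministic evaluation: fitness = mean |gene - 0.5|; a genome
    is bioplausible when its fitness is below 0.95 and nonviable when its
    first gene is below -1.9."""

    def evaluate(genome, seeds):
        f = float(np.abs(genome - 0.5).mean())
        viable = genome[0] >= -1.9
        return fit.Candidate(
            genome=np.asarray(genome, dtype=float),
            fitness=f,
            viable=viable,
            bioplausible=viable and f < 0.95,
        )

    return evaluate


class TestEvolve:
    def make_inputs(self):
        sim_config = abm.SimConfig(
            grid_width=4, grid_height=4, horizon_days=0.5,
        )
        targets = fit.ClinicalTargets(
            cytokines=("TNFa",),
            time_points_hours=np.array([3.0]),
            range_min=np.zeros((1, 1)),
            range_max=np.ones((1, 1)),
            mortality_rate=0.5,
            weights=np.ones(1),
        )
        return targets, abm.InjuryParams.sterile_burn(), sim_config

    def test_loop_determinism_and_monotone_best(self):
        targets, injury, sim_config = self.make_inputs()
        cfg = ga.GAConfig(population_size=16, max_generations=8, root_seed=5,
                          replicates_per_candidate=1)
        runs = [
            ga.evolve(targets, injury, sim_config, cfg, evaluate_fn=stub_evaluator())
            for _ in range(2)
        ]
        a, b = runs
        assert a.best_fitness_trace == b.best_fitness_trace
        assert [d.total for d in a.diversity_trace] == [
            d.total for d in b.diversity_trace
        ]
        assert len(a.archive) == len(b.archive)
        for ma, mb in zip(a.archive, b.archive):
            assert np.array_equal(ma.genome, mb.genome)
        trace = np.array(a.best_fitness_trace)
        assert np.all(np.diff(trace) <= 0)

    def test_best_fitness_improves_with_stub(self):
        targets, injury, sim_config = self.make_inputs()
        cfg = ga.GAConfig(population_size=16, max_generations=12, root_seed=1,
                          replicates_per_candidate=1)
        state = ga.evolve(targets, injury, sim_config, cfg,
                          evaluate_fn=stub_evaluator())
        assert state.best_fitness_trace[-1] < state.best_fitness_trace[0]

    def test_archive_members_are_bioplausible_and_append_only(self):
        targets, injury, sim_config = self.make_inputs()
        cfg = ga.GAConfig(population_size=16, max_generations=12, root_seed=2,
                          replicates_per_candidate=1)
        state = ga.evolve(targets, injury, sim_config, cfg,
                          evaluate_fn=stub_evaluator())
        assert len(state.archive) > 0
        for m in state.archive:
            assert np.abs(m.genome - 0.5).mean() < 0.95

    def test_nonviable_candidates_replaced_by_viable(self):
        targets, injury, sim_config = self.make_inputs()
        cfg = ga.GAConfig(population_size=16, max_generations=3, root_seed=3,
                          replicates_per_candidate=1)
        state = ga.evolve(targets, injury, sim_config, cfg,
                          evaluate_fn=stub_evaluator())
        for c in state.population:
            assert c.viable

    def test_fitness_ceiling_replaces_over_ceiling_candidates(self):
        targets, injury, sim_config = self.make_inputs()
        cfg = ga.GAConfig(population_size=16, max_generations=1, root_seed=6,
                          replicates_per_candidate=1, fitness_ceiling=1.0)
        state = ga.evolve(targets, injury, sim_config, cfg,
                          evaluate_fn=stub_evaluator())
        assert all(c.fitness <= 1.0 for c in state.population)

    def test_all_nonviable_aborts_with_diagnostic(self):
        targets, injury, sim_config = self.make_inputs()
        cfg = ga.GAConfig(population_size=4, max_generations=2, root_seed=4,
                          replicates_per_candidate=1, max_redraws=2)

        def always_nonviable(genome, seeds):
            return fit.Candidate(genome=genome, fitness=1.0, viable=False,
                                 bioplausible=False)

        with pytest.raises(RuntimeError, match="no viable"):
            ga.evolve(targets, injury, sim_config, cfg,
                      evaluate_fn=always_nonviable)
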