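import dataclasses

import numpy as np
import pytest

from frailty_ga import GAConfig, multi_run, run_ga
from frailty_ga.ga_core import (check_termination, crossover, init_population,
                                mutate, replace, select_couples,
                                selection_probabilities)

FAST = GAConfig(population_size=40, init_k_range=(5, 15), max_iterations=8,
                patience=4, seed=2)


class TestConfig:
    def test_printed_bookkeeping(self):
        cfg = GAConfig()
        assert cfg.population_size == 1100
        assert cfg.elite_count == 33
        assert cfg.n_couples == 1067

    def test_yaml_roundtrip(self, tmp_path):
        import yaml
        path = tmp_path / "ga.yaml"
        path.write_text(yaml.safe_dump(FAST.to_dict()))
        assert GAConfig.from_yaml(path) == FAST

    def test_invalid_probabilities(self):
        with pytest.raises(ValueError):
            GAConfig(mutation_prob=1.5)


class TestInitPopulation:
    def test_size_and_band(self):
        pop = init_population(GAConfig(seed=0), n_deficits=109)
        assert pop.shape == (1100, 109)
        counts = pop.sum(axis=1)
        assert counts.min() >= 30 and counts.max() <= 70

    def test_forced_saturation(self):
        cfg = GAConfig(population_size=5, init_k_range=(109, 109), seed=0)
        pop = init_population(cfg, 109)
        assert (pop == 1).all()

    def test_size_distribution_matches_conditioned_coin_flips(self):
        """Included counts follow a binomial(n, 1/2) truncated to the band."""
        cfg = GAConfig(population_size=4000, init_k_range=(30, 70), seed=1)
        counts = init_population(cfg, 109).sum(axis=1)
        # mean of Binomial(109, .5) truncated to [30, 70] is ~54.5
        assert abs(counts.mean() - 54.5) < 0.5

    def test_infeasible_band(self):
        with pytest.raises(ValueError):
            init_population(GAConfig(init_k_range=(30, 70)), n_deficits=50)

    def test_reproducible(self):
        a = init_population(GAConfig(population_size=20, seed=7), 109)
        b = init_population(GAConfig(population_size=20, seed=7), 109)
        np.testing.assert_array_equal(a, b)


class TestSelection:
    def test_uniform_fitness_gives_uniform_probs(self):
        p = selection_probabilities(np.full(8, 0.7)).p
        np.testing.assert_allclose(p, 1 / 8)

    def test_proportionality(self):
        p = selection_probabilities(np.array([0.6, 0.4])).p
        np.testing.assert_allclose(p, [0.6, 0.4])

    def test_normalization(self):
        rng = np.random.default_rng(0)
        p = selection_probabilities(rng.random(500)).p
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_rejects_all_zero_or_negative(self):
        with pytest.raises(ValueError):
            selection_probabilities(np.zeros(4))
        with pytest.raises(ValueError):
            selection_probabilities(np.array([0.5, -0.1]))

    def test_degenerate_roulette(self):
        probs = selection_probabilities(np.array([1.0, 0.0, 0.0]))
        couples = select_couples(probs, 10, np.random.default_rng(0))
        assert (couples == 0).all()

    def test_empirical_frequencies_match_probabilities(self):
        """Selection frequencies over 1e5 draws match p within 3 SE."""
        f = np.array([0.9, 0.6, 0.3, 0.2])
        probs = selection_probabilities(f)
        draws = select_couples(probs, 50_000, np.random.default_rng(1)).ravel()
        n = draws.size
        freq = np.bincount(draws, minlength=4) / n
        se = np.sqrt(probs.p * (1 - probs.p) / n)
        assert np.all(np.abs(freq - probs.p) < 3 * se)


class TestCrossoverMutation:
    def test_identical_parents_idempotent(self):
        p = np.array([1, 0, 1, 1, 0, 1], dtype=np.int8)
        np.testing.assert_array_equal(crossover(p, p, 2, 4), p)

    def test_segment_rule(self):
        p1 = np.ones(6, dtype=np.int8)
        p2 = np.zeros(6, dtype=np.int8)
        np.testing.assert_array_equal(crossover(p1, p2, 2, 4),
                                      [1, 1, 0, 0, 1, 1])

    def test_every_allele_comes_from_a_parent(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            p1 = (rng.random(20) < 0.5).astype(np.int8)
            p2 = (rng.random(20) < 0.5).astype(np.int8)
            c1, c2 = sorted(rng.choice(np.arange(1, 20), 2, replace=False))
            child = crossover(p1, p2, int(c1), int(c2))
            assert np.all((child == p1) | (child == p2))

    def test_invalid_cut_points(self):
        p = np.ones(6, dtype=np.int8)
        with pytest.raises(ValueError):
            crossover(p, p, 4, 2)
        with pytest.raises(ValueError):
            crossover(p, p, 0, 3)

    def test_mutation_prob_zero_is_noop(self):
        c = np.array([1, 0, 1], dtype=np.int8)
        out = mutate(c, 0.0, np.random.default_rng(0))
        np.testing.assert_array_equal(out, c)

    def test_mutation_prob_one_flips_exactly_one(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            c = (rng.random(15) < 0.5).astype(np.int8)
            out = mutate(c, 1.0, rng)
            assert np.sum(out != c) == 1

    def test_mutation_rate_empirical(self):
        """Fraction of children changed at 3% over 1e4 trials within 3 SE."""
        rng = np.random.default_rng(2)
        c = np.ones(10, dtype=np.int8)
        changed = sum(np.any(mutate(c, 0.03, rng) != c) for _ in range(10_000))
        assert 0.02 <= changed / 10_000 <= 0.04


class TestReplacement:
    def test_default_elite_count(self):
        rng = np.random.default_rng(0)
        pop = (rng.random((1100, 109)) < 0.5).astype(np.int8)
        fits = rng.random(1100)
        children = (rng.random((1067, 109)) < 0.5).astype(np.int8)
        nxt = replace(pop, fits, children, 33)
        assert nxt.shape == pop.shape
        # the 33 fittest incumbents survive verbatim
        order = np.argsort(-fits, kind="stable")[:33]
        np.testing.assert_array_equal(nxt[:33], pop[order])

    def test_full_elitism_preserves_population(self):
        pop = np.eye(4, dtype=np.int8)
        fits = np.array([0.1, 0.4, 0.2, 0.3])
        nxt = replace(pop, fits, np.empty((0, 4), dtype=np.int8), 4)
        np.testing.assert_array_equal(np.sort(nxt.sum(axis=1)),
                                      np.sort(pop.sum(axis=1)))

    def test_elite_ties_break_by_lower_index(self):
        pop = np.arange(8, dtype=np.int8).reshape(4, 2) % 2
        fits = np.array([0.5, 0.5, 0.5, 0.5])
        nxt = replace(pop, fits, pop[:2], 2)
        np.testing.assert_array_equal(nxt[:2], pop[:2])

    def test_size_mismatch(self):
        with pytest.raises(ValueError):
            replace(np.zeros((4, 3), dtype=np.int8), np.zeros(4),
                    np.zeros((1, 3), dtype=np.int8), 2)


class TestTermination:
    def test_max_iterations(self):
        cfg = GAConfig(max_iterations=5, patience=7)
        assert check_termination([0.5] * 5, cfg) == "stop_max_iter"

    def test_patience_on_flat_trace(self):
        cfg = GAConfig(max_iterations=150, patience=7)
        trace = [0.5, 0.6] + [0.7] * 8
        assert check_termination(trace, cfg) == "stop_patience"

    def test_short_increasing_trace_continues(self):
        cfg = GAConfig(max_iterations=150, patience=7)
        assert check_termination([0.5, 0.55, 0.6, 0.62, 0.63, 0.64], cfg) == "continue"

    def test_improvement_below_tolerance_counts_as_stall(self):
        cfg = GAConfig(max_iterations=150, patience=3, improvement_tol=1e-3)
        trace = [0.5, 0.7, 0.7001, 0.7002, 0.7003]
        assert check_termination(trace, cfg) == "stop_patience"

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            check_termination([], GAConfig())


@pytest.fixture(scope="module")
def result(medium_cohort):
    return run_ga(medium_cohort, dataclasses.replace(FAST, seed=3))


class TestRunGA:
    def test_best_trace_monotone(self, result):
        best = [rec["best_auc"] for rec in result.trace]
        assert all(b2 >= b1 for b1, b2 in zip(best, best[1:]))

    def test_final_beats_initial(self, result):
        assert result.final_best_fitness >= result.trace[0]["best_auc"]

    def test_converged_by_set(self, result):
        assert result.converged_by in {"stop_max_iter", "stop_patience"}
        assert result.iterations_run == len(result.trace)

    def test_deficit_counts_not_clamped_after_init(self, medium_cohort):
        """The init band binds only at initialization; children may leave it."""
        cfg = GAConfig(population_size=30, init_k_range=(10, 14), max_iterations=25,
                       patience=25, mutation_prob=0.5, seed=6)
        res = run_ga(medium_cohort, cfg)
        ks = [rec["best_deficit_count"] for rec in res.trace]
        assert len(res.trace) >= 2  # ran past initialization
        assert all(k >= 1 for k in ks)

    def test_same_seed_identical_traces(self, medium_cohort):
        cfg = dataclasses.replace(FAST, max_iterations=4, seed=9)
        a = run_ga(medium_cohort, cfg)
        b = run_ga(medium_cohort, cfg)
        assert a.trace == b.trace
        assert a.final_best == b.final_best

    def test_trace_jsonl(self, result):
        import json
        lines = result.trace_jsonl().splitlines()
        assert len(lines) == result.iterations_run
        assert json.loads(lines[0])["iteration"] == 1


class TestMultiRun:
    def test_single_run_is_its_own_best(self, medium_cohort):
        res = multi_run(medium_cohort, dataclasses.replace(FAST, max_iterations=4),
                        n_runs=1)
        assert res.best == res.runs[0].final_best
        assert res.best_run_index == 0

    def test_best_is_argmax_over_runs(self, medium_cohort):
        res = multi_run(medium_cohort, dataclasses.replace(FAST, max_iterations=4),
                        n_runs=3)
        fits = [r.final_best_fitness for r in res.runs]
        assert res.best_fitness == max(fits)
        assert all(r.converged_by for r in res.runs)

    def test_rejects_zero_runs(self, medium_cohort):
        with pytest.raises(ValueError):
            multi_run(medium_cohort, FAST, n_runs=0)
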