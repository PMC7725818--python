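"""Mind evolutionary algorithm: entropy, search width, operators, GA baseline."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import greyresid as gr
from greyresid.bp_network import NetworkConfig, TrainingSample
from greyresid.pemea import (
    GAConfig,
    Individual,
    PEMEAConfig,
    dissimilation,
    init_population,
    similartaxis,
)


def sphere_scorer(target):
    target = np.asarray(target, dtype=float)
    return lambda g: 1.0 / (1.0 + float(np.sum((g - target) ** 2)))


class TestScore:
    def test_known_mse_maps_to_reciprocal(self):
        # a zero-weight logsig net outputs 0.5 everywhere; targets at
        # 0.5 +- sqrt(0.5) give MSE 0.5 and hence fitness 2
        cfg = NetworkConfig(n_in=2, n_hidden=2, n_out=1)
        genome = np.zeros(gr.encoding_length(cfg))
        d = math.sqrt(0.5)
        samples = [
            TrainingSample(x=[0.0, 0.0], d=[0.5 + d]),
            TrainingSample(x=[0.0, 0.0], d=[0.5 - d]),
        ]
        assert gr.make_bp_scorer(samples, cfg)(genome) == pytest.approx(2.0, rel=1e-9)

    def test_perfect_fit_is_capped_finite(self):
        cfg = NetworkConfig(n_in=1, n_hidden=1, n_out=1, output_activation="linear")
        genome = np.zeros(gr.encoding_length(cfg))
        samples = [TrainingSample(x=[1.0], d=[0.0])]
        fitness = gr.make_bp_scorer(samples, cfg)(genome)
        assert np.isfinite(fitness) and fitness == pytest.approx(1e12)

    def test_lower_mse_scores_higher(self):
        cfg = NetworkConfig(n_in=1, n_hidden=1, n_out=1, output_activation="linear")
        samples = [TrainingSample(x=[0.0], d=[0.2])]
        scorer = gr.make_bp_scorer(samples, cfg)
        near = np.array([0.0, 0.0, 0.1, 0.0])  # output bias 0.1
        far = np.array([0.0, 0.0, 0.9, 0.0])
        assert scorer(near) > scorer(far)

    def test_wrong_genome_length_rejected(self):
        cfg = NetworkConfig(n_in=2, n_hidden=2, n_out=1)
        scorer = gr.make_bp_scorer([TrainingSample(x=[0, 0], d=[0.5])], cfg)
        with pytest.raises(ValueError):
            scorer(np.zeros(3))


class TestEntropy:
    def test_single_bin_zero_entropy(self):
        assert gr.population_entropy(np.full(20, 3.3), 10) == 0.0

    def test_uniform_occupancy_attains_log_m(self):
        M = 16
        scores = np.arange(M, dtype=float)
        assert gr.population_entropy(scores, M) == pytest.approx(math.log(M))

    def test_two_even_bins(self):
        assert gr.population_entropy(np.array([0.0, 0.0, 1.0, 1.0]), 2) == pytest.approx(
            math.log(2)
        )

    @settings(derandomize=True, max_examples=40)
    @given(
        st.lists(st.floats(min_value=-100, max_value=100, allow_nan=False),
                 min_size=2, max_size=60),
        st.integers(min_value=1, max_value=20),
    )
    def test_bounds_and_invariances(self, scores, r):
        scores = np.array(scores)
        H = gr.population_entropy(scores, r)
        assert 0.0 <= H <= math.log(r) + 1e-12
        rng = np.random.default_rng(0)
        assert gr.population_entropy(rng.permutation(scores), r) == pytest.approx(H)
        assert gr.population_entropy(3.0 * scores + 7.0, r) == pytest.approx(H)


class TestSigma:
    def test_uniform_entropy_gives_unit_width(self):
        cfg = PEMEAConfig(M=50, init_range=1.0)
        assert gr.sigma_from_entropy(math.log(50), 50, cfg) == pytest.approx(1.0)

    def test_zero_entropy_hits_floor(self):
        cfg = PEMEAConfig(M=50, init_range=0.5, sigma_min=0.01)
        assert gr.sigma_from_entropy(0.0, 50, cfg) == pytest.approx(0.005)

    def test_pinned_value(self):
        cfg = PEMEAConfig(M=100, init_range=1.0)
        assert gr.sigma_from_entropy(2.302585, 100, cfg) == pytest.approx(
            0.707106766907657, rel=1e-9
        )

    def test_small_population_rejected(self):
        with pytest.raises(ValueError):
            gr.sigma_from_entropy(1.0, 1, PEMEAConfig())


class TestSpawn:
    def test_zero_sigma_clones_parent(self):
        parent = Individual(np.array([1.0, -2.0]), 1.0)
        child = gr.spawn_offspring(parent, 0.0, 0)
        np.testing.assert_array_equal(child.genome, parent.genome)

    def test_same_seed_same_child(self):
        parent = Individual(np.array([1.0, -2.0]), 1.0)
        c1 = gr.spawn_offspring(parent, 0.3, 42)
        c2 = gr.spawn_offspring(parent, 0.3, 42)
        np.testing.assert_array_equal(c1.genome, c2.genome)

    def test_offspring_distribution(self):
        parent = Individual(np.zeros(4), 1.0)
        sigma = 0.7
        rng = np.random.default_rng(9)
        draws = np.stack(
            [gr.spawn_offspring(parent, sigma, rng).genome for _ in range(10_000)]
        )
        se_mean = sigma / math.sqrt(draws.shape[0])
        assert np.all(np.abs(draws.mean(axis=0)) < 3 * se_mean)
        sd = draws.std(axis=0)
        se_sd = sigma / math.sqrt(2 * draws.shape[0])
        assert np.all(np.abs(sd - sigma) < 3 * se_sd)


class TestPopulationOperators:
    cfg = PEMEAConfig(genome_length=2, M=40, n_superior=2, n_temporary=2,
                      init_range=4.0, seed=1)

    def test_init_population_structure(self):
        scorer = sphere_scorer([1.0, -2.0])
        state = init_population(self.cfg, scorer)
        assert len(state.subpops) == 4
        assert all(len(sp.members) == self.cfg.subpop_size for sp in state.subpops)
        kinds = [sp.kind for sp in state.subpops]
        assert kinds.count("superior") == 2 and kinds.count("temporary") == 2
        # centers (first members) of superior groups outscore temporary centers
        sup = [sp.members[0].score for sp in state.subpops if sp.kind == "superior"]
        tmp = [sp.members[0].score for sp in state.subpops if sp.kind == "temporary"]
        assert min(sup) >= max(tmp)
        assert state.global_board == sorted(state.global_board, reverse=True)

    def test_init_population_deterministic(self):
        scorer = sphere_scorer([1.0, -2.0])
        s1 = init_population(self.cfg, scorer)
        s2 = init_population(self.cfg, scorer)
        np.testing.assert_array_equal(s1.best_genome, s2.best_genome)
        assert s1.global_board == s2.global_board

    def test_similartaxis_winner_never_degrades(self):
        scorer = sphere_scorer([1.0, -2.0])
        state = init_population(self.cfg, scorer)
        sp = state.subpops[0]
        rng = np.random.default_rng(0)
        new = similartaxis(sp, 0.5, scorer, self.cfg, rng)
        assert new.score >= sp.score
        assert new.local_board[-1] == new.score

    def test_similartaxis_converges_on_1d_toy(self):
        # winner approaches the optimum of 1/(1+(g-3)^2) within 0.05
        scorer = lambda g: 1.0 / (1.0 + float((g[0] - 3.0) ** 2))
        cfg = PEMEAConfig(genome_length=1, M=40, n_superior=2, n_temporary=2,
                          init_range=1.0, maturity_patience=1000, seed=2)
        sp_state = init_population(cfg, scorer)
        sp = sp_state.subpops[0]
        rng = np.random.default_rng(3)
        for _ in range(50):
            sp = similartaxis(sp, 0.3, scorer, cfg, rng)
        assert abs(sp.winner.genome[0] - 3.0) < 0.05

    def test_maturity_after_stalled_rounds(self):
        scorer = lambda g: 1.0  # flat landscape: no improvement possible
        cfg = PEMEAConfig(genome_length=1, M=20, n_superior=1, n_temporary=1,
                          maturity_patience=3, seed=0)
        state = init_population(cfg, scorer)
        sp = state.subpops[0]
        rng = np.random.default_rng(0)
        for _ in range(3):
            assert not sp.mature
            sp = similartaxis(sp, 0.1, scorer, cfg, rng)
        assert sp.mature

    def test_dissimilation_swaps_winning_temporary(self):
        scorer = sphere_scorer([0.0, 0.0])
        state = init_population(self.cfg, scorer)
        # force one temporary group to hold the global optimum
        tmp = next(sp for sp in state.subpops if sp.kind == "temporary")
        tmp.members[0] = Individual(np.array([0.0, 0.0]), scorer(np.zeros(2)))
        worst_sup = min(
            (sp for sp in state.subpops if sp.kind == "superior"), key=lambda s: s.score
        )
        new = dissimilation(state, scorer, self.cfg, np.random.default_rng(0))
        kinds = [sp.kind for sp in new.subpops]
        assert kinds.count("superior") == 2 and kinds.count("temporary") == 2
        assert tmp.kind == "superior" and worst_sup.kind == "temporary"
        assert new.global_board == sorted(new.global_board, reverse=True)


class TestRunPEMEA:
    def test_zero_iterations_returns_initial_best(self):
        scorer = sphere_scorer([1.0, -2.0])
        cfg = PEMEAConfig(genome_length=2, M=30, n_superior=2, n_temporary=2,
                          iterations=0, init_range=4.0, seed=5)
        best, trace = gr.run_pemea(cfg, scorer)
        state = init_population(cfg, scorer)
        assert scorer(best) == pytest.approx(state.best_score)
        assert trace.empty

    def test_recovers_2d_sphere_optimum(self):
        target = np.array([1.0, -2.0])
        cfg = PEMEAConfig(genome_length=2, M=60, n_superior=3, n_temporary=3,
                          iterations=30, init_range=3.0, seed=11)
        best, trace = gr.run_pemea(cfg, sphere_scorer(target))
        assert np.linalg.norm(best - target) < 0.1
        assert (trace["best_score"].diff().dropna() >= 0).all()

    def test_trace_columns_and_width_bounds(self):
        cfg = PEMEAConfig(genome_length=2, M=30, n_superior=2, n_temporary=2,
                          iterations=5, init_range=2.0, seed=0)
        _, trace = gr.run_pemea(cfg, sphere_scorer([0.5, 0.5]))
        assert list(trace.columns) == ["generation", "best_score", "entropy", "sigma"]
        assert (trace["entropy"] >= 0).all()
        assert (trace["entropy"] <= math.log(cfg.bins) + 1e-9).all()
        assert (trace["sigma"] <= cfg.init_range * math.sqrt(
            math.log(cfg.bins) / math.log(cfg.M)) + 1e-9).all()

    def test_beats_random_search_at_equal_budget(self):
        target = np.array([1.0, -2.0])
        pemea_best, random_best = [], []
        for seed in range(5):
            calls = 0
            base = sphere_scorer(target)

            def counting(g):
                nonlocal calls
                calls += 1
                return base(g)

            cfg = PEMEAConfig(genome_length=2, M=60, n_superior=3, n_temporary=3,
                              iterations=15, init_range=3.0, seed=seed)
            best, _ = gr.run_pemea(cfg, counting)
            pemea_best.append(base(best))
            rng = np.random.default_rng(1000 + seed)
            draws = rng.uniform(-3, 3, size=(calls, 2))
            random_best.append(max(base(g) for g in draws))
        assert np.median(pemea_best) > np.median(random_best)


class TestRunGA:
    def test_no_variation_returns_initial_best(self):
        scorer = sphere_scorer([0.5, 0.5])
        cfg = GAConfig(genome_length=2, iterations=0, pop_size=10,
                       p_crossover=0.0, p_mutation=0.0, init_range=2.0, seed=3)
        best, trace = gr.run_ga(cfg, scorer)
        rng = np.random.default_rng(3)
        pop = rng.uniform(-2, 2, size=(10, 2))
        assert scorer(best) == pytest.approx(max(scorer(g) for g in pop))
        assert len(trace) == 1

    def test_elitism_makes_best_nondecreasing(self):
        cfg = GAConfig(genome_length=2, iterations=200, pop_size=10,
                       init_range=3.0, seed=4)
        _, trace = gr.run_ga(cfg, sphere_scorer([1.0, -2.0]))
        diffs = trace["best_score"].diff().dropna()
        assert (diffs >= 0).all()
        assert trace["best_score"].iloc[-1] >= trace["best_score"].iloc[0]

    def test_same_seed_identical_trajectory(self):
        cfg = GAConfig(genome_length=2, iterations=30, pop_size=8, seed=9)
        b1, t1 = gr.run_ga(cfg, sphere_scorer([0.0, 1.0]))
        b2, t2 = gr.run_ga(cfg, sphere_scorer([0.0, 1.0]))
        np.testing.assert_array_equal(b1, b2)
        assert t1.equals(t2)

    def test_probability_validation(self):
        with pytest.raises(ValueError):
            GAConfig(p_crossover=1.5)
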