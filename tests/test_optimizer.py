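"""Search-engine tests: encoding, DE operators, elitism, determinism,
refinement, and a small end-to-end convergence check."""

import numpy as np
import pytest

import tdss
from tdss.dynamics import SeriesBlock, TDSSGeneModel, TimeSeriesSet
from tdss.optimizer import (
    GeneOptimizer,
    TDEConfig,
    InferredNetwork,
    _prepare,
    crossover,
    de_mutant,
    decode,
    encode,
    infer_gene,
    select_best,
    trig_mutant,
)


class TestEncoding:
    def _model(self):
        return TDSSGeneModel(
            2, 4.0, 9.0,
            [0.0, 1.5, 0.0, -2.0, 0.0],
            [0.0, 0.0, 2.0, 0.0, 0.0],
            [0.0, 1.3, 0.0, 0.6, 0.0],
            [0.0, 0.0, 2.1, 0.0, 0.0],
        )

    def test_round_trip_and_length(self):
        m = self._model()
        v = encode(m)
        assert v.size == 22  # 4N + 2 for N = 5
        back = decode(v, 2, tau_max=3.0)
        assert back.alpha_i == m.alpha_i and back.beta_i == m.beta_i
        assert np.array_equal(back.g_row, m.g_row)
        assert np.allclose(back.taug_row, m.taug_row)

    def test_delay_snapping_and_structural_zero(self):
        v = encode(self._model())
        v[2 + 10 + 1] = 1.34  # taug slot
        v[2 + 1] = 0.05  # below the skeletalising threshold
        back = decode(v, 2, tau_max=3.0)
        assert back.taug_row[1] == pytest.approx(1.3)
        assert back.g_row[1] == 0.0

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            decode(np.zeros(21), 0, 3.0)


class TestDEOperators:
    def test_rand1_examples(self):
        assert np.allclose(de_mutant([0.0], [2.0], [1.0], 0.5), [0.5])
        r = np.array([1.0, 2.0])
        assert np.allclose(de_mutant(r, r, r, 0.5), r)

    def test_rand1_scale_equivariance(self, rng):
        r1, r2, r3 = rng.normal(size=(3, 6))
        a = 3.7
        assert np.allclose(
            de_mutant(a * r1, a * r2, a * r3, 0.5), a * de_mutant(r1, r2, r3, 0.5)
        )

    def test_trig_centroid_cases(self):
        r1, r2, r3 = np.array([1.0]), np.array([2.0]), np.array([6.0])
        assert np.allclose(trig_mutant(r1, r2, r3, 1.0, 1.0, 1.0), [3.0])
        same = np.array([4.0])
        assert np.allclose(trig_mutant(same, same, same, 1.0, 5.0, 2.0), same)
        assert np.allclose(trig_mutant(r1, r2, r3, 0.0, 0.0, 0.0), [3.0])

    def test_trig_hand_evaluation(self):
        v = trig_mutant([1.0], [0.0], [0.0], 1.0, 1.0, 2.0)
        assert np.allclose(v, [7.0 / 12.0])

    def test_crossover_extremes_and_determinism(self):
        target = np.zeros(10)
        mutant = np.ones(10)
        rng = np.random.default_rng(5)
        assert np.array_equal(crossover(target, mutant, 1.0, rng), mutant)
        trial = crossover(target, mutant, 0.0, np.random.default_rng(5))
        assert trial.sum() == 1.0  # exactly the forced component
        a = crossover(target, mutant, 0.5, np.random.default_rng(9))
        b = crossover(target, mutant, 0.5, np.random.default_rng(9))
        assert np.array_equal(a, b)


@pytest.fixture(scope="module")
def small_problem():
    """One decaying gene driven by a known regulator profile."""
    net = tdss.network_5gene("conf1")
    data = tdss.generate_data(net, M=2, T=15, seed=1)
    cfg = TDEConfig(pop_size=20, phase1_generations=60, mra_generations=10, n_e=10, seed=0)
    grids, lags, signs = _prepare(data, cfg)
    return net, data, cfg, grids, lags, signs


class TestSearchDynamics:
    def test_elitist_best_never_worsens(self, small_problem):
        net, data, cfg, grids, lags, signs = small_problem
        opt = GeneOptimizer(1, grids, cfg, np.random.default_rng(3), lags[1], signs[1])
        state = opt.initial_state()
        best = state.total.min()
        for _ in range(30):
            opt.tde_generation(state)
            now = state.total.min()
            assert now <= best + 1e-12
            best = now

    def test_seed_determinism(self, small_problem):
        net, data, cfg, grids, lags, signs = small_problem
        runs = []
        for _ in range(2):
            opt = GeneOptimizer(0, grids, cfg, np.random.default_rng(11), lags[0], signs[0])
            state = opt.initial_state()
            for _ in range(15):
                opt.tde_generation(state)
            runs.append(state.pop.copy())
        assert np.array_equal(runs[0], runs[1])

    def test_warm_up_reseeds_half(self, small_problem):
        net, data, cfg, grids, lags, signs = small_problem
        opt = GeneOptimizer(2, grids, cfg, np.random.default_rng(4), lags[2], signs[2])
        state = opt.initial_state()
        order = np.argsort(state.total, kind="stable")
        survivors = state.pop[order[: 10]].copy()
        opt.end_warm_up(state)
        assert state.warm_up_done
        # the previous top half is still in the population, untouched
        still_there = sum(
            any(np.array_equal(s, p) for p in state.pop) for s in survivors
        )
        assert still_there == 10

    def test_frozen_slots_stay_zero_through_refinement(self, small_problem):
        net, data, cfg, grids, lags, signs = small_problem
        opt = GeneOptimizer(3, grids, cfg, np.random.default_rng(6), lags[3], signs[3])
        state = opt.initial_state()
        state.frozen[2:5] = True
        state.pop[:, 2:5] = 0.0
        for _ in range(20):
            opt.tde_generation(state)
        assert np.all(state.pop[:, 2:5] == 0.0)

    def test_single_gene_convergence(self):
        # pure self-decay profile: best SRE drops below 1e-2 quickly
        t = np.arange(15, dtype=float)
        vals = np.column_stack([2.0 * np.exp(-0.3 * t) + 0.05, np.full(15, 1.0) + 0.001 * t])
        data = TimeSeriesSet([SeriesBlock(t, vals)])
        cfg = TDEConfig(pop_size=20, phase1_generations=200, mra_generations=0, n_e=10,
                        seed=1, tau_max=2.0)
        grids, lags, signs = _prepare(data, cfg)
        opt = GeneOptimizer(0, grids, cfg, np.random.default_rng(2), lags[0], signs[0])
        state = opt.initial_state()
        for _ in range(200):
            opt.tde_generation(state)
        assert state.sre.min() < 1e-2


class TestNetworkAssembly:
    def test_infer_gene_zero_budget_returns_initial_best(self, small_problem):
        net, data, cfg, grids, lags, signs = small_problem
        from dataclasses import replace
        tiny = replace(cfg, phase1_generations=0, mra_generations=0, n_e=1)
        m = infer_gene(0, data, tiny)
        assert isinstance(m, TDSSGeneModel) and m.gene_index == 0

    def test_infer_network_is_deterministic(self, small_problem):
        net, data, cfg, grids, lags, signs = small_problem
        from dataclasses import replace
        tiny = replace(cfg, pop_size=10, phase1_generations=5, mra_generations=0, n_e=2)
        a = tdss.infer_network(data, tiny)
        b = tdss.infer_network(data, tiny)
        assert np.array_equal(a.kinetic_tensor(), b.kinetic_tensor())
        assert np.array_equal(a.delay_tensor(), b.delay_tensor())

    def test_select_best_prefers_lower_criterion(self):
        cfg = TDEConfig()
        sparse = TDSSGeneModel(0, 1, 1, np.array([1.0, 0.0]), np.array([0.0, 0.0]),
                               np.zeros(2), np.zeros(2))
        dense = TDSSGeneModel(0, 1, 1, np.array([1.0, 1.0]), np.array([1.0, 1.0]),
                              np.zeros(2), np.zeros(2))
        good = InferredNetwork([sparse, sparse], cfg, np.array([1e-6, 1e-6]))
        bad = InferredNetwork([dense, dense], cfg, np.array([1e-2, 1e-2]))
        best = select_best([bad, good])
        assert np.array_equal(best.models[0].g_row, sparse.g_row)
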