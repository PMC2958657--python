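"""Cost function and genetic-algorithm identification."""

import numpy as np
import pandas as pd
import pytest

from quiflux.fit import (INFEASIBLE_COST, CostBlock, CostSpec, FitContext,
                         GaConfig, collect_consistent_solutions,
                         default_cost_spec, evaluate_cost, run_ga)
from quiflux.network import FluxParameterSet
from quiflux.synthetic import (ZERO_NOISE, simulate_dataset,
                               simulate_toy_dataset)

LABELING_ONLY = CostSpec((CostBlock("labeling_dynamics"),))


@pytest.fixture()
def toy_data(toy_net, toy_truth):
    return simulate_toy_dataset(toy_truth, toy_net)


def _toy_context(toy_net, toy_data, toy_truth, genes=("f1", "pool:P")):
    return FitContext(net=toy_net, data=toy_data, spec=LABELING_ONLY,
                      base=toy_truth, genes=genes)


class TestCost:
    def test_noise_free_self_consistency(self, toy_net, toy_truth, toy_data):
        spec = CostSpec((CostBlock("labeling_dynamics"),
                         CostBlock("steady_state_labeling"),
                         CostBlock("pool_sizes"), CostBlock("uptake_rates")))
        assert evaluate_cost(toy_truth, toy_data, spec, toy_net) \
            == pytest.approx(1.0, abs=1e-6)

    def test_unit_residual_single_observation_costs_two(self, toy_net,
                                                        toy_truth, toy_data):
        """One observation off by exactly one sigma in a weight-1 block."""
        data = toy_data
        data = type(data)(**{**data.__dict__,
                             "rates": {"A": 0.075}, "rate_sd": {"A": 0.025}})
        spec = CostSpec((CostBlock("uptake_rates"),))
        # params A = 0.05, observed 0.075, sigma = 0.025 -> residual = 1
        assert evaluate_cost(toy_truth, data, spec, toy_net) \
            == pytest.approx(2.0, abs=1e-9)

    def test_three_observation_hand_computation(self, toy_net, toy_truth,
                                                toy_data):
        """Pool block with three observations and printed residuals."""
        data = type(toy_data)(**{
            **toy_data.__dict__,
            "pool_sizes": pd.Series({"P": 0.36, "Q": 0.10}),
            "pool_sd": pd.Series({"P": 0.03, "Q": 0.05}),
            "rates": {"A": 0.05}, "rate_sd": {"A": 0.01}})
        spec = CostSpec((CostBlock("pool_sizes"), CostBlock("uptake_rates")))
        # residuals: (0.3-0.36)/0.03 = -2; (0.15-0.10)/0.05 = 1; rates: 0
        expected = 1.0 + np.mean([4.0, 1.0]) + 0.0
        assert evaluate_cost(toy_truth, data, spec, toy_net) \
            == pytest.approx(expected, abs=1e-9)

    def test_infeasible_candidate_gets_sentinel(self, net, presets):
        p = presets["CI14"].params
        ds = simulate_dataset(presets["CI14"], noise=ZERO_NOISE, seed=3, net=net)
        bad = p.updated(F1=10.0)     # exceeds glucose uptake: drain < 0
        assert evaluate_cost(bad, ds, LABELING_ONLY, net) == INFEASIBLE_COST

    def test_block_weights_scale_contributions(self, toy_net, toy_truth,
                                               toy_data):
        data = type(toy_data)(**{**toy_data.__dict__,
                                 "rates": {"A": 0.075}, "rate_sd": {"A": 0.025}})
        w2 = CostSpec((CostBlock("uptake_rates", weight=2.0),))
        assert evaluate_cost(toy_truth, data, w2, toy_net) \
            == pytest.approx(3.0, abs=1e-9)

    def test_default_spec_has_all_blocks(self):
        kinds = [b.kind for b in default_cost_spec().blocks]
        assert kinds == ["labeling_dynamics", "steady_state_labeling",
                         "pool_sizes", "uptake_rates", "convergence_ratio"]


class TestRunGa:
    def test_truth_in_initial_population_is_kept_by_elitism(
            self, toy_net, toy_truth, toy_data):
        ctx = _toy_context(toy_net, toy_data, toy_truth)
        cfg = GaConfig(population=12, max_generations=3, seed=1,
                       initial_population=((0.02, 0.3),))
        sol = run_ga(ctx, cfg)
        assert sol.cost == pytest.approx(1.0, abs=1e-6)

    def test_best_cost_trajectory_monotone(self, toy_net, toy_truth, toy_data):
        ctx = _toy_context(toy_net, toy_data, toy_truth)
        sol = run_ga(ctx, GaConfig(population=20, max_generations=25, seed=3))
        traj = np.asarray(sol.best_cost_trajectory)
        assert np.all(np.diff(traj) <= 1e-12)

    def test_deterministic_given_seed(self, toy_net, toy_truth, toy_data):
        ctx = _toy_context(toy_net, toy_data, toy_truth)
        cfg = GaConfig(population=16, max_generations=15, seed=42)
        a = run_ga(ctx, cfg)
        b = run_ga(ctx, cfg)
        assert a.cost == b.cost
        assert a.params.free_fluxes == b.params.free_fluxes
        assert a.params.pools == b.params.pools

    def test_convex_surrogate_reaches_analytic_optimum(self):
        """Five-parameter smooth surrogate: the optimum is known in closed
        form; the GA must land within 1% (in parameter space)."""
        target = np.array([0.02, 0.5, 3.0, 0.001, 0.08])

        class Surrogate:
            genes = tuple(f"g{i}" for i in range(5))

            def evaluate(self, vector):
                x = np.log10(vector)
                return 1.0 + float(np.sum((x - np.log10(target)) ** 2))

            def make_params(self, vector):
                return tuple(vector)

        cfg = GaConfig(population=80, max_generations=400,
                       mutation_sigma_decades=0.08, mutation_p=0.3,
                       convergence_window=60, convergence_tol=1e-10, seed=7)
        sol = run_ga(Surrogate(), cfg)
        found = np.asarray(sol.params)
        assert np.all(np.abs(found / target - 1) < 0.01)

    def test_no_feasible_individual_raises(self, toy_net, toy_truth, toy_data):
        from quiflux.errors import QuifluxError

        class Hopeless:
            genes = ("g0",)

            def evaluate(self, vector):
                return INFEASIBLE_COST

            def make_params(self, vector):
                return vector

        with pytest.raises(QuifluxError):
            run_ga(Hopeless(), GaConfig(population=8, max_generations=2,
                                        init_retries=2, seed=0))

    def test_toy_round_trip_recovery_within_10pct(self, toy_net, toy_truth,
                                                  toy_data):
        ctx = FitContext(net=toy_net, data=toy_data, spec=LABELING_ONLY,
                         base=toy_truth.updated(f1=0.005, **{"pool:P": 0.1}),
                         genes=("f1", "pool:P"))
        sol = run_ga(ctx, GaConfig(population=30, max_generations=60,
                                   convergence_window=15, seed=5))
        assert abs(sol.params.free_fluxes["f1"] / 0.02 - 1) < 0.10
        assert abs(sol.params.pools["P"] / 0.3 - 1) < 0.10

    def test_full_model_reduced_gene_recovery(self, net, presets):
        """Noise-free central-carbon dataset: fitting three informative
        fluxes (others held at truth) recovers them within 10%."""
        preset = presets["CI14"]
        data = simulate_dataset(preset, noise=ZERO_NOISE, seed=11, net=net)
        ctx = FitContext(net=net, data=data, spec=LABELING_ONLY,
                         base=preset.params, genes=("F0", "F1", "F8"))
        cfg = GaConfig(population=24, max_generations=25,
                       convergence_window=10, bounds=(1e-4, 1.0), seed=9)
        sol = run_ga(ctx, cfg)
        for g in ctx.genes:
            assert abs(sol.params.free_fluxes[g]
                       / preset.params.free_fluxes[g] - 1) < 0.10, g


class TestEnsembleCollection:
    def test_singleton_matches_single_run(self, toy_net, toy_truth, toy_data):
        ctx = _toy_context(toy_net, toy_data, toy_truth)
        cfg = GaConfig(population=16, max_generations=10, seed=21)
        ens = collect_consistent_solutions(ctx, cfg, n=1, max_restarts=1)
        seeds = np.random.SeedSequence(21).generate_state(1)
        from dataclasses import replace
        direct = run_ga(ctx, replace(cfg, seed=int(seeds[0] % (2 ** 31))))
        assert len(ens) == 1
        assert ens.solutions[0].cost == direct.cost

    def test_reproducible_ensemble(self, toy_net, toy_truth, toy_data):
        ctx = _toy_context(toy_net, toy_data, toy_truth)
        cfg = GaConfig(population=16, max_generations=12, seed=8)
        a = collect_consistent_solutions(ctx, cfg, n=3, max_restarts=5)
        b = collect_consistent_solutions(ctx, cfg, n=3, max_restarts=5)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_noise_free_identifiable_ensemble_near_truth(
            self, toy_net, toy_truth, toy_data):
        ctx = FitContext(net=toy_net, data=toy_data, spec=LABELING_ONLY,
                         base=toy_truth.updated(f1=0.005), genes=("f1",))
        cfg = GaConfig(population=24, max_generations=40,
                       convergence_window=12, seed=13)
        ens = collect_consistent_solutions(ctx, cfg, n=8, max_restarts=12)
        vals = ens.values("f1")
        assert len(ens) == 8
        assert np.all(np.abs(vals / 0.02 - 1) < 0.10)

    def test_degenerate_flux_pair_spreads_but_sum_is_pinned(
            self, toy_parallel_net):
        """Two parallel conversions of which only the sum is constrained:
        ensemble spread per flux far exceeds spread of the sum."""
        truth = FluxParameterSet({"fa": 0.012, "fb": 0.008}, {"A": 0.05},
                                 {"P": 0.3, "Q": 0.15})
        data = simulate_toy_dataset(truth, toy_parallel_net)
        ctx = FitContext(net=toy_parallel_net, data=data, spec=LABELING_ONLY,
                         base=truth, genes=("fa", "fb"))
        cfg = GaConfig(population=24, max_generations=40,
                       convergence_window=12, seed=17, consistency_delta=0.10)
        ens = collect_consistent_solutions(ctx, cfg, n=10, max_restarts=15)
        fa, fb = ens.values("fa"), ens.values("fb")
        spread_each = min(np.ptp(fa), np.ptp(fb))
        spread_sum = np.ptp(fa + fb)
        assert spread_sum < 0.3 * spread_each
        assert np.allclose(fa + fb, 0.02, rtol=0.05)

    def test_partial_ensemble_warns_when_budget_exhausted(
            self, toy_net, toy_truth, toy_data):
        ctx = _toy_context(toy_net, toy_data, toy_truth)
        cfg = GaConfig(population=12, max_generations=6, seed=30)
        with pytest.warns(UserWarning):
            ens = collect_consistent_solutions(ctx, cfg, n=50, max_restarts=2)
        assert len(ens) <= 2
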