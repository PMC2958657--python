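"""Labeling-dynamics simulator: closed forms, conservation, oracles."""

import numpy as np
import pytest
from scipy.linalg import expm

from quiflux.network import FluxParameterSet, LabelState
from quiflux.simulate import (assemble_labeling_odes, integrate,
                              integrate_raw, steady_state_fractions)

from conftest import random_feasible_free_fluxes


def _toy_params(f1=0.02, A=0.05, P=0.3, Q=0.15):
    return FluxParameterSet({"f1": f1}, {"A": A}, {"P": P, "Q": Q})


def _state_idx(system, met, n):
    for i, s in enumerate(system.state_index):
        if s.metabolite == met and s.n_labeled == n:
            return i
    raise KeyError((met, n))


class TestAssembly:
    def test_combined_dimension_is_55(self, net, presets):
        p = presets["CI14"].params
        dims = [assemble_labeling_odes(net, p, t).n_states
                for t in ("U13C-glucose", "U13C-glutamine")]
        assert sum(dims) == 55

    def test_zero_flux_derivative_is_zero(self, toy_net):
        params = _toy_params(f1=0.0, A=0.0)
        system = assemble_labeling_odes(toy_net, params, "U13C-S")
        y0 = system.initial_state()
        assert np.allclose(system.rhs(0.0, y0), 0.0)

    def test_initial_condition_fully_unlabeled(self, net, presets):
        system = assemble_labeling_odes(net, presets["CI7"].params,
                                        "U13C-glucose")
        y0 = system.initial_state()
        for i, st in enumerate(system.state_index):
            assert y0[i] == (1.0 if st.n_labeled == 0 else 0.0)

    def test_total_per_metabolite_is_stationary(self, net, presets):
        """d/dt of the per-metabolite sum over forms vanishes everywhere."""
        system = assemble_labeling_odes(net, presets["CI14"].params,
                                        "U13C-glutamine")
        rng = np.random.default_rng(0)
        y = rng.dirichlet(np.ones(2), size=1)  # build a random simplex state
        y = np.empty(system.n_states)
        groups = {}
        for i, st in enumerate(system.state_index):
            groups.setdefault(st.metabolite, []).append(i)
        for ids in groups.values():
            y[ids] = rng.dirichlet(np.ones(len(ids)))
        dy = system.rhs(0.0, y)
        for met, ids in groups.items():
            pool = system._pools[ids[0]]
            assert abs(np.sum(dy[ids]) * pool) < 1e-12, met


class TestClosedForms:
    def test_one_pool_washout_exponential(self, toy_net):
        """With the conversion flux off, P is a single well-mixed pool fed
        by labeled uptake: unlabeled fraction = exp(-A t / P)."""
        params = _toy_params(f1=0.0, A=0.06, P=0.25)
        system = assemble_labeling_odes(toy_net, params, "U13C-S")
        times = np.array([0.0, 0.2, 0.5, 1.0, 2.0])
        raw = integrate_raw(system, times)
        i0 = _state_idx(system, "P", 0)
        expected = np.exp(-0.06 * times * 60.0 / 0.25)
        assert np.allclose(raw[:, i0], expected, atol=1e-6)

    def test_two_pool_chain_analytic(self, toy_net):
        """Unlabeled Q follows the two-compartment cascade solution."""
        A, f1, P, Q = 0.05, 0.02, 0.3, 0.08
        params = _toy_params(f1=f1, A=A, P=P, Q=Q)
        system = assemble_labeling_odes(toy_net, params, "U13C-S")
        times = np.array([0.0, 0.1, 0.3, 0.8, 1.5])
        raw = integrate_raw(system, times)
        kP, kQ = A / P, f1 / Q           # per-minute rate constants
        t = times * 60.0
        uQ = (kQ * np.exp(-kP * t) - kP * np.exp(-kQ * t)) / (kQ - kP)
        assert np.allclose(raw[:, _state_idx(system, "Q", 0)], uQ, atol=1e-6)

    def test_matrix_exponential_oracle_on_small_network(self, toy_net):
        """On a <=4-state linear network the integrator must agree with
        the matrix-exponential solution to 1e-6."""
        A, f1, P, Q = 0.05, 0.015, 0.3, 0.2
        params = _toy_params(f1=f1, A=A, P=P, Q=Q)
        system = assemble_labeling_odes(toy_net, params, "U13C-S")
        # hand-built generator for [P0, P3, Q0, Q3] + constant input
        M = np.array([
            [-A / P, 0, 0, 0],
            [0, -A / P, 0, 0],
            [f1 / Q, 0, -f1 / Q, 0],
            [0, f1 / Q, 0, -f1 / Q],
        ])
        b = np.array([0.0, A / P, 0.0, 0.0])     # labeled uptake source
        y0 = np.array([1.0, 0.0, 1.0, 0.0])
        times = np.array([0.0, 0.25, 0.75, 1.5])
        raw = integrate_raw(system, times)
        for k, th in enumerate(times * 60.0):
            E = expm(M * th)
            y = E @ y0 + np.linalg.solve(M, (E - np.eye(4)) @ b)
            assert np.allclose(raw[k], y, atol=1e-6)


class TestInvariants:
    @pytest.mark.parametrize("tracer", ["U13C-glucose", "U13C-glutamine"])
    def test_fraction_conservation(self, net, presets, tracer):
        for preset in presets.values():
            system = assemble_labeling_odes(net, preset.params, tracer)
            raw = integrate_raw(system, [0.0, 0.25, 1.0, 2.0, 8.0])
            sums = {}
            for i, st in enumerate(system.state_index):
                sums.setdefault(st.metabolite, np.zeros(raw.shape[0]))
                sums[st.metabolite] += raw[:, i]
            for met, s in sums.items():
                assert np.allclose(s, 1.0, atol=1e-6), (preset.name, met)

    def test_monotone_washout_acyclic(self, toy_net):
        params = _toy_params()
        system = assemble_labeling_odes(toy_net, params, "U13C-S")
        raw = integrate_raw(system, np.linspace(0, 3, 40, endpoint=True))
        for met in ("P", "Q"):
            u = raw[:, _state_idx(system, met, 0)]
            assert np.all(np.diff(u) <= 1e-9)

    def test_flux_time_rescaling_invariance(self, net, presets):
        """Scaling all fluxes and rates by k while dividing times by k
        leaves the labeling fractions unchanged."""
        p = presets["proliferating"].params
        k = 3.0
        scaled = FluxParameterSet(
            {s: v * k for s, v in p.free_fluxes.items()},
            {s: v * k for s, v in p.rates.items()},
            dict(p.pools), p.latent_hexp_pool, p.latent_citrate_fraction)
        times = np.array([0.0, 0.3, 0.9, 1.8])
        sys1 = assemble_labeling_odes(net, p, "U13C-glucose")
        sys2 = assemble_labeling_odes(net, scaled, "U13C-glucose")
        raw1 = integrate_raw(sys1, times)
        raw2 = integrate_raw(sys2, times / k)
        assert np.allclose(raw1, raw2, atol=1e-6)

    def test_tolerance_refinement_stability(self, net, presets):
        system = assemble_labeling_odes(net, presets["CI7"].params,
                                        "U13C-glucose")
        times = [0.0, 0.5, 2.0]
        a = integrate_raw(system, times)
        b = integrate_raw(system, times, rtol=1e-9, atol=1e-11)
        assert np.max(np.abs(a - b)) < 1e-4

    def test_integrate_rejects_bad_time_grid(self, net, presets):
        system = assemble_labeling_odes(net, presets["CI7"].params,
                                        "U13C-glucose")
        with pytest.raises(ValueError):
            integrate_raw(system, [0.5, 1.0])
        with pytest.raises(ValueError):
            integrate_raw(system, [0.0, 1.0, 1.0])


class TestObservedFractions:
    def test_timecourse_schema_and_latent_mixing(self, net, presets):
        p = presets["proliferating"].params       # latent citrate 0.40
        system = assemble_labeling_odes(net, p, "U13C-glucose")
        df = integrate(system, [0.0, 2.0], condition="proliferating")
        assert list(df.columns) == ["metabolite", "n_labeled", "time_h",
                                    "fraction", "sd", "tracer", "condition"]
        cit0 = df[(df.metabolite == "cit") & (df.n_labeled == 0)
                  & (df.time_h == 2.0)]["fraction"].iloc[0]
        assert cit0 >= 0.40
        # per metabolite and time, observed fractions still sum to one
        for (met, t), grp in df.groupby(["metabolite", "time_h"]):
            assert grp["fraction"].sum() == pytest.approx(1.0, abs=1e-6)


class TestSteadyState:
    def test_latent_citrate_floors_unlabeled_asymptote(self, net, presets):
        p = presets["proliferating"].params
        system = assemble_labeling_odes(net, p, "U13C-glucose")
        ss = steady_state_fractions(system)
        assert ss[LabelState("cit", 0, "U13C-glucose")] >= 0.40

    def test_one_pool_washout_labels_fully(self, toy_net):
        params = _toy_params(f1=0.0)
        system = assemble_labeling_odes(toy_net, params, "U13C-S")
        ss = steady_state_fractions(system)
        assert ss[LabelState("P", 3, "U13C-S")] == pytest.approx(1.0, abs=1e-4)

    def test_fixed_point_oracle(self, net, rng):
        """The integrated asymptote solves the stationarity equations,
        checked by an independent damped fixed-point iteration on the
        production/consumption balance."""
        free, rates = random_feasible_free_fluxes(rng, net)
        pools = {m: 0.05 for m in net.pool_metabolites}
        pools["fa"] = 0.5
        params = FluxParameterSet(free, rates, pools)
        system = assemble_labeling_odes(net, params, "U13C-glucose")
        ss = steady_state_fractions(system, observed=False)
        y = np.array([ss[s] for s in system.state_index])
        # independent route: y is stationary iff rhs vanishes
        dy = system.rhs(0.0, y)
        assert np.max(np.abs(dy)) < 1e-6
        # and damped fixed-point iteration from uniform start converges to it
        groups = {}
        for i, st in enumerate(system.state_index):
            groups.setdefault(st.metabolite, []).append(i)
        z = np.empty_like(y)
        for ids in groups.values():
            z[ids] = 1.0 / len(ids)
        for _ in range(20000):
            z = np.clip(z + 0.5 * system.rhs(0.0, z), 0.0, 1.0)
        assert np.allclose(z, y, atol=1e-3)
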