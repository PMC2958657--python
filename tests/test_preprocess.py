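"""Measurement-side estimators: rates, pools, filters, ratios."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quiflux.preprocess import (MediumTimecourse, PoolTable, ProteinCurve,
                                anaplerosis_ratio, blank_enrichment_filter,
                                differential_pools, gsh_gssg_ratio,
                                integrated_protein_hours, latent_pool_fraction,
                                lactate_isotopomer_ratio, normalize_pool_sizes,
                                uptake_excretion_rate)
from quiflux.synthetic import NoiseModel, generate_pool_table


def _medium(times, glucose, volume=1.0, cond="x"):
    return MediumTimecourse(times_h=np.asarray(times),
                            concentrations={"glucose": np.asarray(glucose)},
                            volume_ml=volume, condition=cond)


class TestProteinIntegral:
    def test_rectangle(self):
        curve = ProteinCurve([0.0, 10.0], [100.0, 100.0])
        assert integrated_protein_hours(curve, 0, 10) == pytest.approx(1000.0)

    def test_triangle(self):
        curve = ProteinCurve([0.0, 10.0], [1e-9, 100.0])
        assert integrated_protein_hours(curve, 0, 10) == pytest.approx(500.0, rel=1e-6)

    def test_exponential_growth_close_to_analytic(self):
        k = np.log(2) / 24.0
        t = np.linspace(0, 48, 10)
        curve = ProteinCurve(t, 100 * np.exp(k * t))
        exact = 100 / k * (np.exp(k * 48) - 1)
        approx = integrated_protein_hours(curve, 0, 48)
        assert abs(approx - exact) / exact < 0.01

    def test_interval_outside_range_rejected(self):
        curve = ProteinCurve([0.0, 10.0], [100.0, 100.0])
        with pytest.raises(ValueError):
            integrated_protein_hours(curve, 0, 12)
        with pytest.raises(ValueError):
            integrated_protein_hours(curve, 5, 5)


class TestUptakeRate:
    def test_no_change_gives_zero(self):
        med = _medium([0, 24], [4.0, 4.0])
        curve = ProteinCurve([0, 24], [100.0, 100.0])
        assert uptake_excretion_rate(med, curve, "glucose") == pytest.approx(0.0)

    def test_hand_arithmetic_two_points(self):
        """4 -> 3 mM in 1 ml over 24 h at constant 100 ug protein:
        1000 nmol / (100 ug * 1440 min), recomputed independently."""
        med = _medium([0, 24], [4.0, 3.0])
        curve = ProteinCurve([0, 24], [100.0, 100.0])
        rate = uptake_excretion_rate(med, curve, "glucose")
        spreadsheet = (1.0 * 1.0 * 1e3) / (100.0 * 24.0 * 60.0)
        assert rate == pytest.approx(spreadsheet)
        assert rate == pytest.approx(6.944e-3, rel=1e-3)

    def test_excretion_sign_convention(self):
        med = MediumTimecourse([0, 24], {"lactate": np.array([0.0, 2.0])},
                               volume_ml=1.0)
        curve = ProteinCurve([0, 24], [100.0, 100.0])
        assert uptake_excretion_rate(med, curve, "lactate") > 0

    def test_generator_round_trip_within_5pct(self, presets):
        from quiflux.synthetic import generate_medium_experiment
        preset = presets["CI14"]
        rng = np.random.default_rng(3)
        med, curve = generate_medium_experiment(
            preset, noise=NoiseModel(medium_rel_sd=0.01), rng=rng)
        est = uptake_excretion_rate(med, curve, "glucose")
        assert abs(est - preset.params.rates["A"]) / preset.params.rates["A"] < 0.05

    def test_interval_splitting_invariance_noise_free(self):
        """On exact data the full-interval rate equals the amount-weighted
        combination of sub-interval rates."""
        t = np.array([0.0, 12.0, 24.0, 48.0])
        conc = 5.0 - 0.05 * t
        curve = ProteinCurve(t, np.full(4, 200.0))
        full = uptake_excretion_rate(_medium(t, conc), curve, "glucose")
        parts = []
        for i in range(3):
            med_i = _medium(t[i:i + 2] - t[i], conc[i:i + 2])
            curve_i = ProteinCurve(t[i:i + 2] - t[i], [200.0, 200.0])
            d_amount = (conc[i] - conc[i + 1]) * 1e3
            parts.append((uptake_excretion_rate(med_i, curve_i, "glucose"),
                          d_amount))
        combined = sum(r * w for r, w in parts) / sum(w for _, w in parts)
        assert full == pytest.approx(combined, rel=1e-9)

    def test_endpoint_protein_method(self):
        med = _medium([0, 24], [4.0, 3.0])
        curve = ProteinCurve([0, 24], [50.0, 100.0])
        r_int = uptake_excretion_rate(med, curve, "glucose")
        r_end = uptake_excretion_rate(med, curve, "glucose",
                                      method="endpoint_protein")
        assert r_end < r_int        # final protein exceeds the running average


class TestPools:
    def test_normalization_and_censoring(self):
        sig = pd.DataFrame({"s1": [5000.0, 100.0], "s2": [2500.0, 400.0]},
                           index=["m1", "m2"])
        pt = PoolTable(signals=sig,
                       blank=pd.Series({"m1": 100.0, "m2": 100.0}),
                       protein_ug=pd.Series({"s1": 50.0, "s2": 25.0}),
                       condition=pd.Series({"s1": "a", "s2": "b"}))
        norm = normalize_pool_sizes(pt)
        assert norm.levels.loc["m1", "s1"] == pytest.approx(100.0)
        assert norm.levels.loc["m1", "s2"] == pytest.approx(100.0)
        assert bool(norm.censored.loc["m2", "s1"]) is True
        assert bool(norm.censored.loc["m1", "s1"]) is False

    def test_blank_filter_examples(self):
        sig = pd.DataFrame({"s1": [600.0, 100.0], "s2": [90.0, 100.0]},
                           index=["kept", "dropped"])
        pt = PoolTable(signals=sig,
                       blank=pd.Series({"kept": 100.0, "dropped": 100.0}),
                       protein_ug=pd.Series({"s1": 1.0, "s2": 1.0}),
                       condition=pd.Series({"s1": "a", "s2": "a"}))
        assert blank_enrichment_filter(pt) == ["kept"]

    def test_blank_filter_zero_blank_uses_sentinel_floor(self):
        sig = pd.DataFrame({"s1": [450.0]}, index=["m"])
        pt = PoolTable(signals=sig, blank=pd.Series({"m": 0.0}),
                       protein_ug=pd.Series({"s1": 1.0}),
                       condition=pd.Series({"s1": "a"}))
        assert blank_enrichment_filter(pt) == []          # 450/100 < 5
        sig2 = pd.DataFrame({"s1": [600.0]}, index=["m"])
        pt2 = PoolTable(signals=sig2, blank=pd.Series({"m": 0.0}),
                        protein_ug=pd.Series({"s1": 1.0}),
                        condition=pd.Series({"s1": "a"}))
        assert blank_enrichment_filter(pt2) == ["m"]

    def test_constructed_table_keeps_exactly_n_real(self):
        pt = generate_pool_table(4, 6, seed=12)
        kept = blank_enrichment_filter(pt)
        assert sorted(kept) == [f"met{i:02d}" for i in range(4)]

    @settings(max_examples=30, deadline=None)
    @given(bump=st.floats(min_value=0, max_value=1e4),
           row=st.integers(min_value=0, max_value=3),
           col=st.integers(min_value=0, max_value=7))
    def test_blank_filter_monotone_in_signals(self, bump, row, col):
        pt = generate_pool_table(4, 4, seed=5)
        kept_before = set(blank_enrichment_filter(pt))
        sig = pt.signals.copy()
        sig.iloc[row, col] += bump
        pt2 = PoolTable(signals=sig, blank=pt.blank,
                        protein_ug=pt.protein_ug, condition=pt.condition)
        assert kept_before <= set(blank_enrichment_filter(pt2))


class TestDifferentialPools:
    def test_identical_groups_empty(self):
        pt = generate_pool_table(8, 0, seed=3, noise=NoiseModel(pool_cv=0.08))
        norm = normalize_pool_sizes(pt)
        assert differential_pools(norm) == []

    def test_injected_shift_detected_among_nulls(self):
        pt = generate_pool_table(30, 0, seed=4,
                                 effect={"metabolite": "met07", "n_sd": 10,
                                         "condition": "CI14"})
        norm = normalize_pool_sizes(pt)
        hits = differential_pools(norm)
        assert "met07" in hits
        assert len(hits) <= 3

    def test_fdr_controlled_on_pure_null(self):
        """Mean realized false-discovery proportion over repeated pure-null
        tables stays at the nominal level within Monte-Carlo error."""
        rng = np.random.default_rng(99)
        n_rep, n_met, n_per = 300, 40, 4
        fdp = []
        for _ in range(n_rep):
            levels = pd.DataFrame(
                np.exp(rng.standard_normal((n_met, 2 * n_per)) * 0.1),
                index=[f"m{i}" for i in range(n_met)],
                columns=[f"s{j}" for j in range(2 * n_per)])
            from quiflux.preprocess import NormalizedPools
            norm = NormalizedPools(
                levels=levels,
                censored=pd.DataFrame(False, index=levels.index,
                                      columns=levels.columns),
                condition=pd.Series(["a"] * n_per + ["b"] * n_per,
                                    index=levels.columns))
            hits = differential_pools(norm)
            fdp.append(1.0 if hits else 0.0)   # all discoveries are false
        mean_fdp = np.mean(fdp)
        se = np.sqrt(mean_fdp * (1 - mean_fdp) / n_rep) + 1e-3
        assert mean_fdp <= 0.05 + 3 * se


class TestRatios:
    @pytest.mark.parametrize("a1, a2, expected", [(10, 100, 0.1), (0, 100, 0.0)])
    def test_lactate_ratio(self, a1, a2, expected):
        assert lactate_isotopomer_ratio(a1, a2) == pytest.approx(expected)

    def test_lactate_ratio_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            lactate_isotopomer_ratio(5, 0)

    @pytest.mark.parametrize("a1, a0, expected", [(20, 80, 0.25), (0, 80, 0.0)])
    def test_anaplerosis_ratio(self, a1, a0, expected):
        assert anaplerosis_ratio(a1, a0) == pytest.approx(expected)

    def test_anaplerosis_spreadsheet_fixture(self):
        # small labeled-form table, recomputed spreadsheet-style
        table = pd.DataFrame({
            "condition": ["P", "CI7", "CI14"],
            "cit_1x": [12.0, 30.0, 35.0],
            "cit_0x": [88.0, 70.0, 65.0],
        })
        ratios = [anaplerosis_ratio(r.cit_1x, r.cit_0x)
                  for r in table.itertuples()]
        expected = (table["cit_1x"] / table["cit_0x"]).tolist()
        assert ratios == pytest.approx(expected)

    def test_gsh_gssg_examples(self):
        assert gsh_gssg_ratio(110.0, 5.0) == pytest.approx(20.0)
        assert gsh_gssg_ratio(10.0, 5.0) == pytest.approx(0.0)
        with pytest.raises(ZeroDivisionError):
            gsh_gssg_ratio(10.0, 0.0)
        with pytest.raises(ValueError):
            gsh_gssg_ratio(9.0, 5.0)

    def test_gsh_ratio_monotone_in_gssg(self):
        vals = [gsh_gssg_ratio(100.0, g) for g in (5.0, 10.0, 25.0, 49.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestLatentPool:
    def test_minimum_unlabeled_fraction(self):
        df = pd.DataFrame({
            "metabolite": ["cit"] * 4, "n_labeled": [0] * 4,
            "time_h": [0, 1, 2, 4], "fraction": [1.0, 0.5, 0.02, 0.10],
            "sd": [0.0] * 4, "tracer": ["t"] * 4, "condition": ["c"] * 4})
        assert latent_pool_fraction(df) == pytest.approx(0.02)

    def test_multiple_experiments_pooled(self):
        frames = []
        for tracer, mins in [("a", 0.5), ("b", 0.3)]:
            frames.append(pd.DataFrame({
                "metabolite": ["cit"], "n_labeled": [0], "time_h": [2.0],
                "fraction": [mins], "sd": [0.0], "tracer": [tracer],
                "condition": ["c"]}))
        assert latent_pool_fraction(frames) == pytest.approx(0.3)

    def test_no_labeling_flags_boundary(self):
        df = pd.DataFrame({
            "metabolite": ["cit"] * 3, "n_labeled": [0] * 3,
            "time_h": [0, 1, 2], "fraction": [1.0, 1.0, 1.0],
            "sd": [0.0] * 3, "tracer": ["t"] * 3, "condition": ["c"] * 3})
        with pytest.warns(UserWarning):
            assert latent_pool_fraction(df) == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            latent_pool_fraction([])
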