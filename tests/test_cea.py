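"""Scenario mixing, deterministic CEA, PSA, CEAC and HR sensitivity."""

import numpy as np
import pytest

from rgnact.cea import (
    CEAModel,
    PSAResult,
    ScenarioConfig,
    ceac,
    deterministic_cea,
    excluded_for_contraindications,
    hr_sensitivity,
    icer_label,
    mix_scenario,
    run_psa,
)
from rgnact.markov import ModelInputs


class TestExclusions:
    def test_target_population_exclusion_count(self, pset):
        expected = excluded_for_contraindications(6306, pset.contraindications)
        assert int(np.floor(expected)) == 971

    def test_zero_prevalences(self):
        assert excluded_for_contraindications(6306, [0.0, 0.0]) == 0.0

    def test_additive_vs_complement_product_close(self, pset):
        n = 6306
        add = excluded_for_contraindications(n, pset.contraindications, "additive")
        prod = excluded_for_contraindications(n, pset.contraindications, "complement-product")
        assert abs(add - prod) / n < 0.01  # < 1% absolute of the population

    def test_prevalences_above_one_rejected(self):
        with pytest.raises(ValueError):
            excluded_for_contraindications(100, [0.6, 0.6])


class TestScenarioMixing:
    def test_full_uptake_weight(self, pset, base_inputs):
        w_rg, w_conv = mix_scenario(ScenarioConfig.full(), base_inputs)
        assert w_rg == pytest.approx((6306 - 971.906) / 6306, abs=1e-4)
        assert w_rg + w_conv == pytest.approx(1.0)

    def test_zero_uptake_all_conventional(self, base_inputs):
        w_rg, w_conv = mix_scenario(ScenarioConfig.with_uptake(0.0), base_inputs)
        assert (w_rg, w_conv) == (0.0, 1.0)

    def test_half_uptake_is_midpoint(self, base_inputs):
        w0, _ = mix_scenario(ScenarioConfig.with_uptake(0.0), base_inputs)
        w1, _ = mix_scenario(ScenarioConfig.full(), base_inputs)
        wh, _ = mix_scenario(ScenarioConfig.with_uptake(0.5), base_inputs)
        assert wh == pytest.approx((w0 + w1) / 2)

    def test_current_scenario_uses_configured_scan_count(self, base_inputs):
        w_rg, _ = mix_scenario(ScenarioConfig.current(current_scans=218), base_inputs)
        assert w_rg == pytest.approx(218 / 6306)

    def test_invalid_uptake_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig.with_uptake(1.2)


class TestIcerLabel:
    def test_dominant_quadrant(self):
        icer, label, ce = icer_label(-13.0, 0.005)
        assert icer is None and label == "dominant" and ce

    def test_plain_icer(self):
        icer, label, ce = icer_label(100.0, 0.005)
        assert icer == pytest.approx(20_000.0)
        assert not ce  # NMB exactly zero counts as not cost-effective

    def test_no_difference(self):
        icer, label, ce = icer_label(0.0, 0.0)
        assert icer is None and not ce


class TestDeterministicCEA:
    def test_base_case_dominant_in_both_scenarios(self, pset, life_table):
        for sc in (ScenarioConfig.current(), ScenarioConfig.full()):
            res = deterministic_cea(sc, pset, life_table)
            assert res.delta_cost < 0
            assert res.delta_qaly > 0
            assert res.label == "dominant"
            assert res.cost_effective

    def test_identical_arms_give_zero_deltas(self, pset, life_table):
        res = deterministic_cea(ScenarioConfig.with_uptake(0.0), pset, life_table)
        assert res.delta_cost == 0.0
        assert res.delta_qaly == 0.0
        assert res.icer is None

    def test_deltas_linear_in_uptake(self, pset, life_table):
        uptakes = [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]
        results = [
            deterministic_cea(ScenarioConfig.with_uptake(u), pset, life_table)
            for u in uptakes
        ]
        d_qaly = [r.delta_qaly for r in results]
        d_cost = [r.delta_cost for r in results]
        assert all(np.diff(d_qaly) > 0)  # more uptake -> more QALY gain
        assert all(np.diff(d_cost) < 0)  # ... and more savings

    def test_summary_mentions_decision(self, pset, life_table):
        res = deterministic_cea(ScenarioConfig.full(), pset, life_table)
        text = res.summary()
        assert "dominant" in text
        assert "QALY" in text

    def test_model_results_roundtrip_dict(self, pset, life_table):
        res = CEAModel(pset, ScenarioConfig.full(), life_table).fit()
        d = res.to_dict()
        assert d["label"] == "dominant"
        assert d["arms"]["rg_nact"]["qaly"] > 0


class TestPSA:
    def test_seeded_runs_bit_identical(self, pset, life_table):
        kw = dict(n_draws=50, seed=11, life_table=life_table)
        a = run_psa(ScenarioConfig.full(), pset, **kw)
        b = run_psa(ScenarioConfig.full(), pset, **kw)
        assert np.array_equal(a.delta_cost, b.delta_cost)
        assert np.array_equal(a.delta_effect, b.delta_effect)

    def test_different_seeds_differ(self, pset, life_table):
        a = run_psa(ScenarioConfig.full(), pset, n_draws=20, seed=1, life_table=life_table)
        b = run_psa(ScenarioConfig.full(), pset, n_draws=20, seed=2, life_table=life_table)
        assert not np.array_equal(a.delta_cost, b.delta_cost)

    def test_invalid_seed_type_rejected(self, pset, life_table):
        with pytest.raises(TypeError):
            run_psa(ScenarioConfig.full(), pset, n_draws=5, seed="abc", life_table=life_table)

    def test_mean_consistent_across_sample_sizes(self, pset, life_table):
        small = run_psa(ScenarioConfig.full(), pset, n_draws=200, seed=3, life_table=life_table)
        large = run_psa(ScenarioConfig.full(), pset, n_draws=2000, seed=4, life_table=life_table)
        se = small.delta_effect.std() / np.sqrt(small.n_draws)
        assert abs(small.delta_effect.mean() - large.delta_effect.mean()) < 3 * se

    def test_base_case_inside_psa_cloud(self, pset, life_table):
        res = CEAModel(pset, ScenarioConfig.full(), life_table).fit_psa(n_draws=1000, seed=5)
        lo_c, hi_c = np.percentile(res.psa.delta_cost, [0.5, 99.5])
        lo_e, hi_e = np.percentile(res.psa.delta_effect, [0.5, 99.5])
        assert lo_c < res.delta_cost < hi_c
        assert lo_e < res.delta_qaly < hi_e

    def test_hr_mode_fixed_keeps_conventional_tps(self, pset, rng):
        from rgnact.markov import sample_inputs

        base = ModelInputs.from_means(pset)
        fixed = sample_inputs(pset, rng, 5, hr_mode="fixed")
        assert all(
            np.array_equal(d.relapse_conventional, base.relapse_conventional) for d in fixed
        )
        resampled = sample_inputs(pset, rng, 5, hr_mode="resample")
        assert any(
            not np.array_equal(d.relapse_conventional, base.relapse_conventional)
            for d in resampled
        )


class TestCEAC:
    def _psa(self, delta_cost, delta_effect):
        return PSAResult(np.asarray(delta_cost, float), np.asarray(delta_effect, float),
                         seed=0, hr_mode="fixed", scenario="test")

    def test_dominant_draws_give_probability_one(self):
        psa = self._psa([-10, -5, -1], [0.1, 0.2, 0.3])
        curve = ceac(psa, thresholds=[0, 10_000, 20_000])
        assert np.all(curve["probability"] == 1.0)

    def test_symmetric_draws_give_half(self):
        psa = self._psa([-1, 1], [0.01, -0.01])
        curve = ceac(psa, thresholds=[20_000])
        assert curve["probability"].iloc[0] == pytest.approx(0.5)

    def test_probabilities_are_proper(self, pset, life_table):
        psa = run_psa(ScenarioConfig.full(), pset, n_draws=300, seed=9, life_table=life_table)
        curve = ceac(psa)
        assert curve["probability"].between(0, 1).all()

    def test_empty_draws_rejected(self):
        psa = self._psa([], [])
        with pytest.raises(ValueError):
            ceac(psa)


class TestHrSensitivity:
    def test_base_hazard_ratio_reproduces_base_case(self, pset, life_table):
        base = deterministic_cea(ScenarioConfig.full(), pset, life_table)
        table = hr_sensitivity(ScenarioConfig.full(), pset, taus_rfs=[0.5],
                               life_table=life_table)
        assert table["delta_cost"].iloc[0] == pytest.approx(base.delta_cost)
        assert table["delta_qaly"].iloc[0] == pytest.approx(base.delta_qaly)

    def test_two_way_grid_is_outer_product(self, pset, life_table):
        table = hr_sensitivity(ScenarioConfig.full(), pset, taus_rfs=[0.3, 0.5],
                               taus_bcss=[0.64, 1.0], life_table=life_table, two_way=True)
        assert len(table) == 4
        pairs = set(zip(table["hr_rfs"], table["hr_bcss"]))
        assert pairs == {(0.3, 0.64), (0.3, 1.0), (0.5, 0.64), (0.5, 1.0)}

    def test_smaller_rfs_hazard_ratio_more_dominant(self, pset, life_table):
        table = hr_sensitivity(ScenarioConfig.full(), pset, taus_rfs=[0.1, 0.5, 1.0],
                               life_table=life_table)
        assert table["delta_qaly"].is_monotonic_decreasing
        assert table["delta_cost"].is_monotonic_increasing

    def test_nonpositive_tau_rejected(self, pset, life_table):
        with pytest.raises(ValueError):
            hr_sensitivity(ScenarioConfig.full(), pset, taus_rfs=[0.0], life_table=life_table)
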