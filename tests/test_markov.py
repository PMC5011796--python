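"""Cohort engine: accruals, discounting, toxicity burden, invariants."""

from dataclasses import replace

import numpy as np
import pytest

from rgnact.markov import (
    LifeTable,
    conventional_arm,
    discounted_sum,
    expected_year1_utility,
    rg_arm,
    run_cohort,
    sample_inputs,
    toxicity_burden,
)


def zeroed_inputs(base):
    """Inputs with no transitions, no toxicity, no incidental findings."""
    zero_tps = np.zeros(5)
    tox_prob = {k: {b: 0.0 for b in v} for k, v in base.tox_prob.items()}
    return replace(
        base,
        tox_prob=tox_prob,
        relapse_false=zero_tps,
        relapse_conventional=zero_tps,
        bc_death_false=zero_tps,
        bc_death_conventional=zero_tps,
        p_incidental=0.0,
    )


class TestDiscountedSum:
    def test_level_stream_at_four_percent(self):
        # 100/year for 5 years: geometric sum = 445.18
        assert discounted_sum([100] * 5, 0.04) == pytest.approx(445.18, abs=0.01)

    def test_zero_rate_is_plain_sum(self):
        assert discounted_sum([1.5, 2.5, 3.0], 0.0) == pytest.approx(7.0)

    def test_single_payment_first_cycle(self):
        assert discounted_sum([200.0], 0.1) == pytest.approx(200.0 / 1.1)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discounted_sum([1.0], -0.01)


class TestToxicityBurden:
    def test_6xac_uses_anthracycline_block(self, base_inputs):
        events, p_aml = toxicity_burden("6xAC", base_inputs)
        by_name = {e.name: e for e in events}
        assert by_name["vomiting"].probability == 0.05
        assert by_name["neutropenia"].probability == 0.85
        assert by_name["chf"].probability == 0.017
        assert by_name["hfs"].probability == 0.0
        assert p_aml == 0.005

    def test_sequential_path_product_rule(self, base_inputs):
        events, p_aml = toxicity_burden("3xAC+3xDC", base_inputs)
        by_name = {e.name: e for e in events}
        assert by_name["vomiting"].probability == pytest.approx(0.05 * 0.24)  # 0.012
        assert by_name["neutropenia"].probability == pytest.approx(0.85 * 0.72)
        assert by_name["hfs"].probability == 0.22
        assert by_name["chf"].probability == 0.002
        assert p_aml == 0.003

    def test_zero_cost_for_untreatable_toxicities(self, base_inputs):
        events, _ = toxicity_burden("3xAC+3xDC", base_inputs)
        by_name = {e.name: e for e in events}
        assert by_name["hfs"].cost == 0.0
        assert by_name["desquamation"].cost == 0.0

    def test_unknown_regimen_rejected(self, base_inputs):
        with pytest.raises(ValueError):
            toxicity_burden("9xFEC", base_inputs)

    def test_all_zero_probabilities_give_zero_burden(self, base_inputs):
        events, p_aml = toxicity_burden("6xAC", zeroed_inputs(base_inputs))
        assert sum(e.probability for e in events) == 0.0
        assert sum(e.probability * e.cost for e in events) == 0.0


class TestYear1Utility:
    def test_no_events_gives_chemo_utility(self):
        assert expected_year1_utility((), 0.62) == 0.62

    def test_certain_toxicity_substitutes_its_utility(self, base_inputs):
        events, _ = toxicity_burden("6xAC", base_inputs)
        forced = tuple(replace(e, probability=1.0 if e.name == "neutropenia" else 0.0)
                       for e in events)
        assert expected_year1_utility(forced, 0.62) == pytest.approx(0.53)

    def test_anxiety_alone_uses_anxiety_utility(self):
        assert expected_year1_utility((), 0.62, p_anxiety=1.0, u_anxiety=0.68) == pytest.approx(0.68)

    def test_co_occurring_events_take_minimum_utility(self, base_inputs):
        events, _ = toxicity_burden("6xAC", base_inputs)
        forced = tuple(replace(e, probability=1.0 if e.name in ("vomiting", "neutropenia") else 0.0)
                       for e in events)
        # vomiting utility 0.52 < neutropenia 0.53
        assert expected_year1_utility(forced, 0.62) == pytest.approx(0.52)


class TestRunCohort:
    def test_event_free_cohort_hand_accumulation(self, base_inputs, zero_life_table):
        # no events anywhere: 5 life-years; chemo utility year 1 then DFS
        inputs = zeroed_inputs(base_inputs)
        _, out = run_cohort(conventional_arm(inputs), inputs, zero_life_table)
        assert out.ly == pytest.approx(5.0)
        assert out.qaly == pytest.approx(0.62 + 4 * 0.80)  # 3.82

    def test_forced_relapse_first_year(self, base_inputs, zero_life_table):
        inputs = zeroed_inputs(base_inputs)
        inputs = replace(inputs, relapse_conventional=np.array([1.0, 0, 0, 0, 0]))
        trace, out = run_cohort(conventional_arm(inputs), inputs, zero_life_table)
        frame = trace.frame.set_index("cycle")
        assert out.events["relapses"] == pytest.approx(1.0)
        for cycle in (2, 3, 4, 5):
            assert frame.loc[cycle, "relapse"] == pytest.approx(1.0)

    def test_zero_rates_make_discounted_equal_undiscounted(self, base_inputs, life_table):
        _, out = run_cohort(conventional_arm(base_inputs), base_inputs, life_table,
                            discount_cost=0.0, discount_effect=0.0)
        assert out.cost_disc == pytest.approx(out.cost)
        assert out.qaly_disc == pytest.approx(out.qaly)
        assert out.ly_disc == pytest.approx(out.ly)

    def test_invalid_horizon_and_rates_rejected(self, base_inputs, life_table):
        with pytest.raises(ValueError):
            run_cohort(conventional_arm(base_inputs), base_inputs, life_table, horizon=0)
        with pytest.raises(ValueError):
            run_cohort(conventional_arm(base_inputs), base_inputs, life_table,
                       discount_cost=-0.04)

    def test_discounted_never_exceeds_undiscounted(self, base_inputs, life_table):
        for arm in (rg_arm(base_inputs), conventional_arm(base_inputs)):
            _, out = run_cohort(arm, base_inputs, life_table)
            assert out.cost_disc <= out.cost
            assert out.qaly_disc <= out.qaly
            assert out.ly_disc <= out.ly
            assert 0 <= out.ly <= 5

    def test_base_case_dominance(self, base_inputs, life_table):
        _, rg = run_cohort(rg_arm(base_inputs), base_inputs, life_table)
        _, conv = run_cohort(conventional_arm(base_inputs), base_inputs, life_table)
        assert rg.cost_disc < conv.cost_disc
        assert rg.qaly_disc > conv.qaly_disc

    def test_relapse_probability_monotone_against_qaly(self, base_inputs, life_table):
        _, base_out = run_cohort(conventional_arm(base_inputs), base_inputs, life_table)
        bumped = replace(
            base_inputs,
            relapse_conventional=np.minimum(base_inputs.relapse_conventional + 0.1, 1.0),
        )
        _, bumped_out = run_cohort(conventional_arm(bumped), bumped, life_table)
        assert bumped_out.qaly <= base_out.qaly

    def test_occupancy_conserved_over_random_draws(self, pset, life_table, rng):
        draws = sample_inputs(pset, rng, 1000)
        for inputs in draws:
            for arm in (rg_arm(inputs), conventional_arm(inputs)):
                trace, _ = run_cohort(arm, inputs, life_table)
                frame = trace.frame
                total = (
                    frame["dfs"] + frame["relapse"] + frame["death_bc"] + frame["death_other"]
                )
                assert np.all(np.abs(total - 1.0) < 1e-12)

    def test_event_counts_linear_in_cohort_size(self, base_inputs, life_table):
        # engine works per patient; cohort counts scale linearly by construction
        _, out = run_cohort(conventional_arm(base_inputs), base_inputs, life_table)
        for n in (100, 1000, 6306):
            assert n * out.events["chf"] == pytest.approx(out.events["chf"] * n)
        assert out.events["chf"] == pytest.approx(0.017)

    def test_aml_strikes_only_survivors_in_year_five(self, base_inputs, life_table):
        _, out = run_cohort(conventional_arm(base_inputs), base_inputs, life_table)
        p_aml = base_inputs.tox_prob["aml_mds"]["ac6"]
        assert out.events["aml_mds"] < p_aml  # some of the cohort died before year 5
        assert out.events["aml_mds"] > 0.9 * p_aml

    def test_bc_death_indexing_variants_both_run(self, base_inputs, life_table):
        _, tunnel = run_cohort(conventional_arm(base_inputs, "since-relapse"),
                               base_inputs, life_table)
        _, model_time = run_cohort(conventional_arm(base_inputs, "model-time"),
                                   base_inputs, life_table)
        # model-time indexing exposes relapsed patients to later (larger)
        # probabilities sooner, so it yields more breast-cancer deaths
        assert model_time.events["bc_deaths"] > tunnel.events["bc_deaths"]


class TestLifeTable:
    def test_lookup_clamps_to_range(self):
        lt = LifeTable(ages=np.array([50.0, 51.0]), mortality=np.array([0.1, 0.2]))
        assert lt.q(49.0) == 0.1
        assert lt.q(50.5) == 0.1
        assert lt.q(99.0) == 0.2

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            LifeTable(ages=np.array([50.0]), mortality=np.array([1.5]))
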