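"""The two-phase lupus-nephritis model: construction, mortality, linkage."""

import numpy as np
import pytest

from lncea.ln_model import (LIFETIME_STATES, MAINTENANCE_STATES, Arm,
                            LifetimeScenario, LifeTable, RescuePolicy,
                            ThreeYearEvaluator, apply_extrapolation,
                            build_lifetime_model, build_maintenance_model,
                            esrd_mortality, link_phases, lupus_mortality)
from lncea.markov_engine import run_cohort


def flat_table(q, ages=(18, 100)):
    a = np.arange(ages[0], ages[1] + 1)
    return LifeTable(a, np.full(len(a), q))


def init_vector():
    v = np.zeros(len(MAINTENANCE_STATES))
    v[0] = 1.0
    return v


@pytest.fixture(scope="module")
def specs(params):
    return {label: build_maintenance_model(Arm(label), params)
            for label in ("AZA", "MMF")}


class TestMaintenanceModel:
    def test_states_and_row_sums(self, specs):
        for spec in specs.values():
            mat = spec.matrix(0, 30.0)
            assert np.allclose(mat.sum(axis=1), 1.0, atol=1e-9)
            assert spec.states == MAINTENANCE_STATES

    def test_arm_specific_remission_probabilities(self, specs):
        i = MAINTENANCE_STATES.index("remission_maintenance")
        j = MAINTENANCE_STATES.index("relapse_mmf")
        assert specs["MMF"].matrix(0, 30.0)[i, j] == pytest.approx(0.0185)
        assert specs["AZA"].matrix(0, 30.0)[i, j] == pytest.approx(0.0364)

    def test_rescue_and_esrd_rows_match_published_values(self, specs):
        mat = specs["AZA"].matrix(0, 30.0)
        idx = {s: k for k, s in enumerate(MAINTENANCE_STATES)}
        r = idx["relapse_mmf"]
        assert mat[r, idx["remission_post_mmf"]] == pytest.approx(0.59)
        assert mat[r, idx["death"]] == pytest.approx(0.041)
        assert mat[r, idx["esrd"]] == pytest.approx(0.061)
        assert mat[r, idx["relapse_cyc"]] == pytest.approx(1 - 0.59 - 0.041 - 0.061)
        c = idx["relapse_cyc"]
        assert mat[c, idx["remission_post_cyc"]] == pytest.approx(0.522)
        assert mat[c, c] == pytest.approx(1 - 0.522 - 0.040 - 0.0855)
        assert mat[idx["esrd"], idx["death"]] == pytest.approx(0.0513)

    def test_aza_first_cycle_expected_cost_is_hand_sum(self, specs):
        # drug + direct + indirect + expected infection cost, from remission
        tr = run_cohort(specs["AZA"], init_vector(), 1, 30.0, time_offset=0.0)
        hand = 769.86 + 1684.17 + 8033.19 + 0.0138 * 17_183.0
        assert tr.total_cost_undisc == pytest.approx(hand, rel=1e-12)

    def test_rescue_policy_prices_the_rescue_state(self, params):
        base = build_maintenance_model(Arm("AZA"), params)
        esc = build_maintenance_model(
            Arm("AZA", RescuePolicy(aza_rescue_drug="mmf3")), params)
        assert base.costs["relapse_mmf"] == pytest.approx(
            4833.92 + 3243.43 + 8564.07)
        assert esc.costs["relapse_mmf"] - base.costs["relapse_mmf"] == \
            pytest.approx(7250.88 - 4833.92)
        # MMF-maintained patients escalate to 3 g/day
        mmf = build_maintenance_model(Arm("MMF"), params)
        assert mmf.costs["relapse_mmf"] == pytest.approx(
            7250.88 + 3243.43 + 8564.07)

    def test_post_cyc_maintenance_switch(self, params):
        aza_after = build_maintenance_model(
            Arm("AZA", RescuePolicy(post_cyc_maintenance="aza")), params)
        default = build_maintenance_model(Arm("AZA"), params)
        assert default.costs["remission_post_cyc"] == pytest.approx(
            4833.92 + 1684.17 + 8033.19)
        assert aza_after.costs["remission_post_cyc"] == pytest.approx(
            769.86 + 1684.17 + 8033.19)
        # the resumed drug also drives the state's transition probabilities
        i = MAINTENANCE_STATES.index("remission_post_cyc")
        j = MAINTENANCE_STATES.index("relapse_mmf")
        assert aza_after.matrix(0, 30.0)[i, j] == pytest.approx(0.0364)
        assert default.matrix(0, 30.0)[i, j] == pytest.approx(0.0185)

    def test_missing_parameter_is_named(self, params):
        v = params.means()
        del v["cost_drug_cyc"]
        with pytest.raises(KeyError, match="cost_drug_cyc"):
            build_maintenance_model(Arm("AZA"), params, v)

    def test_mmf_reaches_esrd_less_often_over_three_years(self, specs):
        occ = {}
        for label, spec in specs.items():
            occ[label] = run_cohort(spec, init_vector(), 6, 30.0).final_occupancy
        i = MAINTENANCE_STATES.index("esrd")
        assert occ["MMF"][i] < occ["AZA"][i]

    def test_cohort_results_are_reproducible(self, three_year):
        a = three_year.outcomes()
        b = three_year.outcomes()
        for label in a:
            assert a[label] == b[label]  # bitwise identical


class TestMortalityOperations:
    def test_relapse_mortality_closed_form(self):
        table = flat_table(0.001)
        assert lupus_mortality(40, "relapse", "MMF", table) == \
            pytest.approx(0.007873, abs=5e-7)

    def test_remission_mortality_footnote_arithmetic(self):
        table = flat_table(0.001)
        mmf = lupus_mortality(40, "remission", "MMF", table)
        assert mmf == pytest.approx(0.007873 / 9.3, abs=5e-7)
        aza = lupus_mortality(40, "remission", "AZA", table)
        assert aza / mmf == pytest.approx(0.58, rel=1e-12)

    def test_remission_to_relapse_ratio_constant_in_age(self, life_table):
        for age in range(25, 80, 5):
            rel = lupus_mortality(age, "relapse", "MMF", life_table)
            rem = lupus_mortality(age, "remission", "MMF", life_table)
            assert rel / rem == pytest.approx(9.3, rel=1e-12)

    def test_esrd_mortality_closed_form_and_identity(self):
        table = flat_table(0.10)
        # rate-scale hazard scaling: 1 - (1 - q)^hr
        assert esrd_mortality(40, table) == pytest.approx(1.0 - 0.9 ** 1.7,
                                                          rel=1e-12)
        assert esrd_mortality(40, table, hr=1.0) == pytest.approx(0.10)

    def test_esrd_mortality_monotone_when_table_is(self, dialysis_table):
        qs = [esrd_mortality(a, dialysis_table) for a in range(25, 80)]
        assert all(a < b for a, b in zip(qs, qs[1:]))

    def test_age_outside_span_raises(self):
        with pytest.raises(ValueError, match="span"):
            flat_table(0.001, ages=(30, 40)).q(80)


class TestLifetimeModel:
    def test_published_annual_probabilities(self, params, life_table, dialysis_table):
        idx = {s: k for k, s in enumerate(LIFETIME_STATES)}
        for label, relapse_p, esrd_p in [("AZA", 0.0716, 0.0061),
                                         ("MMF", 0.0367, 0.0025)]:
            spec = build_lifetime_model(Arm(label), params, life_table,
                                        dialysis_table)
            mat = spec.matrix(0, 33.0)
            assert mat[idx["remission"], idx["relapse"]] == pytest.approx(relapse_p)
            assert mat[idx["remission"], idx["esrd"]] == pytest.approx(esrd_p)

    def test_relapse_row_identical_across_arms(self, params, life_table, dialysis_table):
        idx = {s: k for k, s in enumerate(LIFETIME_STATES)}
        rows = [build_lifetime_model(Arm(label), params, life_table,
                                     dialysis_table).matrix(0, 33.0)[idx["relapse"]]
                for label in ("AZA", "MMF")]
        assert np.allclose(rows[0], rows[1])
        assert rows[0][idx["remission"]] == pytest.approx(0.8319)
        assert rows[0][idx["esrd"]] == pytest.approx(0.1183)

    def test_no_effect_scenario_forces_relapse(self, params, life_table, dialysis_table):
        idx = {s: k for k, s in enumerate(LIFETIME_STATES)}
        spec = build_lifetime_model(Arm("MMF"), params, life_table,
                                    dialysis_table, scenario="no_effect")
        mat = spec.matrix(0, 33.0)
        # competing mortality/ESRD keep the row on the simplex; relapse
        # absorbs everything else
        assert mat[idx["remission"], idx["relapse"]] > 0.99
        assert mat[idx["remission"], idx["remission"]] == pytest.approx(0.0, abs=1e-12)

    def test_decay_scenario_compounds_from_phase_start(self, params, life_table,
                                                       dialysis_table):
        idx = {s: k for k, s in enumerate(LIFETIME_STATES)}
        spec = build_lifetime_model(Arm("MMF"), params, life_table,
                                    dialysis_table, scenario="decay_1pct")
        p0 = spec.matrix(0, 33.0)[idx["remission"], idx["relapse"]]
        p10 = spec.matrix(10, 43.0)[idx["remission"], idx["relapse"]]
        assert p0 == pytest.approx(0.0367)
        assert p10 == pytest.approx(0.0367 * 1.01 ** 10, rel=1e-12)

    def test_apply_extrapolation_switches_rule_only(self):
        base = LifetimeScenario(esrd_increment_per_year=0.005)
        out = apply_extrapolation("decay_2pct", base)
        assert out.extrapolation == "decay_2pct"
        assert out.esrd_increment_per_year == 0.005
        with pytest.raises(ValueError, match="unknown"):
            apply_extrapolation("bogus")

    def test_no_drug_costs_after_maintenance(self, params, life_table, dialysis_table):
        spec = build_lifetime_model(Arm("MMF"), params, life_table, dialysis_table)
        assert spec.costs["remission"] == pytest.approx(3368.34 + 16066.38)
        assert spec.costs["relapse"] == pytest.approx(6486.85 + 17128.13)
        assert spec.costs["esrd"] == pytest.approx(86_608.0)
        assert spec.events == {}


class TestPhaseLink:
    def test_pure_remission_maps_to_pure_remission(self, params):
        spec = build_maintenance_model(Arm("MMF"), params)
        # absorbing start: kill all transitions by running zero-risk chain
        tr = run_cohort(spec, init_vector(), 6, 30.0)
        link = link_phases(tr)
        assert link.occupancy.sum() == pytest.approx(1.0, abs=1e-12)
        assert link.age == pytest.approx(33.0)
        assert link.time_offset == pytest.approx(3.0)

    def test_mapping_merges_states_by_hand(self, params):
        spec = build_maintenance_model(Arm("AZA"), params)
        tr = run_cohort(spec, init_vector(), 6, 30.0)
        link = link_phases(tr)
        final = tr.final_occupancy
        idx = {s: k for k, s in enumerate(MAINTENANCE_STATES)}
        assert link.occupancy[LIFETIME_STATES.index("remission")] == pytest.approx(
            final[idx["remission_maintenance"]] + final[idx["remission_post_mmf"]]
            + final[idx["remission_post_cyc"]])
        assert link.occupancy[LIFETIME_STATES.index("relapse")] == pytest.approx(
            final[idx["relapse_mmf"]] + final[idx["relapse_cyc"]])
        assert link.occupancy[LIFETIME_STATES.index("death")] == pytest.approx(
            final[idx["death"]])

    def test_accumulators_carried_forward(self, params):
        spec = build_maintenance_model(Arm("AZA"), params)
        tr = run_cohort(spec, init_vector(), 6, 30.0)
        link = link_phases(tr)
        assert link.cost_disc == pytest.approx(tr.total_cost_disc)
        assert link.qaly_disc == pytest.approx(tr.total_qaly_disc)


class TestLifetimeEvaluator:
    def test_totals_include_maintenance_phase(self, lifetime, three_year):
        full = lifetime.outcomes()
        short = three_year.outcomes()
        for label in ("AZA", "MMF"):
            assert full[label][0] > short[label][0]
            assert full[label][1] > short[label][1]

    def test_mmf_gains_qalys_over_lifetime(self, lifetime):
        out = lifetime.outcomes()
        assert out["MMF"][1] - out["AZA"][1] > 0.3

    def test_three_year_evaluator_rejects_lifetime_overrides(self, three_year):
        with pytest.raises(KeyError):
            ThreeYearEvaluator(three_year.params).outcomes(
                overrides={"no_such": 1.0})
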