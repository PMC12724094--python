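"""Deterministic therapy-cost scenarios and their closed-form properties."""

import numpy as np
import pandas as pd
import pytest

from trialcea.inference import ImputationConfig, run_main_analysis
from trialcea.sensitivity import (
    BASE_SCENARIO,
    ScenarioSpec,
    apply_scenario,
    default_scenarios,
    scenario_icer_table,
)
from trialcea.trial_data import default_unit_costs


@pytest.fixture(scope="module")
def scenario_table_complete(bundle_complete):
    """Default scenario grid on the no-missingness synthetic trial."""
    b = bundle_complete
    from trialcea.qaly import crosswalk_value_set, qaly_table
    qalys = qaly_table(b.eq5d, crosswalk_value_set())
    return scenario_icer_table(
        b.service_use, b.therapy, b.roster, qalys, b.config.unit_costs,
        imputation=ImputationConfig(m=2, seed=77))


def test_base_scenario_is_identity():
    table = default_unit_costs()
    same = apply_scenario(table, BASE_SCENARIO)
    assert same.therapist_session_cost == table.therapist_session_cost
    assert same.fixed_tech_cost == table.fixed_tech_cost
    assert same.contact_costs == table.contact_costs


def test_multiplier_halves_session_cost():
    table = default_unit_costs()
    half = apply_scenario(table, ScenarioSpec("half", 50.0, 0.5))
    assert half.therapist_session_cost == pytest.approx(
        table.therapist_session_cost / 2)
    # 82.3 GBP/session at base -> 41.2 at half rate
    assert table.therapist_session_cost == pytest.approx(82.3, abs=0.1)
    assert half.therapist_session_cost == pytest.approx(41.2, abs=0.1)


def test_fixed_cost_scenario_touches_only_fixed_component():
    table = default_unit_costs()
    mod = apply_scenario(table, ScenarioSpec("fixed150", 150.0, 1.0))
    assert mod.fixed_tech_cost == 150.0
    assert mod.therapist_session_cost == table.therapist_session_cost
    assert mod.inpatient_per_diem == table.inpatient_per_diem
    assert mod.contact_costs == table.contact_costs


def test_negative_multiplier_rejected():
    with pytest.raises(ValueError):
        ScenarioSpec("bad", 50.0, -0.5)


def test_default_grid_contains_base_and_all_scenarios():
    grid = default_scenarios()
    assert grid[0] == BASE_SCENARIO
    assert {s.fixed_tech_cost for s in grid} == {25, 50, 75, 100, 125, 150}
    assert {s.therapist_multiplier for s in grid} == {0.5, 0.75, 1.0, 1.25, 1.5}


def test_delta_qaly_constant_across_scenarios(scenario_table_complete):
    for _, group in scenario_table_complete.groupby("comparison"):
        assert group["delta_qaly"].nunique() == 1


def test_fixed_cost_icer_shift_closed_form(scenario_table_complete):
    """ICER(fixed=75) - ICER(fixed=50) = 25 / dQALY exactly (NE quadrant)."""
    t = scenario_table_complete
    for comparison in t["comparison"].unique():
        sel = t[t["comparison"] == comparison].set_index("scenario")
        dq = sel.loc["base", "delta_qaly"]
        # cost deltas shift by exactly the fixed-cost change
        assert sel.loc["fixed_75", "delta_cost"] - sel.loc["base", "delta_cost"] \
            == pytest.approx(25.0, abs=1e-9)
        if (sel.loc["fixed_75", "decision"] == "icer_NE"
                and sel.loc["base", "decision"] == "icer_NE"):
            assert sel.loc["fixed_75", "icer"] - sel.loc["base", "icer"] \
                == pytest.approx(25.0 / dq, rel=1e-12)


def test_therapist_multiplier_shifts_cost_by_arm_mean_change(
        scenario_table_complete, bundle_complete):
    """Therapist-cost scenarios shift the incremental cost by exactly the
    mean intervention-arm therapist-cost change."""
    t = scenario_table_complete
    session_cost = bundle_complete.config.unit_costs.therapist_session_cost
    sessions = {}
    for rec in bundle_complete.therapy:
        sessions.setdefault(rec.arm.value, []).append(rec.sessions)
    for comparison, arm in (("BRF_vs_TAU", "AV-BRF"), ("EXT_vs_TAU", "AV-EXT")):
        sel = t[t["comparison"] == comparison].set_index("scenario")
        mean_sessions = np.mean(sessions[arm])
        for mult in (0.5, 1.5):
            expected_shift = (mult - 1.0) * mean_sessions * session_cost
            shift = (sel.loc[f"therapist_x{mult:g}", "delta_cost"]
                     - sel.loc["base", "delta_cost"])
            assert shift == pytest.approx(expected_shift, abs=1e-9)


def test_icer_monotone_in_therapy_costs(scenario_table_complete):
    """Within the NE quadrant the ICER rises with the fixed cost and with
    the therapist multiplier (dQALY is fixed)."""
    t = scenario_table_complete
    for _, group in t.groupby("comparison"):
        fixed = group[group["therapist_multiplier"] == 1.0].sort_values(
            "fixed_tech_cost")
        ne = fixed[fixed["decision"] == "icer_NE"]
        assert ne["icer"].is_monotonic_increasing
        mult = group[group["fixed_tech_cost"] == 50.0].sort_values(
            "therapist_multiplier")
        ne = mult[mult["decision"] == "icer_NE"]
        assert ne["icer"].is_monotonic_increasing


def test_dominance_flip_threshold(scenario_table_complete):
    """A dominant comparison flips to icer_NE exactly when the therapy-cost
    increase exceeds the base-case saving."""
    t = scenario_table_complete
    for _, group in t.groupby("comparison"):
        base_dc = group.set_index("scenario").loc["base", "delta_cost"]
        for row in group.itertuples():
            shift = row.delta_cost - base_dc
            if row.delta_qaly > 0:
                expected = "icer_NE" if base_dc + shift > 0 else "dominant"
                assert row.decision == expected


def test_base_row_reproduces_main_analysis(bundle_complete):
    """A scenario grid containing only the base case equals the main
    MI+SUR analysis row exactly."""
    from trialcea.qaly import crosswalk_value_set, qaly_table
    b = bundle_complete
    qalys = qaly_table(b.eq5d, crosswalk_value_set())
    imp = ImputationConfig(m=2, seed=5)
    table = scenario_icer_table(b.service_use, b.therapy, b.roster, qalys,
                                b.config.unit_costs, [BASE_SCENARIO],
                                imputation=imp)
    main = run_main_analysis(b.analysis_dataset(), imp)
    for est in main.mi_estimates:
        row = table[table["comparison"] == est.comparison].iloc[0]
        assert row["delta_cost"] == pytest.approx(est.delta_cost, abs=1e-9)
        assert row["delta_qaly"] == pytest.approx(est.delta_qaly, abs=1e-12)


def test_offset_and_refit_engines_agree_without_missingness(bundle_complete):
    """With no missing data the exact-offset engine and a full re-run agree
    for fixed-cost scenarios (the shift is collinear with the arm
    indicators)."""
    from trialcea.qaly import crosswalk_value_set, qaly_table
    b = bundle_complete
    qalys = qaly_table(b.eq5d, crosswalk_value_set())
    imp = ImputationConfig(m=2, seed=5)
    scenarios = [BASE_SCENARIO, ScenarioSpec("fixed_100", 100.0, 1.0)]
    offset = scenario_icer_table(b.service_use, b.therapy, b.roster, qalys,
                                 b.config.unit_costs, scenarios,
                                 imputation=imp, engine="offset")
    refit = scenario_icer_table(b.service_use, b.therapy, b.roster, qalys,
                                b.config.unit_costs, scenarios,
                                imputation=imp, engine="refit")
    merged = offset.merge(refit, on=["scenario", "comparison"],
                          suffixes=("_o", "_r"))
    np.testing.assert_allclose(merged["delta_cost_o"], merged["delta_cost_r"],
                               atol=1e-6)
    np.testing.assert_allclose(merged["delta_qaly_o"], merged["delta_qaly_r"],
                               atol=1e-12)
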