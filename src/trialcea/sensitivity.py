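"""Deterministic sensitivity analyses on the therapy-cost assumptions.

Two families of scenarios are examined around the base case (fixed technology
cost 50 GBP per therapy recipient, therapist cost multiplier 1.0): varying
the fixed element (25..150 GBP) and scaling the therapist session cost by
0.5..1.5 (staff of different grades / extra non-contact time).

Therapy cost is a deterministic linear functional of each participant's
observed session count, so changing its assumptions shifts every
intervention-arm participant's follow-up cost by a known amount and leaves
utilities untouched.  The default scenario engine therefore shifts the
estimated incremental cost by the arm-mean therapy-cost change, exactly:
incremental QALYs are identical across scenarios, ICER(fixed=75) -
ICER(fixed=50) = 25/dQALY exactly, and a dominant comparison flips to a
positive ICER exactly when the added therapy cost exceeds the base-case
saving.  A ``refit`` engine that re-runs the full MI+SUR pipeline per
scenario (sharing the master seed so imputation draws are common) is
available for cross-checking; it adds only imputation/regression noise
around the same shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .costing import participant_cost_table, therapy_cost
from .inference import (
    ImputationConfig,
    IncrementalEstimate,
    MainAnalysisResult,
    assemble_analysis_dataset,
    classify_decision,
    run_main_analysis,
)
from .trial_data import Arm, COMPARISONS, TherapyRecord, UnitCostTable

__all__ = [
    "ScenarioSpec",
    "default_scenarios",
    "apply_scenario",
    "scenario_icer_table",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """One deterministic sensitivity scenario.

    fixed_tech_cost replaces the per-recipient technology charge;
    therapist_multiplier scales the per-session therapist cost.  The base
    case is (50, 1.0).
    """

    label: str
    fixed_tech_cost: float = 50.0
    therapist_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.therapist_multiplier < 0:
            raise ValueError("therapist multiplier must be non-negative")
        if self.fixed_tech_cost < 0:
            raise ValueError("fixed technology cost must be non-negative")


BASE_SCENARIO = ScenarioSpec("base", 50.0, 1.0)


def default_scenarios() -> list[ScenarioSpec]:
    """Base case, fixed-cost grid 25..150, therapist multipliers 0.5..1.5."""
    out = [BASE_SCENARIO]
    out += [ScenarioSpec(f"fixed_{int(f)}", float(f), 1.0)
            for f in (25, 75, 100, 125, 150)]
    out += [ScenarioSpec(f"therapist_x{m:g}", 50.0, m)
            for m in (0.5, 0.75, 1.25, 1.5)]
    return out


def apply_scenario(unit_costs: UnitCostTable,
                   scenario: ScenarioSpec) -> UnitCostTable:
    """Scenario-modified unit-cost table; all non-therapy costs untouched."""
    return UnitCostTable(
        contact_costs=dict(unit_costs.contact_costs),
        inpatient_per_diem=unit_costs.inpatient_per_diem,
        therapist_session_rate=(unit_costs.therapist_session_rate
                                * scenario.therapist_multiplier),
        non_contact_uplift=unit_costs.non_contact_uplift,
        fixed_tech_cost=scenario.fixed_tech_cost,
        price_year=unit_costs.price_year,
    )


def _arm_mean_therapy_delta(
    therapy: Sequence[TherapyRecord],
    base_costs: UnitCostTable,
    scenario: ScenarioSpec,
    charge_fixed_without_sessions: bool = True,
) -> dict[str, float]:
    """Mean per-participant therapy-cost change per arm under a scenario."""
    new_costs = apply_scenario(base_costs, scenario)
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for rec in therapy:
        delta = (therapy_cost(rec, new_costs, charge_fixed_without_sessions)
                 - therapy_cost(rec, base_costs, charge_fixed_without_sessions))
        sums[rec.arm.value] = sums.get(rec.arm.value, 0.0) + delta
        counts[rec.arm.value] = counts.get(rec.arm.value, 0) + 1
    return {arm: sums.get(arm, 0.0) / counts[arm] for arm in counts}


def scenario_icer_table(
    service_use,
    therapy: Sequence[TherapyRecord],
    roster: pd.DataFrame,
    qaly_frame: pd.DataFrame,
    unit_costs: UnitCostTable,
    scenarios: Sequence[ScenarioSpec] | None = None,
    imputation: ImputationConfig | None = None,
    include_site_in_qaly: bool = True,
    engine: str = "offset",
    base_result: MainAnalysisResult | None = None,
) -> pd.DataFrame:
    """Re-evaluate incremental estimates under each therapy-cost scenario.

    ``engine='offset'`` (default): run the MI+SUR pipeline once under the
    base-case unit costs, then shift each comparison's incremental cost by
    the exact arm-mean therapy-cost change implied by the scenario (therapy
    cost is deterministic given observed sessions).  ``engine='refit'``:
    recompute costs and re-run the full pipeline per scenario with the same
    imputation seed.
    """
    scenarios = list(scenarios) if scenarios is not None else default_scenarios()
    imputation = imputation or ImputationConfig()
    rows = []

    if engine == "offset":
        if base_result is None:
            base_cost_table = participant_cost_table(service_use, therapy,
                                                     roster, unit_costs)
            base_df = assemble_analysis_dataset(roster, base_cost_table,
                                                qaly_frame)
            base_result = run_main_analysis(base_df, imputation,
                                            include_site_in_qaly)
        base_est = {e.comparison: e for e in base_result.mi_estimates}
        for scen in scenarios:
            deltas = _arm_mean_therapy_delta(therapy, unit_costs, scen)
            for label, arm in COMPARISONS:
                est = base_est[label]
                shift = deltas.get(arm.value, 0.0)
                dc = est.delta_cost + shift
                dec = classify_decision(dc, est.delta_qaly)
                rows.append(_row(scen, label, dc,
                                 (est.ci_cost[0] + shift, est.ci_cost[1] + shift),
                                 est.delta_qaly, est.ci_qaly, dec))
    elif engine == "refit":
        for scen in scenarios:
            scen_costs = apply_scenario(unit_costs, scen)
            cost_table = participant_cost_table(service_use, therapy, roster,
                                                scen_costs)
            df = assemble_analysis_dataset(roster, cost_table, qaly_frame)
            result = run_main_analysis(df, imputation, include_site_in_qaly)
            for est in result.mi_estimates:
                dec = result.decisions[(est.method, est.comparison)]
                rows.append(_row(scen, est.comparison, est.delta_cost,
                                 est.ci_cost, est.delta_qaly, est.ci_qaly, dec))
    else:
        raise ValueError(f"unknown scenario engine {engine!r}")
    return pd.DataFrame(rows)


def _row(scen, comparison, dc, ci_c, dq, ci_q, dec) -> dict:
    return {
        "scenario": scen.label,
        "fixed_tech_cost": scen.fixed_tech_cost,
        "therapist_multiplier": scen.therapist_multiplier,
        "comparison": comparison,
        "delta_cost": dc,
        "cost_ci_lo": ci_c[0],
        "cost_ci_hi": ci_c[1],
        "delta_qaly": dq,
        "qaly_ci_lo": ci_q[0],
        "qaly_ci_hi": ci_q[1],
        "decision": dec.decision,
        "icer": dec.icer if dec.icer is not None else np.nan,
    }
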