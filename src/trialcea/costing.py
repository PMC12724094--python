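"""Per-participant, per-period costs from the health and social care perspective.

Costing is an exact linear operation: community cost sums contacts times
per-contact unit costs over non-inpatient services, in-patient cost is days
times a per-diem, and therapy cost for intervention-arm participants is
attended sessions times the (uplifted) therapist session cost plus a fixed
technology charge per recipient.  Baseline-period costs are never part of the
follow-up outcome — they enter the analysis only as a covariate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .trial_data import (
    Arm,
    INPATIENT_SERVICE,
    INTERVENTION_ARMS,
    PERIOD_LABELS,
    ServiceContactRecord,
    TherapyRecord,
    UnitCostTable,
)

__all__ = [
    "ParticipantCosts",
    "cost_components",
    "therapy_cost",
    "total_followup_cost",
    "participant_cost_table",
    "group_cost_summary",
]


@dataclass(frozen=True)
class ParticipantCosts:
    """Cost components for one participant in one recall period (GBP)."""

    participant_id: str
    period: str
    community_cost: float
    inpatient_cost: float
    therapy_cost: float

    @property
    def total(self) -> float:
        return self.community_cost + self.inpatient_cost + self.therapy_cost


def cost_components(
    records: Iterable[ServiceContactRecord],
    unit_costs: UnitCostTable,
    participant_id: str = "",
    period: str = "",
) -> ParticipantCosts:
    """Cost the service use of one participant x period (therapy excluded).

    Raises ``KeyError`` naming the service if any used service has no unit
    cost; costs are never silently zero.
    """
    community = 0.0
    inpatient = 0.0
    for rec in records:
        participant_id = participant_id or rec.participant_id
        period = period or rec.period
        if rec.service == INPATIENT_SERVICE:
            inpatient += rec.inpatient_days * unit_costs.inpatient_per_diem
        else:
            community += rec.contact_count * unit_costs.cost_for(rec.service)
    return ParticipantCosts(participant_id, period, community, inpatient, 0.0)


def therapy_cost(
    record: TherapyRecord,
    unit_costs: UnitCostTable,
    charge_fixed_without_sessions: bool = True,
) -> float:
    """Therapy cost: sessions x uplifted session cost + fixed technology cost.

    TAU participants cost 0.  The fixed charge applies once per
    intervention-arm participant ("per recipient of therapy"); set
    ``charge_fixed_without_sessions=False`` to restrict it to participants who
    attended at least one session.
    """
    if record.arm is Arm.TAU:
        return 0.0
    fixed = unit_costs.fixed_tech_cost
    if record.sessions == 0 and not charge_fixed_without_sessions:
        fixed = 0.0
    return record.sessions * unit_costs.therapist_session_cost + fixed


def total_followup_cost(w16_total: float, w28_total: float) -> float:
    """Sum of the two follow-up period totals; missing (NaN) propagates."""
    if math.isnan(w16_total) or math.isnan(w28_total):
        return math.nan
    return w16_total + w28_total


def participant_cost_table(
    service_use: Sequence[ServiceContactRecord],
    therapy: Sequence[TherapyRecord],
    roster: pd.DataFrame,
    unit_costs: UnitCostTable,
    charge_fixed_without_sessions: bool = True,
) -> pd.DataFrame:
    """Long cost table: one row per participant x period with components.

    Periods the participant did not attend (per the roster flags) get NaN
    components — missing service use is distinct from zero use.  Therapy cost
    is charged in the w16 period (therapy is delivered during the treatment
    phase, which ends at the 16-week assessment).
    """
    comp: dict[tuple[str, str], list[float]] = {}
    for rec in service_use:
        key = (rec.participant_id, rec.period)
        c = comp.setdefault(key, [0.0, 0.0])
        if rec.service == INPATIENT_SERVICE:
            c[1] += rec.inpatient_days * unit_costs.inpatient_per_diem
        else:
            c[0] += rec.contact_count * unit_costs.cost_for(rec.service)

    tcost = {
        r.participant_id: therapy_cost(r, unit_costs, charge_fixed_without_sessions)
        for r in therapy
    }
    attended_col = {"baseline": "attended_baseline", "w16": "attended_w16",
                    "w28": "attended_w28"}
    rows = []
    for r in roster.itertuples(index=False):
        for period in PERIOD_LABELS:
            if not getattr(r, attended_col[period]):
                rows.append((r.participant_id, r.arm, r.site, period,
                             np.nan, np.nan, np.nan, np.nan))
                continue
            community, inpatient = comp.get((r.participant_id, period), (0.0, 0.0))
            ther = tcost.get(r.participant_id, 0.0) if period == "w16" else 0.0
            rows.append((r.participant_id, r.arm, r.site, period,
                         community, inpatient, ther,
                         community + inpatient + ther))
    return pd.DataFrame(
        rows,
        columns=["participant_id", "arm", "site", "period", "community_cost",
                 "inpatient_cost", "therapy_cost", "total_cost"],
    )


def group_cost_summary(cost_table: pd.DataFrame) -> pd.DataFrame:
    """Mean (s.d.) cost components by arm and period over attended periods."""
    value_cols = ["community_cost", "inpatient_cost", "therapy_cost", "total_cost"]
    grouped = cost_table.groupby(["arm", "period"], sort=True)[value_cols]
    out = grouped.agg(["mean", "std", "count"])
    out.columns = ["_".join(c) for c in out.columns]
    return out.reset_index()
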