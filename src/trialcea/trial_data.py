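"""Domain types, CSV I/O and validation for participant-level trial inputs.

The economic evaluation consumes four participant-level tables plus a unit-cost
table, all plain UTF-8 CSV with a header row:

``roster.csv``
    One row per randomised participant: ``participant_id, arm, site`` plus
    optional boolean columns ``attended_baseline, attended_w16, attended_w28``
    marking whether the service-use interview took place at each assessment.
    A participant present at an assessment with no service rows used *zero*
    services; a participant absent from the assessment has *missing* costs for
    that period.
``service_use.csv``
    One row per participant x period x service with a non-zero contact count
    (``participant_id, period, service, contact_count, inpatient_days``).
``therapy.csv``
    ``participant_id, arm, sessions`` — attended avatar dialogue sessions.
``eq5d.csv``
    ``participant_id, week, mobility, self_care, usual_activities,
    pain_discomfort, anxiety_depression`` with levels 1..5; an absent row for a
    week means the questionnaire is missing at that timepoint.

All money is GBP at 2021/22 prices; the 28-week horizon needs no discounting.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Arm",
    "Period",
    "BASELINE",
    "W16",
    "W28",
    "FOLLOWUP_PERIODS",
    "DEFAULT_SERVICES",
    "INPATIENT_SERVICE",
    "ServiceContactRecord",
    "TherapyRecord",
    "EQ5DResponse",
    "UnitCostTable",
    "default_unit_costs",
    "ValidationError",
    "ValidationReport",
    "load_roster",
    "load_service_use",
    "load_therapy",
    "load_eq5d",
    "load_unit_costs",
    "write_roster",
    "write_service_use",
    "write_therapy",
    "write_eq5d",
    "write_unit_costs",
    "validate_dataset",
]


class Arm(str, enum.Enum):
    """Randomisation arm; TAU (treatment as usual) is always the comparator."""

    TAU = "TAU"
    AV_BRF = "AV-BRF"
    AV_EXT = "AV-EXT"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


INTERVENTION_ARMS: tuple[Arm, Arm] = (Arm.AV_BRF, Arm.AV_EXT)

#: comparisons reported by the analysis; the two therapy arms are never
#: compared directly with each other.
COMPARISONS: tuple[tuple[str, Arm], ...] = (
    ("BRF_vs_TAU", Arm.AV_BRF),
    ("EXT_vs_TAU", Arm.AV_EXT),
)


@dataclass(frozen=True)
class Period:
    """An assessment recall period.

    ``baseline`` covers a recall window before randomisation (default 12
    weeks, configurable); ``w16`` covers weeks (0, 16]; ``w28`` covers weeks
    (16, 28], so the two follow-up spans sum to the 28-week horizon.
    """

    label: str
    span_weeks: float

    def __post_init__(self) -> None:
        if self.span_weeks < 0:
            raise ValueError("period span must be non-negative")

    @property
    def span_days(self) -> float:
        return self.span_weeks * 7.0


BASELINE = Period("baseline", 12.0)
W16 = Period("w16", 16.0)
W28 = Period("w28", 12.0)
FOLLOWUP_PERIODS: tuple[Period, Period] = (W16, W28)
PERIOD_LABELS = ("baseline", "w16", "w28")


def make_periods(baseline_recall_weeks: float = 12.0) -> dict[str, Period]:
    """Period vocabulary with a configurable baseline recall window."""
    return {
        "baseline": Period("baseline", baseline_recall_weeks),
        "w16": W16,
        "w28": W28,
    }


INPATIENT_SERVICE = "inpatient_mental_health"

#: community/primary-care services shipped by default (extensible via aliases)
DEFAULT_SERVICES: tuple[str, ...] = (
    "gp",
    "psychiatrist",
    "mental_health_nurse",
    "psychologist",
    "early_intervention_team",
    "social_worker",
    "other_community",
    INPATIENT_SERVICE,
)


@dataclass(frozen=True)
class ServiceContactRecord:
    """One participant x period x service utilisation row."""

    participant_id: str
    period: str
    service: str
    contact_count: int
    inpatient_days: float = 0.0

    def __post_init__(self) -> None:
        if self.contact_count < 0:
            raise ValueError("contact_count must be non-negative")
        if self.inpatient_days < 0:
            raise ValueError("inpatient_days must be non-negative")
        if self.service != INPATIENT_SERVICE and self.inpatient_days != 0:
            raise ValueError("non-inpatient rows must have inpatient_days = 0")


@dataclass(frozen=True)
class TherapyRecord:
    """Attended avatar dialogue sessions for one participant."""

    participant_id: str
    arm: Arm
    sessions: int

    def __post_init__(self) -> None:
        if self.sessions < 0:
            raise ValueError("sessions must be non-negative")
        if self.arm is Arm.TAU and self.sessions > 0:
            raise ValueError("TAU participants receive no avatar therapy")


EQ5D_DOMAINS = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)


@dataclass(frozen=True)
class EQ5DResponse:
    """Five-domain health questionnaire response at one timepoint.

    ``levels`` is a 5-tuple of integers 1..5 in domain order (mobility,
    self-care, usual activities, pain/discomfort, anxiety/depression), or
    ``None`` when the questionnaire is wholly missing.
    """

    participant_id: str
    week: int
    levels: tuple[int, int, int, int, int] | None

    def __post_init__(self) -> None:
        if self.week not in (0, 16, 28):
            raise ValueError(f"week must be one of 0/16/28, got {self.week}")
        if self.levels is not None:
            if len(self.levels) != 5:
                raise ValueError("levels must have exactly 5 entries")
            for lv in self.levels:
                if not (1 <= int(lv) <= 5):
                    raise ValueError(f"EQ-5D level out of range 1..5: {lv}")

    @property
    def missing(self) -> bool:
        return self.levels is None


class ValidationError(ValueError):
    """Raised for malformed input tables; carries offending row numbers."""

    def __init__(self, message: str, rows: Sequence[int] = ()) -> None:
        self.rows = list(rows)
        if self.rows:
            message = f"{message} (rows {self.rows})"
        super().__init__(message)


@dataclass
class UnitCostTable:
    """Unit costs applied to service use, GBP at a single price year.

    ``therapist_session_rate`` is the per-session staff rate (senior
    clinical band) before the non-contact-time uplift; the applied cost per
    session is ``rate * non_contact_uplift``.  ``fixed_tech_cost`` is the
    hardware/software/maintenance charge per recipient of therapy.
    """

    contact_costs: dict[str, float]
    inpatient_per_diem: float
    therapist_session_rate: float
    non_contact_uplift: float = 1.51
    fixed_tech_cost: float = 50.0
    price_year: str = "2021/22"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.non_contact_uplift < 1:
            raise ValueError("non-contact uplift factor must be >= 1")
        if self.inpatient_per_diem < 0 or self.therapist_session_rate < 0:
            raise ValueError("unit costs must be non-negative")
        if self.fixed_tech_cost < 0:
            raise ValueError("fixed technology cost must be non-negative")
        for svc, c in self.contact_costs.items():
            if c < 0:
                raise ValueError(f"negative unit cost for service {svc!r}")

    @property
    def therapist_session_cost(self) -> float:
        """Applied cost per attended session, including non-contact uplift."""
        return self.therapist_session_rate * self.non_contact_uplift

    def cost_for(self, service: str) -> float:
        if service == INPATIENT_SERVICE:
            return self.inpatient_per_diem
        try:
            return self.contact_costs[service]
        except KeyError:
            raise KeyError(
                f"no unit cost defined for service {service!r}; add it to the "
                "unit-cost table (costs are never silently zero)"
            ) from None


def default_unit_costs() -> UnitCostTable:
    """Representative NHS 2021/22 unit costs shipped as defaults.

    These are documented, representative values for the shipped service
    vocabulary, not a published reference schedule; override any of them via
    ``unit_costs.csv``.  The therapist rate is calibrated so that a mean
    therapy dose of ~5 sessions costs roughly 420 GBP of therapist time and
    ~8 sessions roughly 670 GBP, consistent with a senior-band professional
    with a 51% non-contact uplift.
    """
    return UnitCostTable(
        contact_costs={
            "gp": 41.0,
            "psychiatrist": 239.0,
            "mental_health_nurse": 54.0,
            "psychologist": 93.0,
            "early_intervention_team": 84.0,
            "social_worker": 87.0,
            "other_community": 60.0,
        },
        inpatient_per_diem=341.0,
        therapist_session_rate=54.5,
        non_contact_uplift=1.51,
        fixed_tech_cost=50.0,
        price_year="2021/22",
    )


# ---------------------------------------------------------------------------
# loaders / writers
# ---------------------------------------------------------------------------

_ROSTER_COLS = ["participant_id", "arm", "site",
                "attended_baseline", "attended_w16", "attended_w28"]
_SERVICE_COLS = ["participant_id", "period", "service",
                 "contact_count", "inpatient_days"]
_THERAPY_COLS = ["participant_id", "arm", "sessions"]
_EQ5D_COLS = ["participant_id", "week", *EQ5D_DOMAINS]


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    return df


def load_roster(path: str | Path) -> pd.DataFrame:
    """Load the participant roster (arm, site, assessment attendance)."""
    df = _read_csv(path, _ROSTER_COLS[:3])
    bad = [i + 2 for i, a in enumerate(df["arm"]) if a not in Arm._value2member_map_]
    if bad:
        raise ValidationError("unknown arm label", bad)
    if df["participant_id"].duplicated().any():
        dup = df.index[df["participant_id"].duplicated()] + 2
        raise ValidationError("duplicate participant_id in roster", list(dup))
    for col in _ROSTER_COLS[3:]:
        if col not in df.columns:
            df[col] = True
        df[col] = df[col].astype(bool)
    return df[_ROSTER_COLS].copy()


def load_service_use(
    path: str | Path,
    services: Sequence[str] = DEFAULT_SERVICES,
    aliases: Mapping[str, str] | None = None,
    periods: Sequence[str] = PERIOD_LABELS,
) -> list[ServiceContactRecord]:
    """Load service-use rows, mapping aliases and rejecting unknown services."""
    df = _read_csv(path, _SERVICE_COLS)
    aliases = dict(aliases or {})
    records: list[ServiceContactRecord] = []
    bad_rows: list[int] = []
    messages: list[str] = []
    known = set(services)
    for i, row in enumerate(df.itertuples(index=False)):
        rowno = i + 2  # 1-based with header
        svc = aliases.get(row.service, row.service)
        problems = []
        if svc not in known:
            problems.append(f"unknown service {row.service!r}")
        if row.period not in periods:
            problems.append(f"unknown period {row.period!r}")
        try:
            count = int(row.contact_count)
            days = float(row.inpatient_days)
        except (TypeError, ValueError):
            problems.append("non-numeric contact_count/inpatient_days")
            count, days = 0, 0.0
        if count < 0:
            problems.append("negative contact_count")
        if days < 0:
            problems.append("negative inpatient_days")
        if svc != INPATIENT_SERVICE and days != 0:
            problems.append("inpatient_days on a non-inpatient service")
        if problems:
            bad_rows.append(rowno)
            messages.append(f"row {rowno}: " + "; ".join(problems))
            continue
        records.append(ServiceContactRecord(str(row.participant_id),
                                            row.period, svc, count, days))
    if bad_rows:
        raise ValidationError("invalid service-use rows: " + " | ".join(messages),
                              bad_rows)
    return records


def load_therapy(path: str | Path) -> list[TherapyRecord]:
    df = _read_csv(path, _THERAPY_COLS)
    records, bad = [], []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(TherapyRecord(str(row.participant_id),
                                         Arm(row.arm), int(row.sessions)))
        except ValueError:
            bad.append(i + 2)
    if bad:
        raise ValidationError("invalid therapy rows", bad)
    return records


def load_eq5d(path: str | Path) -> list[EQ5DResponse]:
    """Load questionnaire rows; a row with all domains blank is missing."""
    df = _read_csv(path, _EQ5D_COLS)
    records, bad = [], []
    for i, row in enumerate(df.itertuples(index=False)):
        vals = [getattr(row, d) for d in EQ5D_DOMAINS]
        try:
            if all(pd.isna(v) for v in vals):
                levels = None
            else:
                levels = tuple(int(v) for v in vals)
            records.append(EQ5DResponse(str(row.participant_id),
                                        int(row.week), levels))
        except (TypeError, ValueError):
            bad.append(i + 2)
    if bad:
        raise ValidationError("invalid EQ-5D rows", bad)
    return records


def load_unit_costs(path: str | Path) -> UnitCostTable:
    """Read a unit-cost table from long CSV (item,cost[,price_year]).

    Special items: ``inpatient_per_diem``, ``therapist_session_rate``,
    ``non_contact_uplift``, ``fixed_tech_cost``; every other item is a
    per-contact community service cost.  Missing special items are an error —
    costs are never silently zero.
    """
    df = _read_csv(path, ["item", "cost"])
    mapping = dict(zip(df["item"], df["cost"].astype(float)))
    for required in ("inpatient_per_diem", "therapist_session_rate"):
        if required not in mapping:
            raise ValidationError(f"unit-cost table missing {required!r}")
    price_year = "2021/22"
    if "price_year" in df.columns and df["price_year"].notna().any():
        price_year = str(df["price_year"].dropna().iloc[0])
    special = {"inpatient_per_diem", "therapist_session_rate",
               "non_contact_uplift", "fixed_tech_cost"}
    return UnitCostTable(
        contact_costs={k: v for k, v in mapping.items() if k not in special},
        inpatient_per_diem=mapping["inpatient_per_diem"],
        therapist_session_rate=mapping["therapist_session_rate"],
        non_contact_uplift=mapping.get("non_contact_uplift", 1.51),
        fixed_tech_cost=mapping.get("fixed_tech_cost", 50.0),
        price_year=price_year,
    )


def write_roster(df: pd.DataFrame, path: str | Path) -> None:
    df[_ROSTER_COLS].to_csv(path, index=False)


def write_service_use(records: Iterable[ServiceContactRecord],
                      path: str | Path) -> None:
    pd.DataFrame(
        [(r.participant_id, r.period, r.service, r.contact_count,
          r.inpatient_days) for r in records],
        columns=_SERVICE_COLS,
    ).to_csv(path, index=False)


def write_therapy(records: Iterable[TherapyRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.participant_id, r.arm.value, r.sessions) for r in records],
        columns=_THERAPY_COLS,
    ).to_csv(path, index=False)


def write_eq5d(records: Iterable[EQ5DResponse], path: str | Path) -> None:
    rows = []
    for r in records:
        levels = r.levels if r.levels is not None else (None,) * 5
        rows.append((r.participant_id, r.week, *levels))
    pd.DataFrame(rows, columns=_EQ5D_COLS).to_csv(path, index=False)


def write_unit_costs(table: UnitCostTable, path: str | Path) -> None:
    rows = [("inpatient_per_diem", table.inpatient_per_diem),
            ("therapist_session_rate", table.therapist_session_rate),
            ("non_contact_uplift", table.non_contact_uplift),
            ("fixed_tech_cost", table.fixed_tech_cost)]
    rows += sorted(table.contact_costs.items())
    df = pd.DataFrame(rows, columns=["item", "cost"])
    df["price_year"] = table.price_year
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# cross-table validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Report-only list of cross-table consistency problems."""

    orphan_participants: list[str] = field(default_factory=list)
    duplicate_service_rows: list[tuple[int, int]] = field(default_factory=list)
    tau_with_sessions: list[str] = field(default_factory=list)
    bad_eq5d_weeks: list[tuple[str, int]] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not (self.orphan_participants or self.duplicate_service_rows
                    or self.tau_with_sessions or self.bad_eq5d_weeks)

    def raise_if_issues(self) -> None:
        if not self.empty:
            raise ValidationError(f"dataset validation failed: {self}")


def validate_dataset(
    service_use: Sequence[ServiceContactRecord],
    therapy: Sequence[TherapyRecord],
    eq5d: Sequence[EQ5DResponse],
    roster: pd.DataFrame,
    strict: bool = False,
) -> ValidationReport:
    """Cross-check the four input tables against the roster.

    Flags participant ids absent from the roster, duplicated
    (participant, period, service) rows (with both 0-based record indices),
    TAU participants with attended sessions, and questionnaire weeks outside
    {0, 16, 28}.  Report-only unless ``strict``.
    """
    report = ValidationReport()
    known = set(roster["participant_id"])
    arm_of = dict(zip(roster["participant_id"], roster["arm"]))

    seen: dict[tuple[str, str, str], int] = {}
    orphans: set[str] = set()
    for i, rec in enumerate(service_use):
        if rec.participant_id not in known:
            orphans.add(rec.participant_id)
        key = (rec.participant_id, rec.period, rec.service)
        if key in seen:
            report.duplicate_service_rows.append((seen[key], i))
        else:
            seen[key] = i
    for rec in therapy:
        if rec.participant_id not in known:
            orphans.add(rec.participant_id)
        elif arm_of.get(rec.participant_id) == Arm.TAU.value and rec.sessions > 0:
            report.tau_with_sessions.append(rec.participant_id)
    for rec in eq5d:
        if rec.participant_id not in known:
            orphans.add(rec.participant_id)
        if rec.week not in (0, 16, 28):  # pragma: no cover - type guards this
            report.bad_eq5d_weeks.append((rec.participant_id, rec.week))
    report.orphan_participants = sorted(orphans)
    if strict:
        report.raise_if_issues()
    return report
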