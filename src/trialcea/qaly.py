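"""EQ-5D-5L utilities via a 5L-to-3L crosswalk and area-under-curve QALYs.

A five-level response profile (3125 states) is mapped to a utility index on
the three-level UK tariff scale, then utilities at weeks 0/16/28 are combined
by trapezoidal integration (linear change between assessments) into
quality-adjusted life years over the 28-week horizon, expressed in years.

The packaged value set is a *synthetic crosswalk*: each five-level domain
response is collapsed deterministically onto three levels
(1 -> 1, {2,3} -> 2, {4,5} -> 3) and scored with the published UK
three-level time-trade-off tariff (constant-term 0.081, per-domain
decrements, 0.269 extreme-level term).  It anchors full health at exactly
1.0 and reaches -0.594 for the worst state, but it is not the published
regression-based five-to-three-level mapping; value sets are pluggable so a
direct 5L tariff (or the regression crosswalk, supplied as a 3125-row CSV)
can be substituted.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .trial_data import EQ5D_DOMAINS, EQ5DResponse

__all__ = [
    "ValueSet",
    "UtilityValue",
    "QalyValue",
    "crosswalk_value_set",
    "crosswalk_utility",
    "auc_qaly",
    "qaly_trapezoid",
    "utility_table",
    "qaly_table",
]

WEEKS_PER_YEAR = 52.0
HORIZON_WEEKS = 28.0
ASSESSMENT_WEEKS = (0.0, 16.0, 28.0)

# UK 3L time-trade-off tariff: constant decrement for any dysfunction,
# per-domain decrements at levels 2 and 3, extra decrement if any domain at 3.
_UK3L_CONSTANT = 0.081
_UK3L_N3 = 0.269
_UK3L_DECREMENTS = {
    "mobility": (0.069, 0.314),
    "self_care": (0.104, 0.214),
    "usual_activities": (0.036, 0.094),
    "pain_discomfort": (0.123, 0.386),
    "anxiety_depression": (0.071, 0.236),
}
_COLLAPSE_5L_TO_3L = {1: 1, 2: 2, 3: 2, 4: 3, 5: 3}


@dataclass(frozen=True)
class UtilityValue:
    participant_id: str
    week: int
    utility: float  # NaN when the response is missing


@dataclass(frozen=True)
class QalyValue:
    participant_id: str
    qaly: float  # years of full-health equivalent over weeks 0-28; NaN if any
    # utility is missing


class ValueSet:
    """Mapping from the 3125 five-level states to utility indices.

    ``values`` is indexed by the five-digit state string ("11111".."55555").
    Full health maps to exactly 1.0; the minimum may be negative (states
    valued worse than death).
    """

    def __init__(self, id: str, values: pd.Series, provenance: str = "") -> None:
        if len(values) != 5 ** 5:
            raise ValueError("value set must cover all 3125 states")
        if values.loc["11111"] != 1.0:
            raise ValueError("full-health state must map to exactly 1.0")
        if (values > 1.0).any():
            raise ValueError("utilities cannot exceed 1.0")
        self.id = id
        self.values = values.astype(float)
        self.provenance = provenance

    @property
    def min_utility(self) -> float:
        return float(self.values.min())

    def utility(self, levels: Sequence[int]) -> float:
        for lv in levels:
            if not (1 <= int(lv) <= 5):
                raise ValueError(f"EQ-5D level out of range 1..5: {lv}")
        state = "".join(str(int(lv)) for lv in levels)
        return float(self.values.loc[state])

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# value set: {self.id}\n")
            if self.provenance:
                fh.write(f"# provenance: {self.provenance}\n")
            fh.write("state,utility\n")
            for state, u in self.values.items():
                fh.write(f"{state},{u!r}\n")

    @classmethod
    def read_csv(cls, path: str | Path, id: str | None = None) -> "ValueSet":
        header: list[str] = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if line.startswith("#"):
                    header.append(line[1:].strip())
                else:
                    break
        df = pd.read_csv(path, comment="#", dtype={"state": str})
        values = df.set_index("state")["utility"]
        vid = id or next((h.split(":", 1)[1].strip() for h in header
                          if h.startswith("value set:")), "unnamed")
        prov = next((h.split(":", 1)[1].strip() for h in header
                     if h.startswith("provenance:")), "")
        return cls(vid, values, prov)


def _uk3l_index(levels3: Sequence[int]) -> float:
    if all(lv == 1 for lv in levels3):
        return 1.0
    u = 1.0 - _UK3L_CONSTANT
    for domain, lv in zip(EQ5D_DOMAINS, levels3):
        d2, d3 = _UK3L_DECREMENTS[domain]
        if lv == 2:
            u -= d2
        elif lv == 3:
            u -= d3
    if any(lv == 3 for lv in levels3):
        u -= _UK3L_N3
    return round(u, 6)


def crosswalk_value_set() -> ValueSet:
    """Build the packaged synthetic level-collapse crosswalk value set.

    Deterministic; see the module docstring for what this is and is not.
    """
    states, utils = [], []
    for combo in itertools.product((1, 2, 3, 4, 5), repeat=5):
        states.append("".join(map(str, combo)))
        utils.append(_uk3l_index([_COLLAPSE_5L_TO_3L[lv] for lv in combo]))
    values = pd.Series(utils, index=pd.Index(states, name="state"),
                       name="utility")
    return ValueSet(
        id="synthetic-uk3l-collapse",
        values=values,
        provenance=(
            "synthetic crosswalk: deterministic 5L->3L level collapse "
            "(1->1, 2/3->2, 4/5->3) scored with the published UK 3L TTO "
            "tariff; not the regression-based published crosswalk"
        ),
    )


def crosswalk_utility(response: EQ5DResponse, value_set: ValueSet) -> UtilityValue:
    """Deterministic table lookup; a missing response stays missing."""
    if response.missing:
        return UtilityValue(response.participant_id, response.week, math.nan)
    return UtilityValue(response.participant_id, response.week,
                        value_set.utility(response.levels))


def qaly_trapezoid(utilities: Sequence[float], weeks: Sequence[float]) -> float:
    """Trapezoid-rule QALYs (years) for utilities at arbitrary timepoints."""
    if len(utilities) != len(weeks) or len(weeks) < 2:
        raise ValueError("need matching utility/week sequences of length >= 2")
    if any(b <= a for a, b in zip(weeks, weeks[1:])):
        raise ValueError("weeks must be strictly increasing")
    if any(math.isnan(u) for u in utilities):
        return math.nan
    total = 0.0
    for (w0, w1), (u0, u1) in zip(zip(weeks, weeks[1:]),
                                  zip(utilities, utilities[1:])):
        total += 0.5 * (u0 + u1) * (w1 - w0)
    return total / WEEKS_PER_YEAR


def auc_qaly(u0: float, u16: float, u28: float) -> float:
    """QALYs over weeks 0-28 assuming linear change between assessments.

    QALY = (u0+u16)/2 * 16/52 + (u16+u28)/2 * 12/52, in years; NaN if any
    utility is missing.
    """
    return qaly_trapezoid((u0, u16, u28), ASSESSMENT_WEEKS)


def utility_table(responses: Iterable[EQ5DResponse],
                  value_set: ValueSet) -> pd.DataFrame:
    """Wide utility table (participant_id, u0, u16, u28); absent weeks -> NaN."""
    cells: dict[str, dict[str, float]] = {}
    for resp in responses:
        u = crosswalk_utility(resp, value_set)
        cells.setdefault(resp.participant_id, {})[f"u{resp.week}"] = u.utility
    df = pd.DataFrame.from_dict(cells, orient="index")
    for col in ("u0", "u16", "u28"):
        if col not in df.columns:
            df[col] = math.nan
    df = df[["u0", "u16", "u28"]]
    df.index.name = "participant_id"
    return df.reset_index()


def qaly_table(responses: Iterable[EQ5DResponse],
               value_set: ValueSet) -> pd.DataFrame:
    """Per-participant utilities and the AUC QALY (NaN if any week missing)."""
    df = utility_table(responses, value_set)
    df["qaly"] = [auc_qaly(r.u0, r.u16, r.u28)
                  for r in df.itertuples(index=False)]
    return df
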