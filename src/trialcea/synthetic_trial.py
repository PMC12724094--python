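"""Synthetic three-arm trial generator with the statistical structure the
cost-utility analysis assumes.

The generator emulates a 345-participant, four-site, three-arm trial
(TAU / brief therapy / extended therapy, 115/116/114) over a 28-week
horizon:

* mostly-zero, right-skewed service costs — each community service is used
  with a per-period probability and a zero-truncated contact-count law, and
  rare psychiatric admissions (Bernoulli, ~0.06-0.08 per arm) carry long
  right-skewed lengths of stay, so a handful of in-patient episodes dominate
  the cost distribution;
* therapy dose — attended sessions follow an overdispersed (beta-binomial)
  law on a bounded support, calibrated to mean (s.d.) 5.1 (2.4) sessions in
  the brief arm and 8.2 (4.4) in the extended arm;
* EQ-5D trajectories — a participant-level latent utility with small
  arm-by-time shifts at weeks 16 and 28 is projected onto the nearest
  attainable state of the packaged value set (seeded tie-breaking among
  equally close states; a modelling convenience, not a claim about real
  response patterns);
* missing-at-random follow-up — logistic missingness on arm, baseline
  utility and baseline cost, with per-arm target rates matching observed
  follow-up (~10-25%).

All randomness flows from one master seed through named substreams, so a
fixed seed reproduces the bundle byte for byte.  The true incremental cost
and QALY implied by a configuration are recorded in a sidecar (computed by a
common-random-numbers Monte Carlo routine plus exact therapy-cost means),
which is what parameter-recovery tests compare against.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .costing import participant_cost_table
from .inference import assemble_analysis_dataset
from .qaly import ValueSet, crosswalk_value_set, qaly_table
from .trial_data import (
    Arm,
    EQ5DResponse,
    INPATIENT_SERVICE,
    ServiceContactRecord,
    TherapyRecord,
    UnitCostTable,
    default_unit_costs,
    write_eq5d,
    write_roster,
    write_service_use,
    write_therapy,
)

__all__ = [
    "ServiceLaw",
    "SynthConfig",
    "TrialBundle",
    "generate_trial",
    "impose_missingness",
    "compute_truth",
    "config_with_target_effects",
    "zero_effect_config",
]

_ARMS = [Arm.TAU.value, Arm.AV_BRF.value, Arm.AV_EXT.value]
_SUBSTREAMS = ("roster", "service_use", "therapy", "eq5d", "missingness",
               "truth")

# QALY weight of a latent utility shift applied at weeks 16 and 28 equally:
# d/du16 + d/du28 of the trapezoid = (8+6)/52 + 6/52 = 20/52.
_QALY_SHIFT_WEIGHT = 20.0 / 52.0


@dataclass(frozen=True)
class ServiceLaw:
    """Per-period use probability and mean contacts given any use."""

    p_use: float
    mean_contacts: float

    def __post_init__(self) -> None:
        if not (0 <= self.p_use <= 1):
            raise ValueError("use probability must be in [0, 1]")
        if self.mean_contacts < 1:
            raise ValueError("mean contacts given use must be >= 1")


def _default_services() -> dict[str, ServiceLaw]:
    return {
        "gp": ServiceLaw(0.55, 4.0),
        "psychiatrist": ServiceLaw(0.50, 3.0),
        "mental_health_nurse": ServiceLaw(0.45, 5.0),
        "psychologist": ServiceLaw(0.25, 3.0),
        "early_intervention_team": ServiceLaw(0.33, 3.5),
        "social_worker": ServiceLaw(0.15, 2.5),
        "other_community": ServiceLaw(0.30, 3.0),
    }


def _default_missingness() -> dict[str, dict[str, float]]:
    # per-variable, per-arm target missingness rates calibrated to the
    # observed follow-up of a three-arm trial of this design
    return {
        "cost_w16": {"TAU": 0.096, "AV-BRF": 0.155, "AV-EXT": 0.158},
        "cost_w28": {"TAU": 0.113, "AV-BRF": 0.155, "AV-EXT": 0.202},
        "eq5d_w0": {"TAU": 0.0, "AV-BRF": 0.009, "AV-EXT": 0.018},
        "eq5d_w16": {"TAU": 0.139, "AV-BRF": 0.172, "AV-EXT": 0.193},
        "eq5d_w28": {"TAU": 0.139, "AV-BRF": 0.190, "AV-EXT": 0.272},
    }


@dataclass
class SynthConfig:
    """Generator configuration; the defaults are the study conditions.

    Arm sizes, admission rates, lengths of stay, therapy dose moments and
    follow-up rates default to the trial design the analysis targets; the
    service-use laws and latent utility parameters are representative values
    for a community psychosis sample (documented in the methods note).
    """

    arm_sizes: tuple[int, int, int] = (115, 116, 114)  # TAU, AV-BRF, AV-EXT
    site_count: int = 4
    baseline_recall_weeks: float = 12.0
    services: dict[str, ServiceLaw] = field(default_factory=_default_services)
    # rare long psychiatric admissions drive the cost skew
    admission_prob: dict[str, float] = field(default_factory=lambda: {
        "TAU": 0.078, "AV-BRF": 0.069, "AV-EXT": 0.061})
    admission_los_mean: dict[str, float] = field(default_factory=lambda: {
        "TAU": 76.7, "AV-BRF": 70.0, "AV-EXT": 27.9})
    admission_los_shape: float = 0.9
    baseline_admission_prob: float = 0.06
    baseline_los_mean: float = 40.0
    # therapy dose: bounded overdispersed counts (assessment + dialogues)
    sessions_max: dict[str, int] = field(default_factory=lambda: {
        "AV-BRF": 7, "AV-EXT": 13})
    sessions_mean: dict[str, float] = field(default_factory=lambda: {
        "AV-BRF": 5.1, "AV-EXT": 8.2})
    sessions_sd: dict[str, float] = field(default_factory=lambda: {
        "AV-BRF": 2.4, "AV-EXT": 4.4})
    # latent utility trajectory
    utility_mean0: float = 0.62
    utility_sd_between: float = 0.20
    utility_sd_within: float = 0.10
    # additive latent-utility shifts at (week 16, week 28) per therapy arm
    utility_effects: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"AV-BRF": (0.045, 0.033),
                                 "AV-EXT": (0.050, 0.033)})
    # MAR missingness: logistic on standardized baseline utility and
    # log-baseline-cost with per-arm intercepts solved to hit target rates
    missingness: dict[str, dict[str, float]] = field(
        default_factory=_default_missingness)
    miss_beta_utility: float = -1.2
    miss_beta_cost: float = 0.25
    unit_costs: UnitCostTable = field(default_factory=default_unit_costs)

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.arm_sizes):
            raise ValueError("arm sizes must be positive")
        for var, per_arm in self.missingness.items():
            for arm, rate in per_arm.items():
                if not (0 <= rate < 1):
                    raise ValueError(
                        f"missingness target for {var}/{arm} must be in "
                        "[0, 1); a rate of 1.0 would remove a variable the "
                        "MAR model conditions on")
        for arm, p in self.admission_prob.items():
            if not (0 <= p <= 1):
                raise ValueError(f"admission probability for {arm} not in [0,1]")

    def scaled(self, factor: int) -> "SynthConfig":
        """Same conditions at ``factor`` times the sample size."""
        return replace(self, arm_sizes=tuple(n * factor for n in self.arm_sizes))


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(child)
            for name, child in zip(_SUBSTREAMS, children)}


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------

def _sample_sessions(rng: np.random.Generator, n: int, n_max: int,
                     mean: float, sd: float) -> np.ndarray:
    """Beta-binomial attendance counts with the requested mean and s.d.

    The beta-binomial keeps the exact target mean on the bounded support and
    inflates the variance toward the target s.d. (capped at the two-point
    maximum); it reproduces the completer-heavy, long-left-tail shape of
    session attendance.
    """
    if n_max == 0 or mean <= 0:
        return np.zeros(n, dtype=int)
    p = min(mean / n_max, 1.0)
    if p >= 1.0:
        return np.full(n, n_max, dtype=int)
    npq = n_max * p * (1 - p)
    rho = (sd ** 2 / npq - 1) / (n_max - 1) if n_max > 1 else 0.0
    rho = min(max(rho, 0.0), 0.98)
    if rho <= 0:
        return rng.binomial(n_max, p, size=n)
    ab = 1.0 / rho - 1.0
    alpha, beta = p * ab, (1 - p) * ab
    return rng.binomial(n_max, rng.beta(alpha, beta, size=n))


def _nearest_utilities(u: np.ndarray, grid: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Project latent utilities onto the nearest attainable grid value.

    Exactly equidistant latent values pick the lower/upper neighbour by a
    seeded fair coin.
    """
    u = np.clip(u, grid[0], grid[-1])
    hi = np.clip(np.searchsorted(grid, u), 1, len(grid) - 1)
    lo = hi - 1
    d_lo = u - grid[lo]
    d_hi = grid[hi] - u
    pick_hi = d_hi < d_lo
    ties = d_hi == d_lo
    if ties.any():
        pick_hi = pick_hi | (ties & (rng.random(len(u)) < 0.5))
    return grid[np.where(pick_hi, hi, lo)]


class _StatePicker:
    """Maps a grid utility back to a concrete 5-level state (seeded choice
    among states sharing that utility)."""

    def __init__(self, value_set: ValueSet) -> None:
        by_util: dict[float, list[str]] = {}
        for state, util in value_set.values.items():
            by_util.setdefault(float(util), []).append(state)
        self.grid = np.array(sorted(by_util), dtype=float)
        self.states = {u: sorted(v) for u, v in by_util.items()}

    def pick(self, utilities: np.ndarray,
             rng: np.random.Generator) -> list[str]:
        out = []
        for u in utilities:
            options = self.states[float(u)]
            out.append(options[rng.integers(len(options))]
                       if len(options) > 1 else options[0])
        return out


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

@dataclass
class TrialBundle:
    """A complete synthetic input bundle in the dialects `trial_data` reads."""

    roster: pd.DataFrame
    service_use: list[ServiceContactRecord]
    therapy: list[TherapyRecord]
    eq5d: list[EQ5DResponse]
    config: SynthConfig

    def write(self, outdir: str | Path, truth: dict | None = None) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_roster(self.roster, outdir / "roster.csv")
        write_service_use(self.service_use, outdir / "service_use.csv")
        write_therapy(self.therapy, outdir / "therapy.csv")
        write_eq5d(self.eq5d, outdir / "eq5d.csv")
        if truth is not None:
            (outdir / "truth.json").write_text(
                json.dumps(truth, indent=2, sort_keys=True) + "\n")

    def analysis_dataset(self, value_set: ValueSet | None = None
                         ) -> pd.DataFrame:
        """Cost + QALY pipeline applied to this bundle, ready for inference."""
        value_set = value_set or crosswalk_value_set()
        costs = participant_cost_table(self.service_use, self.therapy,
                                       self.roster, self.config.unit_costs)
        qalys = qaly_table(self.eq5d, value_set)
        return assemble_analysis_dataset(self.roster, costs, qalys)


def generate_trial(config: SynthConfig | None = None, seed: int = 0,
                   value_set: ValueSet | None = None) -> TrialBundle:
    """Generate a complete (no-missingness) synthetic trial bundle."""
    config = config or SynthConfig()
    value_set = value_set or crosswalk_value_set()
    rngs = _substreams(seed)
    n_total = sum(config.arm_sizes)
    ids = [f"P{i:04d}" for i in range(1, n_total + 1)]
    arms = np.repeat(_ARMS, config.arm_sizes)
    order = rngs["roster"].permutation(n_total)  # interleave arms
    arms = arms[order]
    sites = rngs["roster"].integers(1, config.site_count + 1, size=n_total)
    roster = pd.DataFrame({
        "participant_id": ids, "arm": arms,
        "site": [f"S{s}" for s in sites],
        "attended_baseline": True, "attended_w16": True, "attended_w28": True,
    })

    # --- service use -------------------------------------------------------
    rng = rngs["service_use"]
    periods = [("baseline", config.baseline_recall_weeks * 7),
               ("w16", 16 * 7.0), ("w28", 12 * 7.0)]
    records: list[ServiceContactRecord] = []
    for period, span_days in periods:
        for svc, law in config.services.items():
            use = rng.random(n_total) < law.p_use
            counts = 1 + rng.poisson(law.mean_contacts - 1.0, size=n_total)
            for i in np.flatnonzero(use):
                records.append(ServiceContactRecord(
                    ids[i], period, svc, int(counts[i])))
    # admissions: baseline window, then one admission over follow-up split
    # between the two periods in proportion to their spans
    adm_base = rng.random(n_total) < config.baseline_admission_prob
    los_base = rng.gamma(config.admission_los_shape,
                         config.baseline_los_mean / config.admission_los_shape,
                         size=n_total)
    p_adm = np.array([config.admission_prob[a] for a in arms])
    adm_fu = rng.random(n_total) < p_adm
    in_w16 = rng.random(n_total) < 16.0 / 28.0
    los_mean = np.array([config.admission_los_mean[a] for a in arms])
    los_fu = rng.gamma(config.admission_los_shape, 1.0, size=n_total) \
        * los_mean / config.admission_los_shape
    for i in range(n_total):
        if adm_base[i]:
            days = float(min(los_base[i], config.baseline_recall_weeks * 7))
            records.append(ServiceContactRecord(
                ids[i], "baseline", INPATIENT_SERVICE, 1, round(days, 1)))
        if adm_fu[i]:
            period, span = ("w16", 112.0) if in_w16[i] else ("w28", 84.0)
            days = float(min(los_fu[i], span))
            records.append(ServiceContactRecord(
                ids[i], period, INPATIENT_SERVICE, 1, round(days, 1)))

    # --- therapy -----------------------------------------------------------
    rng = rngs["therapy"]
    therapy: list[TherapyRecord] = []
    sessions = np.zeros(n_total, dtype=int)
    for arm_label in ("AV-BRF", "AV-EXT"):
        mask = arms == arm_label
        sessions[mask] = _sample_sessions(
            rng, int(mask.sum()), config.sessions_max[arm_label],
            config.sessions_mean[arm_label], config.sessions_sd[arm_label])
    for i in range(n_total):
        therapy.append(TherapyRecord(ids[i], Arm(arms[i]), int(sessions[i])))

    # --- EQ-5D -------------------------------------------------------------
    rng = rngs["eq5d"]
    picker = _StatePicker(value_set)
    b = rng.normal(config.utility_mean0, config.utility_sd_between, n_total)
    eq5d: list[EQ5DResponse] = []
    for week, effect_idx in ((0, None), (16, 0), (28, 1)):
        eps = rng.normal(0.0, config.utility_sd_within, n_total)
        shift = np.zeros(n_total)
        if effect_idx is not None:
            for arm_label, effects in config.utility_effects.items():
                shift[arms == arm_label] = effects[effect_idx]
        latent = b + shift + eps
        grid_u = _nearest_utilities(latent, picker.grid, rng)
        for pid, state in zip(ids, picker.pick(grid_u, rng)):
            eq5d.append(EQ5DResponse(pid, week,
                                     tuple(int(ch) for ch in state)))
    return TrialBundle(roster, records, therapy, eq5d, config)


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

def _solve_intercept(eta: np.ndarray, target: float) -> float:
    """Intercept alpha with mean(expit(alpha + eta)) = target."""
    from scipy.optimize import brentq
    from scipy.special import expit
    if target <= 0:
        return -np.inf
    return brentq(lambda a: expit(a + eta).mean() - target, -30.0, 30.0)


def impose_missingness(bundle: TrialBundle, seed: int = 0) -> TrialBundle:
    """Apply MAR missingness markers to a complete bundle.

    Missingness indicators are drawn from a logistic model on arm (separate
    intercepts solved to hit each arm's target rate), standardized baseline
    utility and standardized log baseline cost — observed covariates only.
    Baseline costs and the roster are never made missing.
    """
    config = bundle.config
    rng = _substreams(seed)["missingness"]
    roster = bundle.roster.copy()
    ids = roster["participant_id"].to_list()
    pos = {pid: i for i, pid in enumerate(ids)}
    arms = roster["arm"].to_numpy()
    n = len(ids)

    value_set = crosswalk_value_set()
    base_u = np.full(n, config.utility_mean0)
    for rec in bundle.eq5d:
        if rec.week == 0 and rec.levels is not None:
            base_u[pos[rec.participant_id]] = value_set.utility(rec.levels)
    base_cost = np.zeros(n)
    for rec in bundle.service_use:
        if rec.period == "baseline":
            i = pos[rec.participant_id]
            if rec.service == INPATIENT_SERVICE:
                base_cost[i] += rec.inpatient_days * config.unit_costs.inpatient_per_diem
            else:
                base_cost[i] += rec.contact_count * config.unit_costs.cost_for(rec.service)

    def z(x: np.ndarray) -> np.ndarray:
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    eta = config.miss_beta_utility * z(base_u) \
        + config.miss_beta_cost * z(np.log1p(base_cost))

    miss: dict[str, np.ndarray] = {}
    from scipy.special import expit
    for var, per_arm in config.missingness.items():
        flag = np.zeros(n, dtype=bool)
        for arm_label, target in per_arm.items():
            mask = arms == arm_label
            if not mask.any() or target <= 0:
                continue
            alpha = _solve_intercept(eta[mask], target)
            flag[mask] = rng.random(int(mask.sum())) < expit(alpha + eta[mask])
        miss[var] = flag

    miss_ids = {var: {ids[i] for i in np.flatnonzero(flag)}
                for var, flag in miss.items()}
    roster["attended_w16"] = [pid not in miss_ids.get("cost_w16", set())
                              for pid in ids]
    roster["attended_w28"] = [pid not in miss_ids.get("cost_w28", set())
                              for pid in ids]
    service_use = [rec for rec in bundle.service_use
                   if not (rec.period == "w16"
                           and rec.participant_id in miss_ids.get("cost_w16", set()))
                   and not (rec.period == "w28"
                            and rec.participant_id in miss_ids.get("cost_w28", set()))]
    eq5d_missing = {(pid, week) for var, week in
                    (("eq5d_w0", 0), ("eq5d_w16", 16), ("eq5d_w28", 28))
                    for pid in miss_ids.get(var, set())}
    eq5d = [rec for rec in bundle.eq5d
            if (rec.participant_id, rec.week) not in eq5d_missing]
    return TrialBundle(roster, service_use, bundle.therapy, eq5d, config)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def compute_truth(config: SynthConfig | None = None, seed: int = 0,
                  n_mc: int = 400_000) -> dict:
    """True incremental (cost, QALY) per comparison implied by a config.

    Therapy cost means are exact (beta-binomial mean = support x mean
    probability); the admission-cost and QALY components are Monte Carlo
    averages at ``n_mc`` simulated participants per arm, using common random
    numbers across arms so a zero-effect configuration yields exactly zero.
    Community service laws are shared across arms and cancel.
    """
    config = config or SynthConfig()
    rng = _substreams(seed)["truth"]
    grid = _StatePicker(crosswalk_value_set()).grid

    # QALY component: shared baseline and noise draws across arms
    b = rng.normal(config.utility_mean0, config.utility_sd_between, n_mc)
    e0 = rng.normal(0.0, config.utility_sd_within, n_mc)
    e16 = rng.normal(0.0, config.utility_sd_within, n_mc)
    e28 = rng.normal(0.0, config.utility_sd_within, n_mc)
    tie = rng.random(n_mc)  # shared tie-break coin

    def mean_qaly(arm_label: str) -> float:
        d16, d28 = (0.0, 0.0) if arm_label == "TAU" else \
            config.utility_effects.get(arm_label, (0.0, 0.0))
        rng_tie = np.random.default_rng(0)  # ties resolved identically per arm
        u0 = _nearest_utilities(b + e0, grid, rng_tie)
        u16 = _nearest_utilities(b + d16 + e16, grid, rng_tie)
        u28 = _nearest_utilities(b + d28 + e28, grid, rng_tie)
        return float(np.mean(u0 * 8 / 52 + u16 * 14 / 52 + u28 * 6 / 52))

    # admission component: shared admission/uniform/gamma draws
    u_adm = rng.random(n_mc)
    in_w16 = rng.random(n_mc) < 16.0 / 28.0
    g = rng.gamma(config.admission_los_shape, 1.0, n_mc)
    span = np.where(in_w16, 112.0, 84.0)

    def mean_admission_cost(arm_label: str) -> float:
        admitted = u_adm < config.admission_prob[arm_label]
        los = np.minimum(
            g * config.admission_los_mean[arm_label] / config.admission_los_shape,
            span)
        return float(np.mean(admitted * np.round(los, 1))
                     * config.unit_costs.inpatient_per_diem)

    def mean_therapy_cost(arm_label: str) -> float:
        if arm_label == "TAU":
            return 0.0
        mean_sessions = min(config.sessions_mean[arm_label],
                            config.sessions_max[arm_label])
        return (mean_sessions * config.unit_costs.therapist_session_cost
                + config.unit_costs.fixed_tech_cost)

    q_tau = mean_qaly("TAU")
    c_tau = mean_admission_cost("TAU")
    truth = {"delta_cost": {}, "delta_qaly": {}, "n_mc": n_mc, "seed": seed}
    for label, arm_label in (("BRF_vs_TAU", "AV-BRF"), ("EXT_vs_TAU", "AV-EXT")):
        truth["delta_qaly"][label] = mean_qaly(arm_label) - q_tau
        truth["delta_cost"][label] = (mean_admission_cost(arm_label)
                                      + mean_therapy_cost(arm_label) - c_tau)
    return truth


# ---------------------------------------------------------------------------
# configuration helpers
# ---------------------------------------------------------------------------

def config_with_target_effects(delta_cost: float, delta_qaly: float,
                               base: SynthConfig | None = None) -> SynthConfig:
    """Configuration whose implied incrementals approximate given targets.

    The latent utility shift at weeks 16/28 is set to
    delta_qaly / (20/52) at both timepoints; the admission length-of-stay
    mean in each therapy arm is solved (closed-form clipped-gamma
    expectation) so that the expected admission-cost change offsets the
    exact therapy-cost mean, leaving ``delta_cost``.  The utility mapping
    ignores state-grid discretisation and range clipping (a few percent of
    attenuation), so the recorded Monte-Carlo truth — not the requested
    target — is the reference for recovery tests.
    """
    from scipy.optimize import brentq
    from scipy.special import gammainc

    base = base or SynthConfig()
    delta_latent = delta_qaly / _QALY_SHIFT_WEIGHT
    p = base.admission_prob["TAU"]
    los_tau = base.admission_los_mean["TAU"]
    per_diem = base.unit_costs.inpatient_per_diem
    shape = base.admission_los_shape

    def expected_clipped_stay(mean: float) -> float:
        # E[min(X, span)] for X ~ Gamma(shape, mean/shape), averaged over the
        # two follow-up periods in proportion to their spans
        theta = mean / shape
        def one(span: float) -> float:
            return (mean * gammainc(shape + 1, span / theta)
                    + span * (1 - gammainc(shape, span / theta)))
        return (16 * one(112.0) + 12 * one(84.0)) / 28.0

    adm_prob = {"TAU": p}
    los = {"TAU": los_tau}
    effects = {}
    for arm_label in ("AV-BRF", "AV-EXT"):
        mean_sessions = min(base.sessions_mean[arm_label],
                            base.sessions_max[arm_label])
        therapy_mean = (mean_sessions * base.unit_costs.therapist_session_cost
                        + base.unit_costs.fixed_tech_cost)
        target_days = (expected_clipped_stay(los_tau)
                       + (delta_cost - therapy_mean) / (p * per_diem))
        if target_days <= 0:
            raise ValueError(
                f"cost target {delta_cost} infeasible: would require a "
                "negative expected stay; lower the therapy cost or raise "
                "the comparator admission rate")
        adm_prob[arm_label] = p
        los[arm_label] = float(brentq(
            lambda m: expected_clipped_stay(m) - target_days, 1e-3, 5000.0))
        effects[arm_label] = (delta_latent, delta_latent)
    return replace(base, admission_prob=adm_prob, admission_los_mean=los,
                   utility_effects=effects)


def zero_effect_config(base: SynthConfig | None = None) -> SynthConfig:
    """All arms exchangeable: no utility effects, identical admission laws,
    and no therapy dose or technology charge."""
    base = base or SynthConfig()
    p = base.admission_prob["TAU"]
    los = base.admission_los_mean["TAU"]
    costs = default_unit_costs()
    costs.fixed_tech_cost = 0.0
    return replace(
        base,
        admission_prob={a: p for a in _ARMS},
        admission_los_mean={a: los for a in _ARMS},
        utility_effects={"AV-BRF": (0.0, 0.0), "AV-EXT": (0.0, 0.0)},
        sessions_mean={"AV-BRF": 0.0, "AV-EXT": 0.0},
        sessions_sd={"AV-BRF": 0.0, "AV-EXT": 0.0},
        unit_costs=costs,
    )
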