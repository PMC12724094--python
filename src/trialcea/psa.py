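"""Probabilistic analysis: bootstrap with nested imputation, net benefit,
cost-effectiveness planes and acceptability curves.

Each bootstrap draw resamples participants with replacement (stratified by
arm, preserving the randomised design), reruns the multiple-imputation +
SUR pipeline on the resample, and records the pooled incremental cost/QALY
pair for each comparison together with regression-adjusted per-arm means.
Net benefit at willingness-to-pay lambda is lambda x QALYs - cost; the CEAC
reports, per lambda, the fraction of draws in which each option has the
highest net benefit (exact ties split equally).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import (
    ImputationConfig,
    fit_sur_incrementals,
    impute_chained_pmm,
)
from .trial_data import Arm, COMPARISONS

__all__ = [
    "default_lambda_grid",
    "bootstrap_draws",
    "net_benefit",
    "net_benefit_absolute",
    "ceac_from_draws",
    "ceac_pairwise_probability",
    "plane_quadrant_summary",
]

ARM_ORDER = [a.value for a in Arm]


def default_lambda_grid() -> np.ndarray:
    """Willingness-to-pay grid: 0 to 100000 GBP/QALY in 2000 GBP steps."""
    return np.arange(0, 100_001, 2000, dtype=float)


def net_benefit(lam: float, delta_qaly: float, delta_cost: float) -> float:
    """Incremental net monetary benefit: lambda x dQALY - dCost (GBP)."""
    if lam < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return lam * delta_qaly - delta_cost


def net_benefit_absolute(lam: float, mean_qaly: float, mean_cost: float) -> float:
    """Absolute per-arm net monetary benefit: lambda x QALYs - cost (GBP)."""
    if lam < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return lam * mean_qaly - mean_cost


def _one_draw(
    df: pd.DataFrame,
    rng: np.random.Generator,
    arm_indices: dict[str, np.ndarray],
    imputation: ImputationConfig,
    m_boot: int,
    stratify: bool,
    include_site_in_qaly: bool,
    has_missing: bool,
) -> dict[str, float]:
    if stratify:
        idx = np.concatenate([
            rng.choice(ix, size=len(ix), replace=True)
            for ix in arm_indices.values()
        ])
    else:
        idx = rng.choice(len(df), size=len(df), replace=True)
    boot = df.iloc[idx].reset_index(drop=True)
    if stratify is False and boot["arm"].nunique() < df["arm"].nunique():
        # guarded degenerate resample: redraw once, then give up gracefully
        warnings.warn("unstratified resample lost an arm; redrawing",
                      RuntimeWarning, stacklevel=2)
        idx = rng.choice(len(df), size=len(df), replace=True)
        boot = df.iloc[idx].reset_index(drop=True)
    if has_missing:
        cfg = ImputationConfig(m=m_boot, k=imputation.k,
                               cycles=imputation.cycles,
                               seed=int(rng.integers(2 ** 31)))
        completed = impute_chained_pmm(boot, cfg,
                                       include_site=include_site_in_qaly)
    else:
        completed = [boot]
    acc: dict[str, list[float]] = {}
    for comp_df in completed:
        fit = fit_sur_incrementals(comp_df, include_site_in_qaly)
        for label, _ in COMPARISONS:
            dc, dq, _ = fit.incremental(label)
            acc.setdefault(f"delta_cost_{label}", []).append(dc)
            acc.setdefault(f"delta_qaly_{label}", []).append(dq)
        for arm_label, (mc, mq) in fit.adjusted_arm_means().items():
            acc.setdefault(f"mean_cost_{arm_label}", []).append(mc)
            acc.setdefault(f"mean_qaly_{arm_label}", []).append(mq)
    return {k: float(np.mean(v)) for k, v in acc.items()}


def bootstrap_draws(
    df: pd.DataFrame,
    B: int,
    imputation: ImputationConfig | None = None,
    seed: int = 0,
    stratify: bool = True,
    m_boot: int = 2,
    include_site_in_qaly: bool = True,
) -> pd.DataFrame:
    """B bootstrap draws of incremental estimates and adjusted arm means.

    Within each draw the imputation is repeated (m_boot imputations; only
    point estimates are needed per draw) before the SUR fit.  Each draw uses
    an independent seeded substream, so a rerun with the same seed reproduces
    every draw exactly.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    imputation = imputation or ImputationConfig()
    from .inference import ANALYSIS_NUMERIC_COLS
    numeric = [c for c in ANALYSIS_NUMERIC_COLS if c in df.columns]
    has_missing = df[numeric].isna().any().any()
    arm_indices = {
        a: np.flatnonzero((df["arm"] == a).to_numpy())
        for a in sorted(df["arm"].unique())
    }
    if stratify and any(len(ix) == 0 for ix in arm_indices.values()):
        raise ValueError("cannot stratify: an arm has no participants")
    rows = []
    for b, child in enumerate(np.random.SeedSequence(seed).spawn(B), start=1):
        rng = np.random.default_rng(child)
        draw = _one_draw(df, rng, arm_indices, imputation, m_boot,
                         stratify, include_site_in_qaly, has_missing)
        draw["b"] = b
        rows.append(draw)
    out = pd.DataFrame(rows)
    return out[["b"] + [c for c in out.columns if c != "b"]]


def ceac_pairwise_probability(inb: np.ndarray) -> float:
    """P(INB > 0) + half the exact ties, over bootstrap draws."""
    inb = np.asarray(inb, float)
    return float(np.mean(inb > 0) + 0.5 * np.mean(inb == 0))


def ceac_from_draws(
    draws: pd.DataFrame,
    lambdas: np.ndarray | None = None,
    mode: str = "pairwise",
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves from bootstrap draws.

    ``pairwise`` (default, matching two-option acceptability figures): for
    each comparison, the probability that the intervention's incremental net
    benefit beats zero, with the complementary TAU probability.  ``three_way``:
    per lambda, each arm's probability of having the strictly highest absolute
    net benefit among all three arms (exact ties split equally).
    """
    if len(draws) == 0:
        raise ValueError("empty draw set")
    lambdas = default_lambda_grid() if lambdas is None else np.asarray(lambdas, float)
    if len(lambdas) and (np.diff(lambdas) <= 0).any():
        raise ValueError("lambda grid must be ascending")
    rows = []
    if mode == "pairwise":
        for label, arm in COMPARISONS:
            dq = draws[f"delta_qaly_{label}"].to_numpy()
            dc = draws[f"delta_cost_{label}"].to_numpy()
            for lam in lambdas:
                p = ceac_pairwise_probability(lam * dq - dc)
                rows.append((lam, label, arm.value, p))
                rows.append((lam, label, Arm.TAU.value, 1.0 - p))
    elif mode == "three_way":
        qs = np.column_stack([draws[f"mean_qaly_{a}"].to_numpy()
                              for a in ARM_ORDER])
        cs = np.column_stack([draws[f"mean_cost_{a}"].to_numpy()
                              for a in ARM_ORDER])
        for lam in lambdas:
            nb = lam * qs - cs
            best = nb.max(axis=1, keepdims=True)
            is_best = nb == best
            share = is_best / is_best.sum(axis=1, keepdims=True)
            probs = share.mean(axis=0)
            for arm_label, p in zip(ARM_ORDER, probs):
                rows.append((lam, "three_way", arm_label, float(p)))
    else:
        raise ValueError(f"unknown CEAC mode {mode!r}")
    return pd.DataFrame(rows, columns=["lambda", "comparison", "arm",
                                       "probability"])


def plane_quadrant_summary(
    draws: pd.DataFrame, comparison: str
) -> tuple[dict[str, float], pd.DataFrame]:
    """Quadrant fractions and the (dQALY, dCost) point cloud for one comparison.

    Quadrants of the cost-effectiveness plane: NE (more effective, more
    costly), SE (more effective, cheaper), NW (less effective, more costly),
    SW (less effective, cheaper).  Boundary draws (a delta exactly zero) are
    assigned to the quadrant with the weakly negative sign, i.e. zeros count
    as "not more effective" / "not more costly"; with continuous bootstrap
    estimates this is measure-zero.
    """
    dq = draws[f"delta_qaly_{comparison}"].to_numpy()
    dc = draws[f"delta_cost_{comparison}"].to_numpy()
    ne = np.mean((dq > 0) & (dc > 0))
    se = np.mean((dq > 0) & (dc <= 0))
    nw = np.mean((dq <= 0) & (dc > 0))
    sw = np.mean((dq <= 0) & (dc <= 0))
    cloud = pd.DataFrame({"b": draws["b"], "delta_qaly": dq, "delta_cost": dc})
    return ({"NE": float(ne), "SE": float(se), "NW": float(nw),
             "SW": float(sw)}, cloud)
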