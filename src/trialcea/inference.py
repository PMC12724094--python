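"""Incremental cost and QALY estimation: chained-equation imputation with
predictive mean matching, seemingly unrelated regression (SUR), Rubin pooling
and dominance/ICER classification.

The analysis dataset has one row per randomised participant with arm, site,
baseline cost, baseline utility, follow-up cost and QALY.  Missing outcomes
(and, rarely, baseline utility) are multiply imputed by chained equations
with predictive mean matching from the nearest five donors.  Each completed
dataset is analysed with a two-equation SUR — follow-up cost on arm +
baseline cost + site, QALYs on arm + baseline utility (+ site) — estimated
jointly by feasible GLS so the cross-equation error correlation is carried
into the joint covariance of (dCost, dQALY).  Per-imputation estimates are
pooled with Rubin's rules (Barnard-Rubin small-sample degrees of freedom),
and each comparison is classified as dominant, dominated, or given an ICER.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .trial_data import Arm, COMPARISONS

__all__ = [
    "ANALYSIS_NUMERIC_COLS",
    "ImputationConfig",
    "IncrementalEstimate",
    "Decision",
    "SurFit",
    "assemble_analysis_dataset",
    "impute_chained_pmm",
    "fit_sur_incrementals",
    "available_case_ols",
    "pool_rubin",
    "pool_scalar",
    "classify_decision",
    "run_main_analysis",
    "MainAnalysisResult",
]

ANALYSIS_NUMERIC_COLS = ["baseline_cost", "baseline_utility",
                         "followup_cost", "qaly"]


@dataclass
class ImputationConfig:
    """Chained-equation imputation settings.

    m: number of imputed datasets (>= 2 so Rubin's between-imputation
    variance is estimable); k: donor-pool size for predictive mean matching;
    cycles: chained-equation sweeps per imputation; seed: master seed for the
    imputation random stream.
    """

    m: int = 10
    k: int = 5
    cycles: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("m must be >= 2 for Rubin variance estimation")
        if self.k < 1 or self.cycles < 1:
            raise ValueError("k and cycles must be positive")


@dataclass(frozen=True)
class IncrementalEstimate:
    """Adjusted incremental cost (GBP) and QALYs (years) vs TAU."""

    comparison: str
    delta_cost: float
    delta_qaly: float
    ci_cost: tuple[float, float]
    ci_qaly: tuple[float, float]
    vcov: np.ndarray  # 2x2 covariance of (delta_cost, delta_qaly)
    method: str = "MI+SUR"

    def __post_init__(self) -> None:
        if not (self.ci_cost[0] <= self.delta_cost <= self.ci_cost[1]):
            raise ValueError("cost CI does not bracket the point estimate")
        if not (self.ci_qaly[0] <= self.delta_qaly <= self.ci_qaly[1]):
            raise ValueError("QALY CI does not bracket the point estimate")


@dataclass(frozen=True)
class Decision:
    """Dominance class or ICER for one comparison.

    dominant: lower cost, more QALYs.  dominated: higher cost, fewer QALYs.
    icer_NE / icer_SW: north-east (more costly, more effective) or south-west
    (cheaper, less effective) quadrant, with ICER = dCost/dQALY.  Boundary
    cases (a delta exactly zero) take no ICER and fall to the weakly
    dominant/dominated class by cost sign.
    """

    decision: str  # dominant | dominated | icer_NE | icer_SW
    icer: float | None = None


def classify_decision(delta_cost: float, delta_qaly: float) -> Decision:
    if not (math.isfinite(delta_cost) and math.isfinite(delta_qaly)):
        raise ValueError("incremental estimates must be finite")
    if delta_qaly == 0.0:
        return Decision("dominated" if delta_cost > 0 else "dominant", None)
    if delta_cost == 0.0:
        return Decision("dominant" if delta_qaly > 0 else "dominated", None)
    if delta_cost > 0 and delta_qaly > 0:
        return Decision("icer_NE", delta_cost / delta_qaly)
    if delta_cost < 0 and delta_qaly < 0:
        return Decision("icer_SW", delta_cost / delta_qaly)
    if delta_cost < 0 and delta_qaly > 0:
        return Decision("dominant", None)
    return Decision("dominated", None)


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def assemble_analysis_dataset(
    roster: pd.DataFrame,
    cost_table: pd.DataFrame,
    qaly_frame: pd.DataFrame,
) -> pd.DataFrame:
    """One row per randomised participant, ready for imputation/regression.

    Baseline cost comes from the baseline recall period; follow-up cost is
    the w16+w28 total (missing if either period is missing); baseline utility
    is u0; the QALY is missing if any utility is missing.
    """
    wide = cost_table.pivot(index="participant_id", columns="period",
                            values="total_cost")
    for col in ("baseline", "w16", "w28"):
        if col not in wide.columns:
            wide[col] = np.nan
    df = roster[["participant_id", "arm", "site"]].copy()
    df["baseline_cost"] = df["participant_id"].map(wide["baseline"])
    df["followup_cost"] = df["participant_id"].map(wide["w16"] + wide["w28"])
    qmap = qaly_frame.set_index("participant_id")
    df["baseline_utility"] = df["participant_id"].map(qmap["u0"])
    df["qaly"] = df["participant_id"].map(qmap["qaly"])
    if df["arm"].isna().any() or df["site"].isna().any():
        raise ValueError("arm and site must be complete")
    return df


def _design_matrix(
    df: pd.DataFrame,
    covariates: Sequence[str],
    include_site: bool = True,
    drop_cols: Sequence[str] = (),
) -> tuple[np.ndarray, list[str]]:
    """Intercept + arm dummies (TAU reference) + covariates + site dummies."""
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["const"]
    for label, arm in COMPARISONS:
        cols.append((df["arm"] == arm.value).to_numpy(float))
        names.append(f"arm[{arm.value}]")
    for cov in covariates:
        cols.append(df[cov].to_numpy(float))
        names.append(cov)
    if include_site:
        sites = sorted(df["site"].unique())
        for s in sites[1:]:
            cols.append((df["site"] == s).to_numpy(float))
            names.append(f"site[{s}]")
    X = np.column_stack(cols)
    keep = [i for i, nm in enumerate(names) if nm not in drop_cols]
    return X[:, keep], [names[i] for i in keep]


def _drop_singular_sites(X: np.ndarray, names: list[str],
                         label: str) -> tuple[np.ndarray, list[str]]:
    """Restore full rank by dropping adjustment columns (never arm/const).

    Site indicators go first (the usual culprit: a site emptied or collapsed
    into one arm by resampling), then baseline covariates (degenerate
    datasets with constant baselines).  The randomised-arm contrasts stay
    estimable throughout.
    """
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return X, names
    droppable = [nm for nm in names if nm.startswith("site[")] \
        + [nm for nm in names if nm not in ("const",) and not nm.startswith(("arm[", "site["))]
    dropped: list[str] = []
    for nm in droppable:
        dropped.append(nm)
        keep = [i for i, n in enumerate(names) if n not in dropped]
        X2 = X[:, keep]
        if np.linalg.matrix_rank(X2) == X2.shape[1]:
            warnings.warn(
                f"singular design in {label} equation: dropping "
                f"{dropped} for this fit", RuntimeWarning, stacklevel=3)
            return X2, [names[i] for i in keep]
    raise np.linalg.LinAlgError(
        f"singular design matrix in {label} equation even after dropping "
        "adjustment columns (is an arm empty?)")


# ---------------------------------------------------------------------------
# chained-equation imputation with predictive mean matching
# ---------------------------------------------------------------------------

def _pmm_impute_column(
    y: np.ndarray,
    obs: np.ndarray,
    X: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One PMM draw for the missing entries of y given predictors X.

    Fits least squares on the observed rows, draws regression parameters from
    their approximate posterior, and for each missing row copies the observed
    value of a donor chosen uniformly from the k observed rows whose fitted
    means are nearest to the missing row's perturbed prediction (exact
    distance ties broken by a seeded uniform draw).
    """
    X_obs, y_obs, X_mis = X[obs], y[obs], X[~obs]
    n_obs, p = X_obs.shape
    beta_hat, *_ = np.linalg.lstsq(X_obs, y_obs, rcond=None)
    resid = y_obs - X_obs @ beta_hat
    dof = max(n_obs - p, 1)
    rss = float(resid @ resid)
    sigma2_star = rss / rng.chisquare(dof) if rss > 0 else 0.0
    xtx = X_obs.T @ X_obs
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        xtx_inv = np.linalg.pinv(xtx)
    cov = sigma2_star * xtx_inv
    # symmetrise against round-off before the Cholesky-like draw
    cov = (cov + cov.T) / 2.0
    try:
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(p) * max(sigma2_star, 1))
        beta_star = beta_hat + chol @ rng.standard_normal(p)
    except np.linalg.LinAlgError:
        beta_star = beta_hat
    pred_obs = X_obs @ beta_hat
    pred_mis = X_mis @ beta_star
    out = y.copy()
    kk = min(k, n_obs)
    # seeded infinitesimal jitter randomises exact-distance ties among donors
    scale = 1e-9 * (1.0 + float(np.max(np.abs(pred_obs), initial=0.0)))
    jitter = rng.random(n_obs) * scale
    dist = np.abs(pred_obs[None, :] - pred_mis[:, None]) + jitter[None, :]
    part = np.argpartition(dist, kk - 1, axis=1)[:, :kk]
    pick = rng.integers(kk, size=len(pred_mis))
    out[~obs] = y_obs[part[np.arange(len(pred_mis)), pick]]
    return out


def impute_chained_pmm(
    df: pd.DataFrame,
    config: ImputationConfig,
    include_site: bool = True,
) -> list[pd.DataFrame]:
    """Multiply impute missing numeric analysis variables.

    Each incomplete variable is imputed in turn from all other analysis
    variables plus arm and site indicators, cycling ``config.cycles`` times;
    every imputed value is an observed donor value (the PMM property).  With
    a fixed seed the output is reproducible; a dataset with no missing values
    returns m identical copies.
    """
    numeric = [c for c in ANALYSIS_NUMERIC_COLS if c in df.columns]
    missing_mask = {c: df[c].isna().to_numpy() for c in numeric}
    incomplete = [c for c in numeric if missing_mask[c].any()]
    for c in incomplete:
        if missing_mask[c].all():
            raise ValueError(f"variable {c!r} is 100% missing; cannot impute")
    if not incomplete:
        return [df.copy() for _ in range(config.m)]

    # static design block (intercept + arm + site indicators) built once
    X0, _ = _design_matrix(df, (), include_site=include_site)
    values = df[numeric].to_numpy(float)
    col_of = {c: j for j, c in enumerate(numeric)}

    streams = np.random.SeedSequence(config.seed).spawn(config.m)
    completed: list[pd.DataFrame] = []
    for child in streams:
        rng = np.random.default_rng(child)
        V = values.copy()
        for c in incomplete:  # initial fill: random observed draws
            j, mask = col_of[c], missing_mask[c]
            V[mask, j] = rng.choice(V[~mask, j], size=int(mask.sum()),
                                    replace=True)
        for _ in range(config.cycles):
            for c in incomplete:
                j = col_of[c]
                others = [col_of[v] for v in numeric if v != c]
                X = np.column_stack([X0, V[:, others]])
                V[:, j] = _pmm_impute_column(V[:, j], ~missing_mask[c], X,
                                             config.k, rng)
        work = df.copy()
        work[numeric] = V
        completed.append(work)
    return completed


# ---------------------------------------------------------------------------
# seemingly unrelated regression
# ---------------------------------------------------------------------------

@dataclass
class SurFit:
    """Joint two-equation fit (cost, QALY) on one completed dataset."""

    params_cost: dict[str, float]
    params_qaly: dict[str, float]
    cov: np.ndarray          # joint (p_c + p_q) covariance, FGLS
    names_cost: list[str]
    names_qaly: list[str]
    n: int
    covariate_means: dict[str, float] = field(default_factory=dict)

    @property
    def df_cost(self) -> int:
        return self.n - len(self.names_cost)

    @property
    def df_qaly(self) -> int:
        return self.n - len(self.names_qaly)

    def incremental(self, comparison: str) -> tuple[float, float, np.ndarray]:
        """(delta_cost, delta_qaly, 2x2 joint vcov) for one comparison."""
        arm = dict(COMPARISONS)[comparison]
        name = f"arm[{arm.value}]"
        ic = self.names_cost.index(name)
        iq = len(self.names_cost) + self.names_qaly.index(name)
        v = self.cov[np.ix_([ic, iq], [ic, iq])]
        return self.params_cost[name], self.params_qaly[name], v

    def adjusted_arm_means(self) -> dict[str, tuple[float, float]]:
        """Regression-adjusted mean (cost, qaly) per arm at covariate means."""
        out: dict[str, tuple[float, float]] = {}
        for arm in Arm:
            def pred(params: dict[str, float]) -> float:
                total = 0.0
                for nm, b in params.items():
                    if nm == "const":
                        total += b
                    elif nm.startswith("arm["):
                        total += b * (nm == f"arm[{arm.value}]")
                    else:
                        total += b * self.covariate_means[nm]
                return total
            out[arm.value] = (pred(self.params_cost), pred(self.params_qaly))
        return out


def fit_sur_incrementals(
    df: pd.DataFrame,
    include_site_in_qaly: bool = True,
    fgls: bool = True,
) -> SurFit:
    """Fit the two-equation system jointly on a completed dataset.

    Cost equation: followup_cost ~ arm + baseline_cost + site.
    QALY equation: qaly ~ arm + baseline_utility (+ site).
    Estimated by feasible GLS using the OLS residual cross-covariance; with
    identical regressor sets in both equations FGLS reproduces per-equation
    least squares exactly.  ``fgls=False`` stops at per-equation OLS (used for
    the available-case sensitivity analysis).
    """
    if df[ANALYSIS_NUMERIC_COLS].isna().any().any():
        raise ValueError("fit_sur_incrementals requires a completed dataset")
    n = len(df)
    Xc, names_c = _design_matrix(df, ["baseline_cost"], include_site=True)
    Xq, names_q = _design_matrix(df, ["baseline_utility"],
                                 include_site=include_site_in_qaly)
    Xc, names_c = _drop_singular_sites(Xc, names_c, "cost")
    Xq, names_q = _drop_singular_sites(Xq, names_q, "QALY")
    yc = df["followup_cost"].to_numpy(float)
    yq = df["qaly"].to_numpy(float)

    bc, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    bq, *_ = np.linalg.lstsq(Xq, yq, rcond=None)
    rc = yc - Xc @ bc
    rq = yq - Xq @ bq
    S = np.array([[rc @ rc, rc @ rq], [rq @ rc, rq @ rq]]) / n

    pc, pq = Xc.shape[1], Xq.shape[1]
    # a (near-)singular residual covariance (an exact-fit degenerate dataset,
    # or perfectly correlated errors) makes the FGLS weighting undefined;
    # per-equation OLS is then already exact
    sd_c, sd_q = math.sqrt(S[0, 0]) if S[0, 0] > 0 else 0.0, \
        math.sqrt(S[1, 1]) if S[1, 1] > 0 else 0.0
    r = S[0, 1] / (sd_c * sd_q) if sd_c > 0 and sd_q > 0 else 1.0
    if fgls and (sd_c == 0 or sd_q == 0 or abs(r) > 1 - 1e-10):
        fgls = False
    if fgls:
        # scale each equation by its residual s.d. (leaves the coefficients
        # unchanged) and solve the GLS problem in least-squares form for
        # numerical accuracy: with identical regressor sets the result then
        # matches per-equation OLS to ~1e-10
        Xcs, ycs = Xc / sd_c, yc / sd_c
        Xqs, yqs = Xq / sd_q, yq / sd_q
        Rinv = np.linalg.inv(np.array([[1.0, r], [r, 1.0]]))
        C = np.linalg.cholesky(Rinv).T  # upper triangular, C'C = Rinv
        G = np.block([[C[0, 0] * Xcs, C[0, 1] * Xqs],
                      [np.zeros((n, pc)), C[1, 1] * Xqs]])
        h = np.concatenate([C[0, 0] * ycs + C[0, 1] * yqs, C[1, 1] * yqs])
        beta, *_ = np.linalg.lstsq(G, h, rcond=None)
        cov = np.linalg.inv(G.T @ G)
        bc, bq = beta[:pc], beta[pc:]
    else:
        # per-equation OLS with homoskedastic per-equation covariance and the
        # residual cross-covariance for the off-diagonal block
        s2c = (rc @ rc) / max(n - pc, 1)
        s2q = (rq @ rq) / max(n - pq, 1)
        XtXc_inv = np.linalg.inv(Xc.T @ Xc)
        XtXq_inv = np.linalg.inv(Xq.T @ Xq)
        cov = np.zeros((pc + pq, pc + pq))
        cov[:pc, :pc] = s2c * XtXc_inv
        cov[pc:, pc:] = s2q * XtXq_inv
        cross = S[0, 1] * XtXc_inv @ Xc.T @ Xq @ XtXq_inv
        cov[:pc, pc:] = cross
        cov[pc:, :pc] = cross.T

    cov_means: dict[str, float] = {"baseline_cost": float(df["baseline_cost"].mean()),
                                   "baseline_utility": float(df["baseline_utility"].mean())}
    for nm in set(names_c + names_q):
        if nm.startswith("site["):
            s = nm[5:-1]
            cov_means[nm] = float((df["site"] == s).mean())
            try:
                cov_means[nm] = float((df["site"].astype(str) == s).mean())
            except Exception:  # pragma: no cover
                pass
    return SurFit(dict(zip(names_c, bc)), dict(zip(names_q, bq)),
                  cov, names_c, names_q, n, cov_means)


def available_case_ols(
    df: pd.DataFrame,
    include_site_in_qaly: bool = True,
    alpha: float = 0.05,
) -> list[IncrementalEstimate]:
    """Complete-case per-equation OLS (no imputation).

    Each equation uses its own complete cases, so the two equations may be
    fitted on different participants; the cross-equation covariance is not
    estimated (set to zero).
    """
    out = []
    cost_rows = df.dropna(subset=["followup_cost", "baseline_cost"])
    qaly_rows = df.dropna(subset=["qaly", "baseline_utility"])
    Xc, names_c = _design_matrix(cost_rows, ["baseline_cost"], include_site=True)
    Xq, names_q = _design_matrix(qaly_rows, ["baseline_utility"],
                                 include_site=include_site_in_qaly)
    Xc, names_c = _drop_singular_sites(Xc, names_c, "cost")
    Xq, names_q = _drop_singular_sites(Xq, names_q, "QALY")
    yc = cost_rows["followup_cost"].to_numpy(float)
    yq = qaly_rows["qaly"].to_numpy(float)
    bc, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    bq, *_ = np.linalg.lstsq(Xq, yq, rcond=None)
    s2c = float((yc - Xc @ bc) @ (yc - Xc @ bc)) / (len(yc) - Xc.shape[1])
    s2q = float((yq - Xq @ bq) @ (yq - Xq @ bq)) / (len(yq) - Xq.shape[1])
    covc = s2c * np.linalg.inv(Xc.T @ Xc)
    covq = s2q * np.linalg.inv(Xq.T @ Xq)
    for label, arm in COMPARISONS:
        nm = f"arm[{arm.value}]"
        ic, iq = names_c.index(nm), names_q.index(nm)
        dc, dq = float(bc[ic]), float(bq[iq])
        se_c, se_q = math.sqrt(covc[ic, ic]), math.sqrt(covq[iq, iq])
        tc = stats.t.ppf(1 - alpha / 2, len(yc) - Xc.shape[1])
        tq = stats.t.ppf(1 - alpha / 2, len(yq) - Xq.shape[1])
        out.append(IncrementalEstimate(
            label, dc, dq,
            (dc - tc * se_c, dc + tc * se_c),
            (dq - tq * se_q, dq + tq * se_q),
            np.diag([covc[ic, ic], covq[iq, iq]]),
            method="available-case OLS",
        ))
    return out


# ---------------------------------------------------------------------------
# Rubin pooling
# ---------------------------------------------------------------------------

def _barnard_rubin_df(m: int, B: float, T: float, nu_com: float) -> float:
    """Small-sample degrees of freedom for the pooled t reference."""
    if T <= 0 or B <= 0:
        return nu_com
    lam = (1 + 1 / m) * B / T
    if lam < 1e-12:
        return nu_com
    nu_old = (m - 1) / lam ** 2
    nu_obs = (nu_com + 1) / (nu_com + 3) * nu_com * (1 - lam)
    return 1.0 / (1.0 / nu_old + 1.0 / nu_obs)


def pool_scalar(points: Sequence[float], variances: Sequence[float],
                nu_com: float, alpha: float = 0.05
                ) -> tuple[float, float, tuple[float, float]]:
    """Rubin's rules for one scalar: (pooled point, total variance, CI)."""
    m = len(points)
    if m < 2:
        raise ValueError("need m >= 2 estimates to pool")
    q = float(np.mean(points))
    W = float(np.mean(variances))
    B = float(np.var(points, ddof=1))
    T = W + (1 + 1 / m) * B
    df = _barnard_rubin_df(m, B, T, nu_com)
    half = stats.t.ppf(1 - alpha / 2, df) * math.sqrt(T) if T > 0 else 0.0
    return q, T, (q - half, q + half)


def pool_rubin(
    comparison: str,
    points: np.ndarray,        # m x 2 array of (delta_cost, delta_qaly)
    vcovs: np.ndarray,         # m x 2 x 2 within-imputation covariances
    nu_com_cost: float,
    nu_com_qaly: float,
    alpha: float = 0.05,
    method: str = "MI+SUR",
) -> IncrementalEstimate:
    """Pool per-imputation (dCost, dQALY) estimates into one estimate.

    Point = mean of points; total covariance = mean within-covariance +
    (1 + 1/m) x between-covariance; CIs use a t reference with Barnard-Rubin
    degrees of freedom per component.
    """
    points = np.asarray(points, float)
    vcovs = np.asarray(vcovs, float)
    m = points.shape[0]
    dc, T_c, ci_c = pool_scalar(points[:, 0], vcovs[:, 0, 0], nu_com_cost, alpha)
    dq, T_q, ci_q = pool_scalar(points[:, 1], vcovs[:, 1, 1], nu_com_qaly, alpha)
    W = vcovs.mean(axis=0)
    Bmat = np.cov(points.T, ddof=1) if m > 1 else np.zeros((2, 2))
    Bmat = np.atleast_2d(Bmat)
    Tmat = W + (1 + 1 / m) * Bmat
    return IncrementalEstimate(comparison, dc, dq, ci_c, ci_q, Tmat,
                               method=method)


# ---------------------------------------------------------------------------
# main analysis driver
# ---------------------------------------------------------------------------

@dataclass
class MainAnalysisResult:
    mi_estimates: list[IncrementalEstimate]
    available_case: list[IncrementalEstimate]
    decisions: dict[tuple[str, str], Decision]  # (method, comparison)
    m: int

    def frame(self) -> pd.DataFrame:
        """Long table mirroring a cost-effectiveness results layout."""
        rows = []
        for est in self.mi_estimates + self.available_case:
            dec = self.decisions[(est.method, est.comparison)]
            rows.append({
                "comparison": est.comparison,
                "method": est.method,
                "delta_cost": est.delta_cost,
                "cost_ci_lo": est.ci_cost[0],
                "cost_ci_hi": est.ci_cost[1],
                "delta_qaly": est.delta_qaly,
                "qaly_ci_lo": est.ci_qaly[0],
                "qaly_ci_hi": est.ci_qaly[1],
                "decision": dec.decision,
                "icer": dec.icer if dec.icer is not None else np.nan,
            })
        return pd.DataFrame(rows)


def run_main_analysis(
    df: pd.DataFrame,
    imputation: ImputationConfig | None = None,
    include_site_in_qaly: bool = True,
) -> MainAnalysisResult:
    """MI + SUR primary analysis plus the available-case OLS sensitivity."""
    imputation = imputation or ImputationConfig()
    completed = impute_chained_pmm(df, imputation,
                                   include_site=include_site_in_qaly)
    per_comp: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {
        label: [] for label, _ in COMPARISONS}
    dfs: dict[str, tuple[float, float]] = {}
    for comp_df in completed:
        fit = fit_sur_incrementals(comp_df, include_site_in_qaly)
        for label, _ in COMPARISONS:
            dc, dq, v = fit.incremental(label)
            per_comp[label].append((np.array([dc, dq]), v))
        dfs = {label: (fit.df_cost, fit.df_qaly) for label, _ in COMPARISONS}
    mi_estimates = []
    for label, _ in COMPARISONS:
        pts = np.stack([p for p, _ in per_comp[label]])
        vcs = np.stack([v for _, v in per_comp[label]])
        mi_estimates.append(pool_rubin(label, pts, vcs, *dfs[label]))
    ac = available_case_ols(df, include_site_in_qaly)
    decisions = {(e.method, e.comparison): classify_decision(e.delta_cost,
                                                             e.delta_qaly)
                 for e in mi_estimates + ac}
    return MainAnalysisResult(mi_estimates, ac, decisions, imputation.m)
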