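"""Imputation, SUR estimation, Rubin pooling and decision classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trialcea.inference import (
    ImputationConfig,
    classify_decision,
    fit_sur_incrementals,
    impute_chained_pmm,
    pool_rubin,
    pool_scalar,
    run_main_analysis,
)

from conftest import make_gaussian_dataset


# ---------------------------------------------------------------------------
# chained-equation PMM imputation
# ---------------------------------------------------------------------------

def mcar(df, col, frac, seed):
    out = df.copy()
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(df), size=int(frac * len(df)), replace=False)
    out.loc[out.index[idx], col] = np.nan
    return out


def test_no_missing_data_returns_identical_copies(gaussian_dataset):
    completed = impute_chained_pmm(gaussian_dataset, ImputationConfig(m=3))
    assert len(completed) == 3
    for c in completed:
        pd.testing.assert_frame_equal(c, gaussian_dataset)


def test_imputed_values_are_observed_donor_values(gaussian_dataset):
    df = mcar(gaussian_dataset, "followup_cost", 0.25, seed=1)
    df = mcar(df, "qaly", 0.2, seed=2)
    observed_cost = set(df["followup_cost"].dropna())
    observed_qaly = set(df["qaly"].dropna())
    for c in impute_chained_pmm(df, ImputationConfig(m=3, seed=9)):
        assert not c[["followup_cost", "qaly"]].isna().any().any()
        assert set(c["followup_cost"]) <= observed_cost
        assert set(c["qaly"]) <= observed_qaly


def test_imputation_is_seed_reproducible(gaussian_dataset):
    df = mcar(gaussian_dataset, "qaly", 0.2, seed=3)
    a = impute_chained_pmm(df, ImputationConfig(m=2, seed=5))
    b = impute_chained_pmm(df, ImputationConfig(m=2, seed=5))
    for x, y in zip(a, b):
        pd.testing.assert_frame_equal(x, y)


def test_imputation_error_conditions(gaussian_dataset):
    with pytest.raises(ValueError):
        ImputationConfig(m=1)
    df = gaussian_dataset.copy()
    df["qaly"] = np.nan
    with pytest.raises(ValueError, match="100% missing"):
        impute_chained_pmm(df, ImputationConfig(m=2))


def test_mcar_pooled_mean_is_unbiased():
    """Simulation oracle: under 20% MCAR the pooled imputed mean of the
    follow-up cost tracks the complete-data mean (bias within 2 Monte-Carlo
    standard errors over 50 replications)."""
    diffs = []
    for rep in range(50):
        full = make_gaussian_dataset(n_per_arm=334, seed=100 + rep)  # n=1002
        complete_mean = full["followup_cost"].mean()
        holed = mcar(full, "followup_cost", 0.2, seed=500 + rep)
        completed = impute_chained_pmm(holed, ImputationConfig(m=5, cycles=5,
                                                               seed=rep))
        pooled_mean = np.mean([c["followup_cost"].mean() for c in completed])
        diffs.append(pooled_mean - complete_mean)
    bias = np.mean(diffs)
    mc_se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
    assert abs(bias) < 2 * mc_se


# ---------------------------------------------------------------------------
# SUR
# ---------------------------------------------------------------------------

def test_sur_equals_ols_with_identical_regressors():
    """Kruskal equivalence: identical regressor sets in both equations make
    the joint FGLS estimate coincide with per-equation least squares."""
    sm = pytest.importorskip("statsmodels.api")
    df = make_gaussian_dataset(n_per_arm=80, seed=42, shared_baseline=True)
    fit = fit_sur_incrementals(df)
    X = pd.get_dummies(df[["arm", "site"]], drop_first=False)
    exog = pd.DataFrame({
        "const": 1.0,
        "arm[AV-BRF]": (df["arm"] == "AV-BRF").astype(float),
        "arm[AV-EXT]": (df["arm"] == "AV-EXT").astype(float),
        "bc": df["baseline_cost"],
        "site[S2]": (df["site"] == "S2").astype(float),
        "site[S3]": (df["site"] == "S3").astype(float),
        "site[S4]": (df["site"] == "S4").astype(float),
    })
    ols_cost = sm.OLS(df["followup_cost"], exog).fit()
    ols_qaly = sm.OLS(df["qaly"], exog).fit()
    for name in ("arm[AV-BRF]", "arm[AV-EXT]"):
        assert fit.params_cost[name] == pytest.approx(ols_cost.params[name],
                                                      abs=1e-8)
        assert fit.params_qaly[name] == pytest.approx(ols_qaly.params[name],
                                                      abs=1e-8)


def test_sur_zero_effect_recovery():
    """With no true arm effects at large n both incrementals are within
    three standard errors of zero."""
    df = make_gaussian_dataset(n_per_arm=5000, seed=11)
    fit = fit_sur_incrementals(df)
    for comparison in ("BRF_vs_TAU", "EXT_vs_TAU"):
        dc, dq, v = fit.incremental(comparison)
        assert abs(dc) < 3 * np.sqrt(v[0, 0])
        assert abs(dq) < 3 * np.sqrt(v[1, 1])


def test_sur_duplicating_rows_leaves_points_unchanged(gaussian_dataset):
    fit1 = fit_sur_incrementals(gaussian_dataset)
    doubled = pd.concat([gaussian_dataset, gaussian_dataset],
                        ignore_index=True)
    fit2 = fit_sur_incrementals(doubled)
    for comparison in ("BRF_vs_TAU", "EXT_vs_TAU"):
        a = fit1.incremental(comparison)
        b = fit2.incremental(comparison)
        assert a[0] == pytest.approx(b[0], rel=1e-9)
        assert a[1] == pytest.approx(b[1], rel=1e-9)


def test_sur_adjusted_means_difference_equals_incrementals(gaussian_dataset):
    fit = fit_sur_incrementals(gaussian_dataset)
    means = fit.adjusted_arm_means()
    dc, dq, _ = fit.incremental("EXT_vs_TAU")
    assert means["AV-EXT"][0] - means["TAU"][0] == pytest.approx(dc, rel=1e-9)
    assert means["AV-EXT"][1] - means["TAU"][1] == pytest.approx(dq, rel=1e-9)


def test_sur_collinear_site_falls_back_with_warning():
    """A site occupied by exactly one arm makes its indicator collinear with
    the arm indicator; the fit drops site and warns rather than failing."""
    df = make_gaussian_dataset(n_per_arm=40, seed=3)
    df["site"] = np.where(df["arm"] == "AV-EXT", "S9", "S1")
    with pytest.warns(RuntimeWarning, match="site"):
        fit = fit_sur_incrementals(df)
    assert not any(nm.startswith("site[") for nm in fit.names_cost)


def test_sur_requires_completed_dataset(gaussian_dataset):
    df = gaussian_dataset.copy()
    df.loc[0, "qaly"] = np.nan
    with pytest.raises(ValueError):
        fit_sur_incrementals(df)


# ---------------------------------------------------------------------------
# Rubin pooling
# ---------------------------------------------------------------------------

def test_pooling_identical_estimates_has_zero_between_variance():
    pts = np.tile([100.0, 0.01], (5, 1))
    vcv = np.tile(np.diag([4.0, 1e-6]), (5, 1, 1))
    est = pool_rubin("EXT_vs_TAU", pts, vcv, 300, 300)
    assert est.delta_cost == 100.0 and est.delta_qaly == 0.01
    np.testing.assert_allclose(est.vcov, vcv[0])


def test_pooling_point_is_mean_of_points():
    q, _, _ = pool_scalar([100.0, 300.0], [1.0, 1.0], nu_com=100)
    assert q == 200.0


@given(st.lists(st.tuples(st.floats(-100, 100), st.floats(0.1, 10)),
                min_size=2, max_size=8))
@settings(max_examples=50, deadline=None)
def test_pooled_variance_at_least_mean_within_variance(pairs):
    pts = [p for p, _ in pairs]
    ws = [w for _, w in pairs]
    _, total, _ = pool_scalar(pts, ws, nu_com=50)
    assert total >= np.mean(ws) - 1e-12


def test_mi_pipeline_equals_direct_fit_without_missing_data(gaussian_dataset):
    result = run_main_analysis(gaussian_dataset, ImputationConfig(m=4, seed=1))
    direct = fit_sur_incrementals(gaussian_dataset)
    for est in result.mi_estimates:
        dc, dq, _ = direct.incremental(est.comparison)
        assert est.delta_cost == pytest.approx(dc, abs=1e-10)
        assert est.delta_qaly == pytest.approx(dq, abs=1e-12)


# ---------------------------------------------------------------------------
# decisions
# ---------------------------------------------------------------------------

nonzero_cost = st.floats(min_value=-1e5, max_value=1e5).filter(lambda x: x != 0)
nonzero_qaly = st.floats(min_value=-1.0, max_value=1.0).filter(lambda x: x != 0)


@given(nonzero_cost, nonzero_qaly)
@settings(max_examples=200, deadline=None)
def test_decision_quadrants_exhaustive_and_exclusive(dc, dq):
    d = classify_decision(dc, dq)
    expected = {(True, True): "icer_NE", (True, False): "dominated",
                (False, True): "dominant", (False, False): "icer_SW"}
    assert d.decision == expected[(dc > 0, dq > 0)]
    if d.decision.startswith("icer"):
        assert d.icer == pytest.approx(dc / dq)
    else:
        assert d.icer is None


def test_decision_examples():
    assert classify_decision(-196.0, 0.0173).decision == "dominant"
    assert classify_decision(100.0, -0.01).decision == "dominated"
    d = classify_decision(319.0, 0.0159)
    assert d.decision == "icer_NE"
    assert d.icer == pytest.approx(319 / 0.0159, rel=1e-12)
    assert d.icer == pytest.approx(20063, abs=1)


def test_decision_boundary_and_scaling():
    assert classify_decision(150.0, 0.0).icer is None
    assert classify_decision(150.0, 0.0).decision == "dominated"
    assert classify_decision(-150.0, 0.0).decision == "dominant"
    base = classify_decision(319.0, 0.0159)
    scaled = classify_decision(319.0 * 3.5, 0.0159)
    assert scaled.icer == pytest.approx(3.5 * base.icer, rel=1e-12)
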