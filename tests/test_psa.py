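"""Bootstrap draws, net benefit, acceptability curves and plane summaries."""

import numpy as np
import pandas as pd
import pytest

from trialcea.inference import ImputationConfig, fit_sur_incrementals
from trialcea.psa import (
    bootstrap_draws,
    ceac_from_draws,
    ceac_pairwise_probability,
    default_lambda_grid,
    net_benefit,
    net_benefit_absolute,
    plane_quadrant_summary,
)

from conftest import make_gaussian_dataset


@pytest.fixture(scope="module")
def draws_complete(dataset_complete):
    """200 stratified draws on the no-missingness synthetic trial."""
    return bootstrap_draws(dataset_complete, B=200,
                           imputation=ImputationConfig(seed=1), seed=21)


def test_net_benefit_arithmetic():
    assert net_benefit(0.0, 0.0159, 319.0) == -319.0
    assert net_benefit(20_000.0, 0.0159, 319.0) == pytest.approx(-1.0)
    assert net_benefit(50_000.0, 0.0, 0.0) == 0.0
    assert net_benefit_absolute(20_000.0, 0.25, 4000.0) == 1000.0
    with pytest.raises(ValueError):
        net_benefit(-1.0, 0.0, 0.0)


def test_lambda_grid_shape():
    grid = default_lambda_grid()
    assert len(grid) == 51 and grid[0] == 0 and grid[-1] == 100_000


def test_bootstrap_draw_count_and_reproducibility(dataset_missing):
    a = bootstrap_draws(dataset_missing, B=7,
                        imputation=ImputationConfig(seed=2), seed=5)
    assert len(a) == 7 and list(a["b"]) == list(range(1, 8))
    b = bootstrap_draws(dataset_missing, B=7,
                        imputation=ImputationConfig(seed=2), seed=5)
    pd.testing.assert_frame_equal(a, b)
    c = bootstrap_draws(dataset_missing, B=7,
                        imputation=ImputationConfig(seed=2), seed=6)
    assert not np.allclose(a["delta_cost_EXT_vs_TAU"], c["delta_cost_EXT_vs_TAU"])


def test_degenerate_dataset_gives_identical_draws():
    """If every row within an arm is identical, resampling cannot change the
    dataset, so every bootstrap draw is identical (constant baselines are
    dropped from the design with a warning)."""
    import warnings

    rows = []
    for arm, fc, q in [("TAU", 1000.0, 0.25), ("AV-BRF", 900.0, 0.26),
                       ("AV-EXT", 800.0, 0.27)]:
        rows += [{"participant_id": f"{arm}{i}", "arm": arm, "site": "S1",
                  "baseline_cost": 120.0, "baseline_utility": 0.5,
                  "followup_cost": fc, "qaly": q} for i in range(10)]
    df = pd.DataFrame(rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        draws = bootstrap_draws(df, B=12, seed=3)
    for col in draws.columns:
        if col != "b":
            assert draws[col].nunique() == 1


def test_percentile_interval_matches_analytic_ci():
    """With homoskedastic errors and no missingness the bootstrap percentile
    interval of the incremental cost agrees with the SUR analytic CI
    (half-widths within ~10%)."""
    df = make_gaussian_dataset(n_per_arm=150, seed=19)
    draws = bootstrap_draws(df, B=600, seed=23)
    fit = fit_sur_incrementals(df)
    for comparison in ("BRF_vs_TAU", "EXT_vs_TAU"):
        _, _, v = fit.incremental(comparison)
        analytic_half = 1.96 * np.sqrt(v[0, 0])
        lo, hi = np.percentile(draws[f"delta_cost_{comparison}"], [2.5, 97.5])
        boot_half = (hi - lo) / 2
        assert boot_half == pytest.approx(analytic_half, rel=0.10)


def test_ceac_brute_force_count():
    """Four draws with INB {+1,+2,-1,-3} at lambda=0 give probability 0.5."""
    draws = pd.DataFrame({
        "b": [1, 2, 3, 4],
        "delta_cost_BRF_vs_TAU": [-1.0, -2.0, 1.0, 3.0],
        "delta_qaly_BRF_vs_TAU": [0.0, 0.0, 0.0, 0.0],
        "delta_cost_EXT_vs_TAU": [0.0, 0.0, 0.0, 0.0],
        "delta_qaly_EXT_vs_TAU": [0.0, 0.0, 0.0, 0.0],
    })
    ceac = ceac_from_draws(draws, np.array([0.0]))
    brf = ceac[(ceac["arm"] == "AV-BRF")]["probability"].iloc[0]
    assert brf == 0.5
    # all-positive INB -> probability 1
    assert ceac_pairwise_probability(np.array([1.0, 2.0, 0.5])) == 1.0
    # exact zero ties split equally
    assert ceac_pairwise_probability(np.array([0.0, 0.0])) == 0.5


def test_ceac_probabilities_partition(draws_complete):
    for mode in ("pairwise", "three_way"):
        ceac = ceac_from_draws(draws_complete, mode=mode)
        sums = ceac.groupby(["lambda", "comparison"])["probability"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)
        assert ceac["probability"].between(0, 1).all()


def test_ceac_limits_match_sign_fractions(draws_complete):
    """lambda=0 recovers the cost-saving fraction; lambda -> infinity the
    QALY-gaining fraction."""
    ceac = ceac_from_draws(draws_complete, np.array([0.0, 1e9]))
    for comparison, arm in (("BRF_vs_TAU", "AV-BRF"), ("EXT_vs_TAU", "AV-EXT")):
        dc = draws_complete[f"delta_cost_{comparison}"].to_numpy()
        dq = draws_complete[f"delta_qaly_{comparison}"].to_numpy()
        sel = ceac[(ceac["comparison"] == comparison) & (ceac["arm"] == arm)]
        at0 = sel[sel["lambda"] == 0]["probability"].iloc[0]
        atinf = sel[sel["lambda"] == 1e9]["probability"].iloc[0]
        assert at0 == np.mean(dc < 0) + 0.5 * np.mean(dc == 0)
        assert atinf == np.mean(dq > 0) + 0.5 * np.mean(dq == 0)


def test_ceac_ranking_equals_direct_counting(draws_complete):
    """Net-benefit ranking over {intervention, TAU} using absolute per-arm
    net benefits reproduces the direct P(INB>0) + 0.5 P(INB=0) count."""
    lambdas = default_lambda_grid()
    ceac = ceac_from_draws(draws_complete, lambdas)
    for comparison, arm in (("BRF_vs_TAU", "AV-BRF"), ("EXT_vs_TAU", "AV-EXT")):
        qs_i = draws_complete[f"mean_qaly_{arm}"].to_numpy()
        cs_i = draws_complete[f"mean_cost_{arm}"].to_numpy()
        qs_t = draws_complete["mean_qaly_TAU"].to_numpy()
        cs_t = draws_complete["mean_cost_TAU"].to_numpy()
        sel = ceac[(ceac["comparison"] == comparison) & (ceac["arm"] == arm)]
        for lam in lambdas:
            nb_i = lam * qs_i - cs_i
            nb_t = lam * qs_t - cs_t
            ranked = np.mean(nb_i > nb_t) + 0.5 * np.mean(nb_i == nb_t)
            direct = sel[sel["lambda"] == lam]["probability"].iloc[0]
            assert direct == pytest.approx(ranked, abs=1e-9)


def test_plane_quadrants_partition_and_consistency(draws_complete):
    for comparison in ("BRF_vs_TAU", "EXT_vs_TAU"):
        fractions, cloud = plane_quadrant_summary(draws_complete, comparison)
        assert sum(fractions.values()) == pytest.approx(1.0, abs=1e-12)
        assert len(cloud) == len(draws_complete)
        # at lambda=0 the CEAC equals the cheaper-side (SE+SW) mass
        ceac0 = ceac_from_draws(draws_complete, np.array([0.0]))
        arm = {"BRF_vs_TAU": "AV-BRF", "EXT_vs_TAU": "AV-EXT"}[comparison]
        p0 = ceac0[(ceac0["comparison"] == comparison)
                   & (ceac0["arm"] == arm)]["probability"].iloc[0]
        assert p0 == pytest.approx(fractions["SE"] + fractions["SW"], abs=1e-12)


def test_all_draws_southeast_gives_fraction_one():
    draws = pd.DataFrame({
        "b": [1, 2],
        "delta_cost_EXT_vs_TAU": [-10.0, -5.0],
        "delta_qaly_EXT_vs_TAU": [0.01, 0.02],
    })
    fractions, _ = plane_quadrant_summary(draws, "EXT_vs_TAU")
    assert fractions["SE"] == 1.0


def test_empty_draws_and_bad_grid_rejected(draws_complete):
    with pytest.raises(ValueError):
        ceac_from_draws(draws_complete.iloc[:0])
    with pytest.raises(ValueError):
        ceac_from_draws(draws_complete, np.array([1000.0, 500.0]))
    with pytest.raises(ValueError):
        bootstrap_draws(make_gaussian_dataset(10, seed=1), B=0)
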