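"""Shared fixtures: packaged value set, synthetic trial bundles, and a plain
Gaussian analysis-dataset factory for regression/imputation tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from trialcea.qaly import crosswalk_value_set
from trialcea.synthetic_trial import SynthConfig, generate_trial, impose_missingness


@pytest.fixture(scope="session")
def value_set():
    return crosswalk_value_set()


@pytest.fixture(scope="session")
def bundle_complete(value_set):
    """Default-condition synthetic trial, no missingness."""
    return generate_trial(SynthConfig(), seed=11, value_set=value_set)


@pytest.fixture(scope="session")
def bundle_missing(bundle_complete):
    """Same trial with MAR missingness imposed."""
    return impose_missingness(bundle_complete, seed=12)


@pytest.fixture(scope="session")
def dataset_complete(bundle_complete):
    return bundle_complete.analysis_dataset()


@pytest.fixture(scope="session")
def dataset_missing(bundle_missing):
    return bundle_missing.analysis_dataset()


def make_gaussian_dataset(
    n_per_arm: int = 100,
    seed: int = 0,
    cost_effects: tuple[float, float] = (0.0, 0.0),
    qaly_effects: tuple[float, float] = (0.0, 0.0),
    shared_baseline: bool = False,
) -> pd.DataFrame:
    """Plain Gaussian analysis dataset with known arm effects.

    ``shared_baseline=True`` sets baseline_utility equal to baseline_cost so
    both regression equations share an identical regressor set.
    """
    rng = np.random.default_rng(seed)
    arms = np.repeat(["TAU", "AV-BRF", "AV-EXT"], n_per_arm)
    n = len(arms)
    site = rng.integers(1, 5, n)
    baseline_cost = rng.gamma(2.0, 500.0, n)
    baseline_utility = (baseline_cost if shared_baseline
                        else np.clip(rng.normal(0.6, 0.2, n), -0.5, 1.0))
    eff_c = np.select([arms == "AV-BRF", arms == "AV-EXT"], cost_effects, 0.0)
    eff_q = np.select([arms == "AV-BRF", arms == "AV-EXT"], qaly_effects, 0.0)
    followup_cost = (800.0 + 0.8 * baseline_cost + eff_c
                     + rng.normal(0.0, 600.0, n))
    qaly = (0.05 + 0.4 * np.asarray(baseline_utility, float) * 0.5 + eff_q
            + rng.normal(0.0, 0.05, n))
    return pd.DataFrame({
        "participant_id": [f"G{i:05d}" for i in range(n)],
        "arm": arms,
        "site": [f"S{s}" for s in site],
        "baseline_cost": baseline_cost,
        "baseline_utility": baseline_utility,
        "followup_cost": followup_cost,
        "qaly": qaly,
    })


@pytest.fixture()
def gaussian_dataset():
    return make_gaussian_dataset(seed=7)
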