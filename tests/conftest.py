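import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_260_901)


@pytest.fixture(scope="session")
def tiny_table():
    """Ten-subject table with one categorical and one metric covariate."""
    return pd.DataFrame({
        "subject_id": [f"S{i}" for i in range(10)],
        "baseline_weight": [1.0, 0.8, 1.2, 1.1, 0.9, 1.0, 1.3, 0.7, 1.0, 1.0],
        "response": [1, 0, 1, 1, 0, 1, 0, 1, 1, 0],
        "colour": pd.Categorical(
            ["red", "blue", None, "red", "blue", "red", None, "blue",
             "red", "red"], categories=["red", "blue"]),
        "height": [1.2, 1.5, np.nan, 1.7, 1.4, 1.6, 1.3, np.nan, 1.8, 1.5],
    })


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared across model-level tests."""
    from longipw import generate_cohort, realism_preset

    return generate_cohort(realism_preset(n_subjects=1500, seed=11))


@pytest.fixture(scope="session")
def small_design(small_cohort):
    from longipw import build_design_matrix, prepare_covariates

    cfg = small_cohort.config
    prepared, kept = prepare_covariates(
        small_cohort.table, [c.name for c in cfg.covariates],
        baseline_weights=small_cohort.table["baseline_weight"].to_numpy())
    design = build_design_matrix(prepared, kept)
    y = prepared["response"].to_numpy(dtype=float)
    w = prepared["baseline_weight"].to_numpy(dtype=float)
    return design, y, w
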