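import numpy as np
import pandas as pd
import pytest

import zigreg as zg


@pytest.fixture(scope="session")
def study_config():
    """Study-condition configuration: published slopes, calibrated intercepts."""
    return zg.calibrated_config(n=14823, seed=20170803)


@pytest.fixture(scope="session")
def simulated_cohort(study_config):
    """One simulated cohort at the analysed sample size."""
    df = zg.simulate_zig(study_config)
    dm = zg.build_design(df, study_config.spec)
    return df, dm


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture()
def small_table():
    """Tiny hand-written participant table with one incomplete row."""
    return pd.DataFrame(
        {
            "id": [1, 2, 3, 4],
            "gender": ["female", "male", "Female", "MALE"],
            "age_years": [50.0, 35.0, 60.0, 44.0],
            "education": ["basic", "graduate", "high school", "college"],
            "income_usd": [5000.0, 12000.0, np.nan, 3000.0],
            "weekly_minutes": [0.0, 300.0, 90.0, 150.0],
        }
    )


def intercept_only(n):
    """Design matrix with a single all-ones column."""
    return zg.DesignMatrix(columns=("intercept",), values=np.ones((n, 1)))


@pytest.fixture()
def small_logistic_data(rng):
    """n<=200 logistic instance with p=3 columns and known generator."""
    n = 200
    X = np.column_stack([np.ones(n), rng.normal(size=n), rng.integers(0, 2, n)])
    eta = 0.3 + 0.8 * X[:, 1] - 0.5 * X[:, 2]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return X, y
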