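import numpy as np
import pandas as pd
import pytest

import brainpath as bp


@pytest.fixture(scope="session")
def cohort_small() -> pd.DataFrame:
    """An 800-participant synthetic cohort under default study conditions."""
    return bp.generate_cohort(bp.GeneratorConfig(n_participants=800, seed=11))


@pytest.fixture(scope="session")
def cohort_scored(cohort_small) -> pd.DataFrame:
    scored = bp.score_cohort(cohort_small)
    return cohort_small.assign(
        libra_score=scored["libra_score"], libra_tertile=scored["libra_tertile"]
    )


@pytest.fixture(scope="session")
def path_data() -> pd.DataFrame:
    """Known-truth serial-mediation dataset (default injected coefficients)."""
    return bp.generate_path_dataset(2000, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)


def make_record(**overrides):
    """A complete raw participant record with no factor present by default."""
    base = dict(
        age=55.0,
        sex="female",
        education="medium",
        glucose_status="normal",
        diet_score=3,
        alcohol_g_week=100.0,
        mvpa_min_week=300.0,
        smoking_status="never",
        bmi=24.0,
        sbp=120.0,
        dbp=75.0,
        antihypertensive_med=0,
        total_cholesterol=5.0,
        fasting_glucose=5.2,
        ogtt_glucose=5.5,
        diabetes_med=0,
        heart_disease=0,
        egfr=90.0,
        albuminuria=0,
        phq9=2,
        mini_depression=0,
    )
    base.update(overrides)
    return base
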