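import numpy as np
import pytest

from biaperf.cohort import (
    FEMALE_PROTOCOL,
    MALE_PROTOCOL,
    CohortConfig,
    SyntheticAthlete,
)
from biaperf.types import AthleteProfile


@pytest.fixture
def female_protocol():
    return FEMALE_PROTOCOL


@pytest.fixture
def male_protocol():
    return MALE_PROTOCOL


@pytest.fixture
def noiseless_config():
    return CohortConfig(n_per_sex=14, seed=7).noiseless()


@pytest.fixture
def mean_female_athlete():
    """Athlete carrying the female cohort's mean traits exactly."""
    return SyntheticAthlete(
        profile=AthleteProfile(
            athlete_id="F00", sex="female", body_mass_kg=62.8,
            height_cm=166.4, age_yr=22.9, hr_max=188.0,
        ),
        true_vo2max=55.6,
        true_ge_pct=16.6,
        true_frac_util=0.821,
        true_aod=49.2,
        bc_speed_m_s=4.7,
    )


@pytest.fixture
def mean_male_athlete():
    return SyntheticAthlete(
        profile=AthleteProfile(
            athlete_id="M00", sex="male", body_mass_kg=74.8,
            height_cm=178.8, age_yr=24.0, hr_max=191.0,
        ),
        true_vo2max=66.0,
        true_ge_pct=18.4,
        true_frac_util=0.813,
        true_aod=57.7,
        bc_speed_m_s=6.1,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
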