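import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from disattrib.additive_hazard import ModelParams
from disattrib.survey_data import AgeGrouping, StudyDesign
from disattrib.synthetic_cohort import (
    GeneratorConfig,
    default_standard_population,
    default_truth,
    generate_cohort,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def std_pop():
    return default_standard_population()


@pytest.fixture(scope="session")
def truth_20k():
    return default_truth(n=20_000, seed=42)


@pytest.fixture(scope="session")
def cohort_20k(truth_20k):
    return generate_cohort(truth_20k)


def make_small_design() -> StudyDesign:
    """Two diseases, one education level, two bands, single sex in use."""
    grouping = AgeGrouping(
        background_bands=((25, 55), (55, math.inf)),
        rank_bands=((25, 55), (55, math.inf)),
    )
    return StudyDesign(
        diseases=("d1", "d2"), education_levels=("low",), grouping=grouping
    )


def make_small_truth(n: int = 5000, seed: int = 11) -> GeneratorConfig:
    design = make_small_design()
    params = ModelParams(
        alpha=np.array([[0.08], [0.25]]),
        gamma=np.array([1.0, 1.8]),
        delta=np.array([[0.35], [0.50]]),
        design=design,
    )
    prevalence = np.zeros((2, 2, 1, 2))
    prevalence[0] = 0.20
    prevalence[1] = 0.12
    return GeneratorConfig(
        n=n,
        seed=seed,
        disease_prevalence=prevalence,
        true_params={"male": params, "female": params},
        education_mix=np.array([1.0]),
        age_distribution=np.array([0.6, 0.4]),
        sex_mix=np.array([1.0, 0.0]),
        weight_dispersion=0.5,
        design=design,
    )


@pytest.fixture()
def small_truth():
    return make_small_truth()
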