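import warnings

import pytest

from prosash import PatientCovariates, load_published_model
from prosash.model_core import linear_predictor_batch
from prosash.synthetic_cohort import CohortConfig, generate_dataset


@pytest.fixture(scope="session")
def published():
    return load_published_model()


@pytest.fixture(scope="session")
def worked_patient():
    """The example patient whose survival curve the model documentation prints."""
    return PatientCovariates(
        age=71, vascular_invasion=False, ecog=1, afp=850.3, albumin=46,
        creatinine=35.36, ast=29, ehs=False, aetiology="other")


@pytest.fixture(scope="session")
def cohort_factory(published):
    """Synthetic cohorts from the published model, keyed by (n, seed)."""
    cache = {}

    def make(n=500, seed=0, **kwargs):
        key = (n, seed, tuple(sorted(kwargs.items())))
        if key not in cache:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cache[key] = generate_dataset(
                    CohortConfig(n=n, seed=seed, **kwargs), published)
        return cache[key]

    return make


@pytest.fixture(scope="session")
def eta_of(published):
    def compute(df):
        return linear_predictor_batch(df, published)

    return compute
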