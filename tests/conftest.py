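import numpy as np
import pytest
from hypothesis import settings

import growthkit as gk

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def refs():
    return gk.default_reference()


@pytest.fixture(scope="session")
def profile():
    return gk.EffectProfile()


@pytest.fixture(scope="session")
def small_cohort(refs, profile):
    """A modest default-profile cohort shared across tests."""
    cfg = gk.GeneratorConfig(n_normal=1200, n_obese=1200, seed=11)
    return gk.generate_cohort(cfg, profile, refs)


@pytest.fixture(scope="session")
def annotated_small(refs, small_cohort):
    ann = gk.annotate_observations(small_cohort.children,
                                   small_cohort.observations, refs)
    filtered, analytes, _ = gk.apply_inclusion_filters(
        small_cohort.children, ann, analytes=small_cohort.analytes)
    return filtered, analytes


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
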