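import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hypnoeeg.pipeline import PipelineConfig
from hypnoeeg.synthetic import CohortSpec, GroupParams, generate_cohort

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_spec(seed=7, n_young=3, n_elderly=3) -> CohortSpec:
    spec = CohortSpec(seed=seed)
    return dataclasses.replace(
        spec,
        young=dataclasses.replace(spec.young, n=n_young),
        elderly=dataclasses.replace(spec.elderly, n=n_elderly),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 3+3-subject cohort with the default (study-condition) parameters."""
    return generate_cohort(small_spec())


@pytest.fixture(scope="session")
def full_cohort():
    """The full 18 young + 12 elderly study-sized cohort."""
    return generate_cohort(CohortSpec(seed=42))


@pytest.fixture(scope="session")
def full_stage_table(full_cohort):
    from hypnoeeg.pipeline import analyze_cohort

    return analyze_cohort(full_cohort, PipelineConfig())
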