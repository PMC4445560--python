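import numpy as np
import pytest
from hypothesis import settings

from dloopabc.coalescent_sim import (
    DemographicModel,
    MutationModel,
    SampleSpec,
    SamplingScheme,
)
from dloopabc.synthetic_data import StudyTemplate, build_study, make_toy_fixtures

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toys():
    return make_toy_fixtures()


@pytest.fixture(scope="session")
def constant_model():
    """Single-deme constant-size demography (N = 1,000 everywhere)."""
    n = 1_000.0
    return DemographicModel(n_anc=n, n_d=n, n_ne_modern=n, n_e_modern=n)


@pytest.fixture(scope="session")
def mut_240():
    return MutationModel(seq_length=240)


@pytest.fixture(scope="session")
def desk_study():
    """Scaled-down study layout shared by the slower inference tests."""
    template = StudyTemplate(scale=0.1)
    scheme, meta = build_study(template, seed=42)
    return template, scheme, meta


def pair_scheme(t1: float = 0.0, t2: float = 0.0) -> SamplingScheme:
    entries = (
        [SampleSpec("NE", t1, 2)]
        if t1 == t2
        else [SampleSpec("NE", t1, 1), SampleSpec("NE", t2, 1)]
    )
    return SamplingScheme(entries)
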