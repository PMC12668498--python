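import numpy as np
import pytest

import scolimorph as sm
from scolimorph import model_builder as mb


@pytest.fixture(scope="session")
def template():
    return sm.generate_template()


@pytest.fixture(scope="session")
def base_model(template):
    """Default base model; session-scoped, treat as read-only (copy to mutate)."""
    return mb.build_base_model(template)


@pytest.fixture(scope="session")
def scoliotic_subject():
    """Severe lumbar scoliosis: Cobb 75 deg, LL 34 deg, slope 27.7 deg, apex L2."""
    spec = sm.severe_scoliosis_spec()
    ls, truth = sm.synthetic.generate_subject(spec)
    return ls, truth


@pytest.fixture(scope="session")
def morphed_model(scoliotic_subject):
    _, truth = scoliotic_subject
    return mb.build_subject_model(truth.template, truth.landmarks_model)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
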