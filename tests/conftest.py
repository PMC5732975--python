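import numpy as np
import pytest

from assrdeconv.sequences import CLAD_ISIS_MS, make_clad_sequence, to_impulse_train
from assrdeconv.synthdata import TemplateSpec, make_template

#: Coarse test grid: every loop ISI is an integer number of samples and the
#: 204.8 ms sweep is exactly 512 samples.
FS_TEST = 2500.0


@pytest.fixture(scope="session")
def fs():
    return FS_TEST


@pytest.fixture(scope="session")
def clad_sequence():
    return make_clad_sequence(CLAD_ISIS_MS)


@pytest.fixture(scope="session")
def clad_train(clad_sequence):
    return to_impulse_train(clad_sequence, FS_TEST)


@pytest.fixture(scope="session")
def template_spec():
    return TemplateSpec(fs=FS_TEST)


@pytest.fixture(scope="session")
def template(template_spec):
    return make_template(template_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20170)
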