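import numpy as np
import pytest

from neomhc.synth import make_micro_groove
from neomhc.threader import TemplateComplex, groove_residues


@pytest.fixture(scope="session")
def micro_groove():
    return make_micro_groove(0)


@pytest.fixture(scope="session")
def occluded_groove():
    return make_micro_groove(0, occlude_pocket_b=True)


@pytest.fixture(scope="session")
def template(micro_groove):
    tc = TemplateComplex(micro_groove.copy(), "A", "C")
    tc.groove_resseqs = groove_residues(tc)
    return tc


@pytest.fixture(scope="session")
def occluded_template(occluded_groove):
    tc = TemplateComplex(occluded_groove.copy(), "A", "C")
    tc.groove_resseqs = groove_residues(tc)
    return tc


@pytest.fixture
def rng():
    return np.random.default_rng(20180130)
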