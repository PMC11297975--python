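import pytest

from salmotrial.bayes import PriorSpec
from salmotrial.trial_data import organ_lipid_table


@pytest.fixture(scope="session")
def pen_table():
    """The packaged per-pen organ/lipid table (12 pens, 8 variables)."""
    return organ_lipid_table()


@pytest.fixture(scope="session")
def default_prior():
    return PriorSpec()
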