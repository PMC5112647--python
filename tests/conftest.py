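import pytest

from orsim import DurationModel, ORPolicy, neostigmine_arm, sugammadex_arm
from orsim.variates import DistributionSpec


@pytest.fixture
def base_policy():
    return ORPolicy()


@pytest.fixture
def neostigmine():
    return neostigmine_arm()


@pytest.fixture
def sugammadex():
    return sugammadex_arm()


@pytest.fixture
def deterministic_model():
    """All durations replaced by their base-case means: a hand-computable day."""
    return DurationModel(
        procedure=DistributionSpec("fixed", (72.9,)),
        turnover=DistributionSpec("fixed", (35.6,)),
        first_patient_delay=DistributionSpec("fixed", (10.0,)),
        cleanup=DistributionSpec("fixed", (15.0,)),
    )
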