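import pytest
from hypothesis import settings

from alphapk import simulate

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def default_spec():
    """Default synthetic cohort mirroring the three-patient study design."""
    return simulate.CohortSpec(seed=12345)
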