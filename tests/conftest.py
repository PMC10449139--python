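import pytest
from hypothesis import settings

import tcm_equity as te

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def proportional_panel():
    """Synthetic panel with proportional allocation (gamma=0, no noise)."""
    return te.generate(seed=11)


@pytest.fixture(scope="session")
def wealth_skewed_panel():
    """Synthetic panel whose allocation favours richer provinces."""
    return te.generate(seed=11, gamma=1.0)


@pytest.fixture(scope="session")
def noisy_panel():
    """Synthetic panel with mild allocation noise."""
    return te.generate(seed=7, gamma=0.5, noise=0.3)


@pytest.fixture(scope="session")
def institutions_model():
    return te.fit_gm11(te.table1_series("institutions"))
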