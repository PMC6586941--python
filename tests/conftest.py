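import numpy as np
import pytest

from plmsim import presets
from plmsim.io import make_synthetic_session
from plmsim.model import PiecewiseLinearControlModel


@pytest.fixture
def default_user():
    return presets.default_user()


@pytest.fixture
def default_decoder():
    return presets.default_decoder()


@pytest.fixture
def default_task():
    return presets.default_task()


@pytest.fixture(scope="session")
def synthetic_session():
    """One 300-s canonical synthetic block (shared across fitting tests)."""
    return make_synthetic_session(presets.default_user(), presets.default_decoder(),
                                  presets.default_task(), 300.0, seed=11)


@pytest.fixture(scope="session")
def fitted_results(synthetic_session):
    """Model fit at the true delay on the shared synthetic block."""
    model = PiecewiseLinearControlModel.from_session(synthetic_session)
    return model.fit(delay_tau=10)
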