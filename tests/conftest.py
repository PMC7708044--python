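import pytest

from nanobeam.calibration import calibrate_default
from nanobeam.mechanics import MaterialParams


@pytest.fixture(scope="session")
def material():
    return MaterialParams()


@pytest.fixture(scope="session")
def calib():
    """Two-step calibration on the measured C170L/C170N means (shared:
    deterministic and moderately expensive)."""
    return calibrate_default()
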