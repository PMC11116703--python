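import numpy as np
import pytest

from wfgica.atlas import make_atlas
from wfgica.pipeline import RunConfig, run_study
from wfgica.synthetic import default_design


#: reduced problem size used by the shared end-to-end fixture; the study-scale
#: configuration lives in tests/test_acceptance.py
SMALL_SIM = dict(fps=10.0, dur_per_state=120.0, height=40, width=40)


@pytest.fixture(scope="session")
def atlas64():
    return make_atlas(64, 64, seed=0)


@pytest.fixture(scope="session")
def design64(atlas64):
    """Calibrated default design at the 10 Hz analysis rate."""
    return default_design(atlas64, fps=10.0)


@pytest.fixture(scope="session")
def uncalibrated_design(atlas64):
    """Default design without the coupling calibration (cheap construction)."""
    return default_design(atlas64, fps=10.0, calibrate=False)


@pytest.fixture(scope="session")
def small_study():
    """One complete synthetic study run at reduced scale (seed 0, K=8)."""
    cfg = RunConfig(seed=0, k=8, simulate=dict(SMALL_SIM))
    result, truth = run_study(cfg)
    return result, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
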