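import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from arguide import build_patient_frame, build_exp1_plate  # noqa: E402


@pytest.fixture(scope="session")
def frame():
    return build_patient_frame()


@pytest.fixture(scope="session")
def plates():
    return [build_exp1_plate(50.0), build_exp1_plate(100.0)]


@pytest.fixture(scope="session")
def bead_positions_world(plates):
    """The 8 bead positions in frame (= world) coordinates."""
    return np.vstack([p.targets_in_frame().points for p in plates])
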