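import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pricklemap as pm

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def simple_stem() -> pm.StemRecord:
    """Three-leaf right-handed spiral with two interior prickles."""
    organs = [
        pm.OrganObservation(pm.OrganKind.LEAF, 0.0, 0.0),
        pm.OrganObservation(pm.OrganKind.PRICKLE, 200.0, 20.0),
        pm.OrganObservation(pm.OrganKind.LEAF, 140.0, 50.0),
        pm.OrganObservation(pm.OrganKind.PRICKLE, 300.0, 75.0),
        pm.OrganObservation(pm.OrganKind.LEAF, 280.0, 100.0),
    ]
    return pm.StemRecord(stem_id="s1", organs=organs)


@pytest.fixture
def recovery_truth() -> pm.ModelParams:
    return pm.ModelParams(alpha=0.2, beta=0.1, T_a=-0.5, T_b=0.2, T_c=1.5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
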