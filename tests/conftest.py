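from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from helpers import make_cohort

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture
def t1_cohort():
    """Three participants; C's only entry is a non-informative answer."""
    return make_cohort({
        "A": {"Height": "170 cm", "Weight": "70 kg"},
        "B": {"Height": "180", "Eye Color": "blue"},
        "C": {"Height": "unsure"},
    })


@pytest.fixture
def t2_cohort():
    """Three participants, all values valid: Height score 3, Weight score 2."""
    return make_cohort({
        "A": {"Height": "170", "Weight": "70"},
        "B": {"Height": "180", "Weight": "80"},
        "C": {"Height": "175"},
    })
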