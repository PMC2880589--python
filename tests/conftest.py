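import math

import pytest
from hypothesis import HealthCheck, settings

import gcmature as g

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

KT = 0.59


@pytest.fixture(scope="session")
def default_spec():
    return g.default_spectrum()


@pytest.fixture
def anchor_params():
    """Reference setting: 50% mutated daughters, b = 0.7, germline one
    kcal/mol weaker than neutral (Ka_in/Ka* = 0.18), pooled-spleen size."""
    return g.ModelParams(p_mutated_daughter=0.5, b=0.7, N0=1e5, X_star_offset_in=1.0)


def ka_to_offset(ka_ratio: float, kT: float = KT) -> float:
    return -kT * math.log(ka_ratio)
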