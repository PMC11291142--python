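import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_simplex_states(rng, n):
    """(n, 3) rows of valid (X, Y, Z) genotype frequencies."""
    return rng.dirichlet([1.0, 1.0, 1.0], size=n)


def random_params(rng):
    from parentaldrive import DriveParams

    return DriveParams(
        k1=float(rng.uniform()),
        k2=float(rng.uniform()),
        S=float(rng.uniform()),
        type1=str(rng.choice(["maternal", "paternal"])),
        type2=str(rng.choice(["maternal", "paternal"])),
    )
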