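import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import uterosim as us

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def unit_tissue_fields():
    """1x1 fields with anatomy exactly 1 and a low threshold."""
    return us.fields_from_matrices([[1.0]], [[0.558]])


@pytest.fixture(scope="session")
def canonical_config():
    """Isolated-strip configuration: repetitive-contraction regime."""
    return us.default_config(9)  # 1x1, 300 steps, init 1, min 0.6, 10/20, 3/0.2


@pytest.fixture(scope="session")
def canonical_run(canonical_config, unit_tissue_fields):
    return us.run(canonical_config, unit_tissue_fields)


def seed_pairs(master: int, n: int):
    """Deterministic panel of (anatomy_seed, threshold_seed) pairs."""
    rng = np.random.default_rng(master)
    return [
        (int(a), int(t))
        for a, t in zip(rng.integers(1000, 2000, n), rng.integers(2000, 3000, n))
    ]
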