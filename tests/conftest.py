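import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import lpfs

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_xm(values, prefix="s"):
    """Wrap a raw array in an ExpressionMatrix with generated identifiers."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return lpfs.ExpressionMatrix(
        values=values,
        sample_ids=tuple(f"{prefix}{i}" for i in range(n)),
        gene_ids=tuple(f"g{j}" for j in range(m)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_xm(rng):
    return make_xm(rng.uniform(0.1, 2.0, size=(6, 5)))
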