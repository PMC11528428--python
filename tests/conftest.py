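import numpy as np
import pytest

import smlmeq as sq


@pytest.fixture(scope="session")
def small_field():
    """One modest simulated hetero field reused by read-only tests."""
    gt, frame = sq.simulate_field(160.0, -2.0, pattern_area_um2=50.0, seed=7)
    return gt, frame


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def csr_disk(n, radius_nm, rng, center=(0.0, 0.0)):
    """n uniform points in a disk (nm) -- a CSR helper for tests."""
    r = radius_nm * np.sqrt(rng.uniform(0, 1, n))
    th = rng.uniform(0, 2 * np.pi, n)
    return np.column_stack([center[0] + r * np.cos(th), center[1] + r * np.sin(th)])
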