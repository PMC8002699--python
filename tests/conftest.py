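import numpy as np
import pytest

from trackreject import benchmark as bm
from trackreject.filtering import FilterConfig
from trackreject.scene import CameraIntrinsics


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def intr_small():
    """A tiny camera for fast unit tests (integer principal point)."""
    return CameraIntrinsics(fx=20.0, fy=20.0, cx=8.0, cy=6.0, width=16, height=12,
                            d_min=0.3, d_max=3.0, df=4e-6, bn=4e-6)


@pytest.fixture
def cfg_mid():
    """A mid-range filter configuration."""
    return FilterConfig(n_trans=0.005, n_rot=0.05, vf=0.9,
                        w_exp=0.3, w_gaus=0.6, w_uni=0.1, K=20, dt=1.0 / 30.0)


@pytest.fixture(scope="session")
def benchmark_dataset():
    """The packaged synthetic benchmark table (built once per session)."""
    df, _ = bm.make_benchmark(seed=1, n_configs=120)
    return df
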