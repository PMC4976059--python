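import numpy as np
import pytest

from pmctseq import PhantomSpec, make_phantom_series


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(bool)
    b = b.astype(bool)
    denom = a.sum() + b.sum()
    return 2.0 * (a & b).sum() / denom if denom else 1.0


@pytest.fixture(scope="session")
def small_series():
    """Shrinking, HU-rising series on a desk-scale 64-cube grid."""
    spec = PhantomSpec(
        grid_shape=(64, 64, 64),
        v0_ml=8.0,
        vol_rate_ml_per_h=-0.2,
        schedule_h=(2.0, 8.0, 14.0),
        rng_seed=11,
    )
    return spec, make_phantom_series(spec)


@pytest.fixture(scope="session")
def small_static_volume(small_series):
    spec, series = small_series
    return spec, series[0][0], series[0][1]
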