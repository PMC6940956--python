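import numpy as np
import pytest

from droughtlight.ojip import JipLandmarks
from droughtlight.synth import TransientSpec


@pytest.fixture
def worked_landmarks() -> JipLandmarks:
    """Hand-checkable landmark set: VJ=0.5, VI=0.8, M0=0.8, phiP0=0.8."""
    return JipLandmarks(
        F0=500.0, F300=900.0, FJ=1500.0, FI=2100.0, FM=2500.0,
        VJ=0.5, VI=0.8, M0=0.8,
    )


@pytest.fixture
def clean_spec() -> TransientSpec:
    return TransientSpec(noise_sd=0.0, seed=11)


def random_landmarks(rng: np.random.Generator) -> JipLandmarks:
    """A random valid landmark set (0 < VJ < VI < 1, M0 > 0, F0 < FM)."""
    f0 = rng.uniform(100.0, 1000.0)
    fm = f0 * rng.uniform(1.5, 6.0)
    vj = rng.uniform(0.05, 0.9)
    vi = rng.uniform(vj, 0.98)
    f300 = f0 + rng.uniform(0.02, 0.9 * vj) * (fm - f0)
    return JipLandmarks(
        F0=f0, F300=f300, FJ=f0 + vj * (fm - f0), FI=f0 + vi * (fm - f0),
        FM=fm, VJ=vj, VI=vi, M0=4.0 * (f300 - f0) / (fm - f0),
    )
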