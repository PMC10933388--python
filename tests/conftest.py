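import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from psoct.phantom import LayerSpec, PhantomSpec, simulate_tomogram


@pytest.fixture(scope="session")
def slab_tomogram():
    """Noiseless homogeneous slab, Δn = 1e-3, 500 μm deep."""
    layer = LayerSpec(thickness_um=500.0, birefringence=1e-3)
    spec = PhantomSpec(layers=(layer,), seed=0)
    return spec, simulate_tomogram(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
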