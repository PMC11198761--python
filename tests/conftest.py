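import numpy as np
import pytest

from slipscan import PhantomSpec, generate_phantom, compute_noss


def small_spec(**kw):
    """A fast phantom: 32x32x20 grid, 8 mm tumor, sphere well inside."""
    defaults = dict(
        grid_shape=(32, 32, 20),
        tumor_center_vox=(15.5, 15.5, 9.5),
        tumor_radius_mm=8.0,
        seed=11,
    )
    defaults.update(kw)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def small_phantom():
    return generate_phantom(small_spec())


@pytest.fixture(scope="session")
def small_noss(small_phantom):
    ds = small_phantom
    return compute_noss(ds.phase, brain_mask=ds.brain_mask)["noss"]


@pytest.fixture(scope="session")
def default_phantom():
    """Full-size default phantom, half the surface slipping."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
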