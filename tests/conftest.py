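import numpy as np
import pytest

from dcetensor import Ellipsoid, KineticProfile, PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_spec():
    """Compact phantom for fast pipeline tests: 40x40x20 grid, one washout
    tumour, one fatty confounder, low noise."""
    return PhantomSpec(
        shape=(40, 40, 20),
        tumour_ellipsoids=(
            Ellipsoid((16, 19, 10), (6, 6, 4), KineticProfile("washout", 4, 100.0, 0.3)),
        ),
        fat_regions=(
            Ellipsoid((28, 16, 9), (3, 3, 2), KineticProfile("plateau", 4, 25.0, 0.0)),
        ),
        noise_sigma=2.0,
        seed=0,
    )


@pytest.fixture
def small_study(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture
def default_spec():
    """The canonical desk-scale phantom (64x64x32, n=6, washout tumour
    peaking at frame 4, noise sigma = 5% of the tumour peak)."""
    return PhantomSpec()
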