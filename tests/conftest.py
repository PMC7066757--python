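import numpy as np
import pytest

from spectreg.phantom import PhantomSpec, generate_knee_phantom
from spectreg.registration import RegistrationConfig

# Reduced grid with the same physical extent as the default phantom: unit
# tests exercise behaviour, not resolution.
SMALL_SPEC = PhantomSpec(shape=(80, 80, 48), spacing=(1.96, 1.96, 5.0))


@pytest.fixture(scope="session")
def small_spec():
    return SMALL_SPEC


@pytest.fixture(scope="session")
def small_phantom():
    """Pre-operative (no implant) phantom on the reduced grid."""
    return generate_knee_phantom(SMALL_SPEC, "p0")


@pytest.fixture(scope="session")
def small_postop_phantom():
    import dataclasses

    spec = dataclasses.replace(SMALL_SPEC, implant=True, seed=1)
    return generate_knee_phantom(spec, "p0", "postop")


@pytest.fixture()
def quick_affine_config():
    """Cheap affine settings for behavioural tests (not the tuned defaults)."""
    return RegistrationConfig.affine_defaults(
        seed=0, max_iterations=250, n_points=1000
    )


@pytest.fixture()
def quick_bspline_config():
    return RegistrationConfig.bspline_defaults(
        seed=0, max_iterations=100, n_points=1000,
        smoothing_factors=((4, 4, 2), (2, 2, 1)),
        grid_multipliers=((4, 4, 2), (2, 2, 1)),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
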