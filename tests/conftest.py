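import numpy as np
import pytest

from cctpipe.lesions import RigidTransform
from cctpipe.synth import PhantomParams, gen_mri_subject, make_template


@pytest.fixture(scope="session")
def small_params() -> PhantomParams:
    return PhantomParams.small()


@pytest.fixture(scope="session")
def small_subject(small_params):
    """Coarse phantom with a known mild misregistration; shared (read-only)."""
    params = PhantomParams.small(
        applied_rigid=RigidTransform((0.0, 0.0, 2.0), (1.5, -1.0, 0.5))
    )
    return gen_mri_subject(params, seed=11)


@pytest.fixture(scope="session")
def aligned_subject(small_params):
    """Coarse phantom with identity transforms (no misregistration)."""
    return gen_mri_subject(small_params, seed=7)


@pytest.fixture(scope="session")
def small_template(small_params):
    return make_template(small_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
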