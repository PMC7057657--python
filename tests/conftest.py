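import numpy as np
import pytest

from shootseg import PhantomSpec, generate_phantom

#: Small phantom used by unit tests: one branch, one compound leaf per branch,
#: short trunk — generates in well under a second.
TINY_SPEC = PhantomSpec(
    n_branches=1,
    leaves_per_branch=1,
    trunk_length_range=(14.0, 16.0),
    branch_length_range=(10.0, 12.0),
    petiole_length_range=(7.0, 9.0),
    leaflet_semiaxis_a_range=(4.0, 6.0),
    leaflet_semiaxis_b_range=(3.0, 4.0),
    seed=7,
)


@pytest.fixture(scope="session")
def tiny_phantom():
    return generate_phantom(TINY_SPEC)


@pytest.fixture(scope="session")
def tiny_phantom_pair():
    """Two small phantoms with both classes present, for train/test checks."""
    from dataclasses import replace

    return generate_phantom(TINY_SPEC), generate_phantom(replace(TINY_SPEC, seed=8))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
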