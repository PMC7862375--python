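import numpy as np
import pytest

from octaprof.binarize import BinarizationParams, NormalCCDatabase
from octaprof.synth import SyntheticCaseParams, generate_case, make_normal_cc_database


@pytest.fixture(scope="session")
def small_params():
    """Fast 512-px study parameters (half the default resolution)."""
    return SyntheticCaseParams(image_size_px=512, seed=77)


@pytest.fixture(scope="session")
def small_case(small_params):
    return generate_case(small_params, "X")


@pytest.fixture(scope="session")
def small_bparams(small_params):
    return BinarizationParams.for_grid(small_params.image_size_px)


@pytest.fixture(scope="session")
def small_normal_db(small_params):
    return NormalCCDatabase(make_normal_cc_database(small_params, 5))


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
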