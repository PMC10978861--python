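import numpy as np
import pytest

import femurcut as fc

# A cheap phantom configuration used throughout the unit tests: coarser
# in-plane sampling than the default study grid, same anatomy and slice
# thickness, so every stage runs in well under a second.
SMALL_SPEC = dict(shape=(24, 40, 52), spacing=(3.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def small_phantom():
    return fc.generate(fc.PhantomSpec(**SMALL_SPEC, rng_seed=11))


@pytest.fixture(scope="session")
def small_phantom_clean():
    return fc.generate(fc.PhantomSpec(**SMALL_SPEC, noise_sd_hu=0.0, rng_seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def random_mask(rng, shape=(6, 7, 8), p=0.3, spacing=(1.0, 1.0, 1.0)):
    data = rng.random(shape) < p
    if not data.any():
        data[tuple(s // 2 for s in shape)] = True
    return fc.BinaryMask(data, spacing)
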