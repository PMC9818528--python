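import numpy as np
import pytest

import mammobalance as mb

# compact phantom used throughout the suite: a small breast at 0.2 mm/px
# keeps lesion synthesis fast while staying within realistic geometry
SMALL = dict(height_px=320, width_px=256, pixel_spacing_mm=0.2)


@pytest.fixture(scope="session")
def small_phantom() -> mb.Mammogram:
    return mb.generate_phantom(mb.PhantomSpec(seed=42, **SMALL))


@pytest.fixture(scope="session")
def small_preprocessed(small_phantom) -> mb.Mammogram:
    return mb.preprocess(small_phantom, target=256)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
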