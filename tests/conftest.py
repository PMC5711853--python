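import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _reference oracles


@pytest.fixture
def rng():
    return np.random.default_rng(20170)


@pytest.fixture
def small_scene():
    """One deterministic 192x128 scene with 25% cover."""
    from canopyvi import SceneParams, generate_canopy_scene

    params = SceneParams(green_fraction=0.25, chlorosis=0.2, purpling=0.1,
                         image_size=(192, 128), seed=11)
    return generate_canopy_scene(params)
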