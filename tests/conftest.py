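import numpy as np
import pytest

from lumigain.stimuli import ScreenGeometry


@pytest.fixture
def small_screen() -> ScreenGeometry:
    """Coarse screen keeping full-field stimulus tests fast."""
    return ScreenGeometry(width_deg=60.0, height_deg=60.0, degrees_per_pixel=2.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
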