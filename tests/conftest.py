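import numpy as np
import pytest

from mycoquant import SlidePhantomSpec, generate_slide, generate_classification_set


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def clean_slide():
    """A small aligned phantom: 3 vertical x 3 horizontal lines, no noise."""
    spec = SlidePhantomSpec(
        width_px=756,
        height_px=756,
        grid_spacing_px=252,
        rotation_deg=0.0,
        noise_sigma=0.0,
        class_labels=[3] * 9,
        seed=11,
    )
    return generate_slide(spec)


@pytest.fixture(scope="session")
def patch_set():
    """Small balanced 4-class patch set shared by classifier tests."""
    return generate_classification_set(60, seed=21)
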