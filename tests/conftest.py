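import numpy as np
import pytest

from spiraltremor import (SpiralSpec, binarize_spiral, render_spiral,
                          spiral_trace, thin)


@pytest.fixture(scope="session")
def clean_spec():
    """Tremor-free default-geometry spiral spec."""
    return SpiralSpec(seed=1)


@pytest.fixture(scope="session")
def clean_image_and_mask(clean_spec):
    return render_spiral(clean_spec, return_mask=True)


@pytest.fixture(scope="session")
def clean_image(clean_image_and_mask):
    return clean_image_and_mask[0]


@pytest.fixture(scope="session")
def clean_mask(clean_image):
    return binarize_spiral(clean_image)


@pytest.fixture(scope="session")
def clean_skeleton(clean_mask):
    return thin(clean_mask)


@pytest.fixture(scope="session")
def clean_trace(clean_image):
    return spiral_trace(clean_image)


@pytest.fixture(scope="session")
def tremor_image():
    """Factory for spirals with injected radial tremor."""

    def make(amplitude, frequency, seed=0, **kw):
        spec = SpiralSpec(tremor_amplitude=amplitude,
                          tremor_frequency=frequency, seed=seed,
                          intensity_jitter=kw.pop("intensity_jitter", 6.0),
                          **kw)
        return render_spiral(spec), spec

    return make


@pytest.fixture(scope="session")
def small_cohort():
    """Small labeled synthetic cohort shared by dataset/classifier tests."""
    from spiraltremor import make_labeled_set

    return make_labeled_set(8, 8, seed=42)
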