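import numpy as np
import pytest

from camricap import ImageSample, LeafDataset, SyntheticSpec, generate_samples


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_spec():
    """A compact synthetic family (64 px, 3 classes) for fast tests."""
    return SyntheticSpec(image_size=64, lesion_sigma=6.0, num_classes=3, seed=7)


@pytest.fixture
def small_batch(small_spec):
    """Eight 64-px leaf samples covering all three classes."""
    rng = np.random.default_rng(42)
    from camricap import generate_leaf_image

    return [generate_leaf_image(i % 3, small_spec, rng) for i in range(8)]


@pytest.fixture
def full_spec():
    """The default 224-px family used by the pipeline-scale checks."""
    return SyntheticSpec(num_classes=3, seed=0)


def make_sample(image_dims=(64, 64), label=0, center=(32, 32), color=1.0):
    """A flat grey image with known lesion metadata (no generator involved)."""
    H, W = image_dims
    return ImageSample(
        image=np.full((H, W, 3), float(color) * 0.5),
        label=label,
        lesion_center=center,
    )
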