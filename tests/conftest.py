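import numpy as np
import pytest

from contrast_gate.io_manifest import SliceSample
from contrast_gate.synthetic_data import PhantomConfig, generate_synthetic_dataset


def make_sample(
    rng: np.random.Generator,
    side: int = 32,
    patient_id: str = "p0",
    slice_index: int = 0,
    lesion_mean: float = 30.0,
    background_mean: float = 40.0,
    sd: float = 3.0,
) -> SliceSample:
    """Small random slice with a square lesion in the left hemisphere."""
    image = np.zeros((side, side))
    brain = np.zeros((side, side), dtype=np.uint8)
    brain[2 : side - 2, 2 : side - 2] = 1
    lesion = np.zeros((side, side), dtype=np.uint8)
    q = side // 4
    lesion[q : q + side // 4, q : q + side // 4] = 1
    image[brain > 0] = background_mean + sd * rng.standard_normal(int(brain.sum()))
    image[lesion > 0] = lesion_mean + sd * rng.standard_normal(int(lesion.sum()))
    return SliceSample(
        image=image,
        brain_mask=brain,
        lesion_mask=lesion,
        patient_id=patient_id,
        slice_index=slice_index,
        spacing=(1.0, 1.0),
    )


def random_mask(rng: np.random.Generator, shape=(32, 32), p: float = 0.05) -> np.ndarray:
    return (rng.random(shape) < p).astype(np.uint8)


@pytest.fixture(scope="session")
def small_phantom_config() -> PhantomConfig:
    return PhantomConfig(side=96, lesion_radius_range=(6, 10), seed=0)


@pytest.fixture(scope="session")
def small_dataset(small_phantom_config):
    """100 skewed-contrast phantom slices shared by read-only tests."""
    samples, truth = generate_synthetic_dataset(
        small_phantom_config, n_slices=100, n_patients=10, seed=7
    )
    return samples, truth
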