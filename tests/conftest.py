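from datetime import datetime

import numpy as np
import pytest

from fetpet import ImageVolume, InjectionRecord, Mask, PhantomSpec, make_pet_phantom


@pytest.fixture
def injection():
    """180 MBq / 72 kg: dose per weight exactly 2.5 kBq/g."""
    return InjectionRecord(
        injected_activity_MBq=180.0,
        body_weight_kg=72.0,
        injection_time=datetime(2020, 1, 1, 10, 0),
        acquisition_time=datetime(2020, 1, 1, 10, 12),
    )


@pytest.fixture
def hotspot_phantom(injection):
    """Noise-free isotropic hotspot (amp 10, background 1) on a 24^3 grid."""
    spec = PhantomSpec(
        grid_shape=(24, 24, 24),
        voxel_spacing_mm=(2.0, 2.0, 2.0),
        background_uptake=1.0,
        hotspots=[((12, 12, 12), (6.0, 6.0, 6.0), 10.0)],
        noise_sd=0.0,
        seed=0,
    )
    return make_pet_phantom(spec, injection)


@pytest.fixture
def whole_grid_roi():
    return Mask(np.ones((24, 24, 24), bool), (2.0, 2.0, 2.0), "roi")


def random_mask(rng: np.random.Generator, shape, p: float = 0.3, role: str = "roi") -> Mask:
    return Mask(rng.random(shape) < p, (1.0, 1.0, 1.0), role)


def brute_force_jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Independent voxel-count Jaccard: loops-free but separate from the
    implementation's union/intersection bookkeeping."""
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return float(inter) / float(union) if union else 1.0
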