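import numpy as np
import pytest

from npwmf import (
    DiskFeature,
    NoiseSpec,
    PhantomSpec,
    layout_from_spec,
    place_rois,
    simulate_ensemble,
)


@pytest.fixture(scope="session")
def small_scene():
    """A 30 mm field with one faint 2 mm disk, cheap enough for many sims."""
    spec = PhantomSpec(
        grid_shape=(64, 64),
        pixel_size=0.469,
        background_level=0.0,
        features=(DiskFeature(center_mm=(15.0, 7.0), diameter_mm=2.0, contrast_hu=4.0),),
        psf_sigma=0.6,
    )
    noise = NoiseSpec(model="white", target_std=5.0)
    return spec, noise


@pytest.fixture(scope="session")
def small_ensemble(small_scene):
    spec, noise = small_scene
    return simulate_ensemble(spec, noise, n_repeats=8, m_slices=3, seed=42)


@pytest.fixture(scope="session")
def small_geometry(small_scene):
    spec, _ = small_scene
    return place_rois(
        layout_from_spec(spec), spec.pixel_size, spec.grid_shape,
        n_exp=4, n_ann=4, n_gap=4,
    )[0]


@pytest.fixture
def rng():
    return np.random.default_rng(7)
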