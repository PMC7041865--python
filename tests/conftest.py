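import numpy as np
import pytest

import histoquant as hq
from histoquant.scene import default_viability_params


@pytest.fixture(scope="session")
def small_scene():
    """A 256-px section with 60 nuclei, no touching — fast and easy to segment."""
    params = hq.SceneParams(
        image_height_px=256,
        image_width_px=256,
        n_nuclei=60,
        touching_fraction=0.0,
        rng_seed=7,
    )
    img, truth = hq.generate_tissue_scene(params)
    return params, img, truth


@pytest.fixture(scope="session")
def small_scene_segmented(small_scene):
    _, img, truth = small_scene
    nuclei, cells = hq.segment(img)
    return img, truth, nuclei, cells


@pytest.fixture(scope="session")
def control_scene():
    """Secondary-only control: same optics, no positive cells."""
    params = default_viability_params(
        n_nuclei=60,
        size_px=256,
        positive_fractions={"Ki67": 0.0, "CC-3": 0.0, "Beclin1": 0.0},
        rng_seed=977,
    )
    img, truth = hq.generate_tissue_scene(params)
    return img, truth


@pytest.fixture(scope="session")
def uptake_scene():
    params = hq.SceneParams(
        image_height_px=128, image_width_px=128, n_nuclei=0, rng_seed=11
    )
    img, truth = hq.generate_uptake_scene(
        params, viable_mean=100.0, necrotic_mean=300.0, necrotic_area_fraction=0.3,
        noise_sd=10.0,
    )
    return img, truth
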