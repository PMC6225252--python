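import dataclasses

import numpy as np
import pandas as pd
import pytest

from chrysaspec.hypercube import WavelengthAxis, calibrate_reflectance
from chrysaspec.synthetic import (
    SceneConfig,
    default_classes,
    render_scene,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def axis():
    return WavelengthAxis.linear()


@pytest.fixture(scope="session")
def tiny_config():
    """Small scene: 2 medium flowers, quick to render."""
    return SceneConfig(image_width_px=96, image_length_px=96,
                       n_flowers_per_sample=2, n_samples_per_class=2,
                       noise_sd=0.005, seed=7)


def make_scene(config, noise_sd=None, seed=0, class_spec=None,
               poly=3.76, flav=9.11):
    """Render one scene with fixed per-flower contents (no jitter)."""
    if noise_sd is not None:
        config = dataclasses.replace(config, noise_sd=noise_sd)
    if class_spec is None:
        class_spec = default_classes()[1]
    contents = pd.DataFrame({
        "poly_pct": [poly] * config.n_flowers_per_sample,
        "flav_pct": [flav] * config.n_flowers_per_sample,
    })
    rng = np.random.default_rng(seed)
    return render_scene(config, class_spec, contents, rng)


@pytest.fixture()
def noisefree_scene(tiny_config):
    return make_scene(tiny_config, noise_sd=0.0)


@pytest.fixture()
def noisefree_cube(noisefree_scene):
    s = noisefree_scene
    return calibrate_reflectance(s.raw, s.dark, s.white, axis=s.axis)


@pytest.fixture(scope="session")
def small_dataset():
    """15 samples/class, used by identifiability-style checks."""
    cfg = SceneConfig(image_width_px=120, image_length_px=120,
                      n_flowers_per_sample=3, n_samples_per_class=15,
                      seed=11)
    return simulate_dataset(cfg)
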