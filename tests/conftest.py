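import numpy as np
import pytest

import greencube as gc


@pytest.fixture(scope="session")
def clean_scene():
    """Small noise-free, cloud-free scene: exact recovery territory."""
    truth = gc.default_scene(seed=1, shape=(48, 48), patch_scale=16,
                             noise_sd=0.0, cloud_prob=0.0)
    series = gc.render_reflectance(truth)
    return truth, series


@pytest.fixture(scope="session")
def noisy_scene():
    """The default study scene: 128x128, noise sd 0.01, 30% patchy clouds."""
    truth = gc.default_scene(seed=2)
    series = gc.render_reflectance(truth)
    return truth, series


@pytest.fixture(scope="session")
def noisy_result(noisy_scene):
    truth, series = noisy_scene
    return truth, gc.run_pipeline(series)


@pytest.fixture(scope="session")
def clean_result(clean_scene):
    truth, series = clean_scene
    return truth, gc.run_pipeline(series)
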