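import numpy as np
import pytest

import gliamorph as gm
from gliamorph.pipeline import PipelineConfig, preprocess_iba1

# settings that switch off every stochastic / blurring term so painted
# values survive rendering exactly
NOISELESS = dict(
    background_level=0.0,
    background_gradient_amplitude=0.0,
    gaussian_noise_sd=0.0,
    poisson_scaling=0.0,
    psf_sigma_um=0.0,
)


@pytest.fixture(scope="session")
def noiseless_scene():
    spec = gm.SceneSpec(
        seed=3,
        n_cells_per_class={"ramified": 4, "hypertrophic": 4, "ameboid": 4},
        **NOISELESS,
    )
    stack, truth = gm.render_scene(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def noisy_scene():
    spec = gm.SceneSpec(
        seed=5, n_cells_per_class={"ramified": 7, "hypertrophic": 7, "ameboid": 6}
    )
    stack, truth = gm.render_scene(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def default_threshold():
    """Segmentation cut-off derived once from a cell-free control scene."""
    ctrl_spec = gm.SceneSpec(seed=99, n_cells_per_class={})
    ctrl_stack, _ = gm.render_scene(ctrl_spec)
    ctrl = preprocess_iba1(
        gm.max_project(ctrl_stack)["iba1"], PipelineConfig(threshold_gray=1)
    )
    return float(gm.suggest_threshold(ctrl, 0.999))


@pytest.fixture(scope="session")
def default_config(default_threshold):
    return PipelineConfig(threshold_gray=default_threshold)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
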