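import numpy as np
import pytest

from graftkit import (
    FitConfig,
    GraftSceneSpec,
    GrowthSimSpec,
    NoiseModel,
    RetentionSimSpec,
    simulate_graft_scene,
    simulate_growth,
    simulate_retention,
)


@pytest.fixture
def noiseless_retention():
    """Observation table exactly on the retention curve at beta = 0.24."""
    spec = RetentionSimSpec(
        beta_true=0.24, noise=NoiseModel("gaussian_additive", 0.0), seed=1
    )
    return spec, simulate_retention(spec)


@pytest.fixture
def noiseless_growth():
    """Observation table exactly on the growth curve (Gmax=2, gamma=3)."""
    spec = GrowthSimSpec(
        g_max_true=2.0,
        gamma_true=3.0,
        noise=NoiseModel("lognormal_multiplicative", 0.0),
        seed=1,
    )
    return spec, simulate_growth(spec)


@pytest.fixture
def quick_cfg():
    """Fit config with a small bootstrap for fast unit tests."""
    return FitConfig(n_boot=50, seed=7)


@pytest.fixture
def graft_scene():
    spec = GraftSceneSpec(seed=11)
    tracks, rois, site = simulate_graft_scene(spec)
    return spec, tracks, rois, site
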