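import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from placodekit import (SceneConfig, generate_scene, render_channels,
                        scene_cell_table)

settings.register_profile(
    "default", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def clustered_scene():
    """Default clustered-constriction scene with rendered channels."""
    cfg = SceneConfig(n_cells=150, field_mode="clustered", seed=11)
    return render_channels(generate_scene(cfg))


@pytest.fixture(scope="session")
def random_scene():
    cfg = SceneConfig(n_cells=150, field_mode="random", seed=11)
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free scene for oracle comparisons."""
    cfg = SceneConfig(n_cells=100, field_mode="clustered", seed=21,
                      noise_model="none")
    return render_channels(generate_scene(cfg))


@pytest.fixture(scope="session")
def smooth_scene():
    """Placode with a smooth circular rim amid a surrounding cell layer."""
    cfg = SceneConfig(n_cells=80, surround_layers=2, smooth_boundary=True,
                      seed=31, noise_model="none")
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def clustered_table(clustered_scene):
    return scene_cell_table(clustered_scene)


def toy_grid_junction(n=2, cell_px=20, ridge_px=2, amplitude=100.0):
    """An n x n grid of square cells drawn as junction ridges."""
    size = n * cell_px + ridge_px
    img = np.zeros((size, size))
    for k in range(n + 1):
        lo = k * cell_px
        img[lo:lo + ridge_px, :] = amplitude
        img[:, lo:lo + ridge_px] = amplitude
    mask = np.zeros_like(img, dtype=bool)
    mask[:] = True
    return img, mask
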