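"""Shared fixtures: small synthetic scenes reused across test modules.

The "tiny" geometry (24x32 grid of 5x5 px modules over 120x160 frames,
45 s at 2 fps) keeps per-test rendering cheap while exercising exactly the
same code paths as the full 72x96 / 360x480 geometry.
"""

import numpy as np
import pytest

from icgfa.config import FeatureConfig, SamplingConfig, SceneConfig
from icgfa.containers import FeatureGrid
from icgfa.extraction import build_grid_series
from icgfa.features import featurize_grid, normalize_features
from icgfa.stabilization import stabilize_sequence
from icgfa.synthetic import render_scene


def tiny_scene_config(**overrides) -> SceneConfig:
    defaults = dict(frame_height=120, frame_width=160, grid_rows=24,
                    grid_cols=32, fps=2.0, duration=45.0, boundary_pos=0.55,
                    band_row_range=(6, 18), noise_sd=2.0,
                    motion_amplitude=1.5, seed=123)
    defaults.update(overrides)
    return SceneConfig(**defaults)


def tiny_sampling(**overrides) -> SamplingConfig:
    defaults = dict(max_offset=2)
    defaults.update(overrides)
    return SamplingConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_config():
    return tiny_scene_config()


@pytest.fixture(scope="session")
def noiseless_config():
    return tiny_scene_config(noise_sd=0.0, motion_amplitude=0.0, seed=321)


@pytest.fixture(scope="session")
def tiny_scene(tiny_config):
    return render_scene(tiny_config)


@pytest.fixture(scope="session")
def noiseless_scene(noiseless_config):
    return render_scene(noiseless_config)


@pytest.fixture(scope="session")
def noiseless_feature_grid(noiseless_scene):
    seq, annotation = noiseless_scene
    grid = build_grid_series(seq, (24, 32))
    return featurize_grid(grid), annotation


@pytest.fixture(scope="session")
def normalized_feature_grid(noiseless_feature_grid):
    fg, annotation = noiseless_feature_grid
    nfg, scaling = normalize_features(fg)
    return nfg, scaling, annotation


@pytest.fixture(scope="session")
def stabilized_tiny(tiny_scene):
    seq, annotation = tiny_scene
    stab, log = stabilize_sequence(seq, warp_white=False)
    return stab, log, annotation


def constant_feature_grid(rows=24, cols=32, values=(0.5, 0.5, 0.5, 0.5),
                          window=30.0) -> FeatureGrid:
    feats = np.tile(np.asarray(values, dtype=float), (rows, cols, 1))
    return FeatureGrid(features=feats, valid=np.ones((rows, cols), bool),
                       degenerate=np.zeros((rows, cols), bool),
                       onset_time=10.0, window=window, normalized=True)


def gradient_feature_grid(rows=72, cols=96, window=30.0) -> FeatureGrid:
    """Analytic feature grid with a perfusion-like left-to-right gradient
    (no video rendering involved)."""
    x = np.linspace(1.0, 0.0, cols)
    feats = np.empty((rows, cols, 4))
    feats[..., 0] = x[None, :]
    feats[..., 1] = 0.8 * x[None, :]
    feats[..., 2] = 1.0 - 0.7 * x[None, :]
    feats[..., 3] = 0.9 - 0.6 * x[None, :]
    return FeatureGrid(features=feats, valid=np.ones((rows, cols), bool),
                       degenerate=np.zeros((rows, cols), bool),
                       onset_time=12.0, window=window, normalized=True)
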