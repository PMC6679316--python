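"""Shared fixtures: all inputs are generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

import grainspec as gs
from grainspec.grid import WavelengthGrid
from grainspec.table import SpectraTable


@pytest.fixture(scope="session")
def default_grid() -> WavelengthGrid:
    return gs.make_wavelength_grid()


@pytest.fixture(scope="session")
def table_400() -> SpectraTable:
    """Default-condition table at the study scale: 4 classes x 100 kernels."""
    return gs.simulate_spectra_table(gs.SceneConfig(rng_seed=0, grains_per_class=100))


@pytest.fixture(scope="session")
def scene_default():
    """Default 4 x 25-grain scene (fixed seed), shared by image-chain tests."""
    cube, refs, truth = gs.simulate_scene(gs.SceneConfig(rng_seed=0))
    return cube, refs, truth


@pytest.fixture(scope="session")
def reflectance_trimmed(scene_default):
    cube, refs, truth = scene_default
    reflectance = gs.reflectance_correct(cube, refs)
    return gs.trim_bands(reflectance, 931.8, 1653.8), truth


@pytest.fixture(scope="session")
def small_scene_noiseless():
    """Tiny float64 scene with no pixel or frame noise, for exactness checks."""
    cfg = gs.SceneConfig(
        rng_seed=0, grains_per_class=2, height=120, width=120,
        noise_sd=0.0, frame_noise_sd=0.0, dn_dtype="float64",
    )
    cube, refs, truth = gs.simulate_scene(cfg)
    return cfg, cube, refs, truth


def make_table(x: np.ndarray, labels=None) -> SpectraTable:
    """Wrap a plain matrix in a SpectraTable with a synthetic band axis."""
    x = np.asarray(x, dtype=float)
    grid = WavelengthGrid(900.0 + 10.0 * np.arange(x.shape[1]))
    return SpectraTable(x, grid, ids=np.arange(1, x.shape[0] + 1),
                        labels=labels)
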