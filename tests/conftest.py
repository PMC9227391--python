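"""Shared fixtures: tiny synthetic libraries and one trained toy model.

Everything is generated programmatically at test time; the toy training
run is session-scoped so the (fast) fit happens once.
"""

from __future__ import annotations

import numpy as np
import pytest

from pscnn.augment import AugmentationConfig, build_dataset, split_dataset
from pscnn.model import ModelConfig, PSCNN
from pscnn.simulate import lorentzian_line
from pscnn.spectra import SpectralLibrary, Spectrum, default_grid, normalize_max

TOY_GRID_POINTS = 256


@pytest.fixture(scope="session")
def toy_grid() -> np.ndarray:
    return default_grid(TOY_GRID_POINTS, low=0.0, high=10.0)


@pytest.fixture(scope="session")
def toy_library(toy_grid) -> SpectralLibrary:
    """Eight single-multiplet compounds with well-separated peaks."""
    centers = [1.0, 2.1, 3.2, 4.3, 5.4, 6.5, 7.6, 8.7]
    entries = []
    for i, c in enumerate(centers):
        inten = lorentzian_line(c, 0.06, 1.0, toy_grid)
        inten += lorentzian_line(c + 0.5, 0.06, 0.6, toy_grid)
        entries.append(
            normalize_max(Spectrum(toy_grid.copy(), inten, name=f"toy-{i}"))
        )
    return SpectralLibrary(entries=entries)


@pytest.fixture(scope="session")
def toy_aug_config() -> AugmentationConfig:
    return AugmentationConfig(
        n_pairs=700,
        components_range=(2, 3),
        split_sizes=(600, 50, 50),
        seed=11,
    )


@pytest.fixture(scope="session")
def toy_dataset(toy_library, toy_aug_config):
    return split_dataset(build_dataset(toy_library, toy_aug_config))


@pytest.fixture(scope="session")
def toy_model_config() -> ModelConfig:
    # a short, hot training schedule: plenty for the separable toy problem
    return ModelConfig(epochs=60, learning_rate=1e-3, seed=5)


@pytest.fixture(scope="session")
def toy_trained_model(toy_dataset, toy_model_config) -> PSCNN:
    model = PSCNN(toy_model_config, input_length=TOY_GRID_POINTS)
    model.fit(toy_dataset.arrays("train"), toy_dataset.arrays("val"))
    return model
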