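"""Shared fixtures: synthetic datasets and (expensive) trained modules.

The desk-scale training fixtures are session-scoped so the training-descent
unit tests and the end-to-end accuracy checks share one training run.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from histosynth.clustering import assign_guide, fit_pixel_clusters
from histosynth.segmodule import SegModuleConfig, train_seg_module
from histosynth.synthetic import PatchSpec, generate_patches


@pytest.fixture(scope="session")
def noiseless_spec():
    """Default 64x64 patch spec with noise disabled (exact palette colours)."""
    return PatchSpec(noise_sigma=0.0)


@pytest.fixture(scope="session")
def desk_dataset(noiseless_spec):
    """200 noiseless 64x64 patches with ground-truth component maps."""
    patches, cmaps = generate_patches(200, noiseless_spec, seed=100)
    return patches, cmaps


@pytest.fixture(scope="session")
def desk_guide(desk_dataset):
    patches, _ = desk_dataset
    return fit_pixel_clusters(patches, k=4, seed=1)


@pytest.fixture(scope="session")
def desk_guides(desk_dataset, desk_guide):
    patches, _ = desk_dataset
    return [assign_guide(p, desk_guide) for p in patches]


@pytest.fixture(scope="session")
def desk_seg_config():
    return SegModuleConfig(input_size=64, stem_channels=16)


@pytest.fixture(scope="session")
def desk_trained_seg(desk_dataset, desk_guides, desk_seg_config):
    """Seg module trained for 5 epochs on the 200-patch desk set."""
    patches, _ = desk_dataset
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        module, history = train_seg_module(
            patches, desk_guides, desk_seg_config,
            epochs=5, batch_size=8, seed=42)
    return module, history


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
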