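"""Shared fixtures: synthetic datasets at the canonical study conditions.

Session-scoped fixtures cache the expensive objects (default 4-participant
dataset and its two-level factor model) so the whole suite reuses them.
"""

from __future__ import annotations

import numpy as np
import pytest

import neurofactor as nf
from neurofactor.decoding import select_common_factors


@pytest.fixture(scope="session")
def wordset():
    return nf.builtin_wordset()


@pytest.fixture(scope="session")
def default_data(wordset):
    """Canonical conditions: 4 participants, 4 factors x 4 clusters, noise 0.3."""
    cfg = nf.SyntheticConfig(seed=1)
    dataset, truth = nf.generate_dataset(cfg, wordset)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def two_level_model(default_data):
    _, dataset, _ = default_data
    return nf.run_two_level(dataset)


@pytest.fixture(scope="session")
def common_factors(two_level_model):
    return select_common_factors(two_level_model, 4)


@pytest.fixture(scope="session")
def noise_free_data(wordset):
    """Exactly separable single-participant dataset (zero noise, unit gain)."""
    cfg = nf.SyntheticConfig(
        n_participants=1, noise_sd=0.0, participant_gain_sd=0.0, seed=2
    )
    dataset, truth = nf.generate_dataset(cfg, wordset)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def null_data(wordset):
    """Signal-free single-participant dataset (noise only)."""
    cfg = nf.SyntheticConfig(n_participants=1, signal_scale=0.0, seed=3)
    dataset, truth = nf.generate_dataset(cfg, wordset)
    return cfg, dataset, truth


def make_toy_dataset(values, voxel_size=(1.0, 1.0, 1.0), coords=None, words=None):
    """A minimal hand-built ActivationDataset for unit arithmetic tests.

    ``values`` is (participants, presentations, words, voxels); all voxels
    are labelled 'frontal' and laid out along the x axis unless coords given.
    """
    values = np.asarray(values, dtype=float)
    n_vox = values.shape[3]
    if coords is None:
        coords = np.column_stack(
            [np.arange(n_vox), np.zeros(n_vox, int), np.zeros(n_vox, int)]
        )
    if words is None:
        words = tuple(f"w{i}" for i in range(values.shape[2]))
    return nf.ActivationDataset(
        values=values,
        voxel_coords=coords,
        voxel_size_mm=voxel_size,
        grid_origin_mm=(0.0, 0.0, 0.0),
        region_labels=np.array(["frontal"] * n_vox, dtype=object),
        words=words,
        grid_dims=tuple(int(d) for d in np.max(coords, axis=0) + 1),
    )
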