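"""Shared fixtures: random binary volumes, blob volumes, a small cohort."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage


def random_sparse_volume(rng: np.random.Generator, shape, density: float = 0.15) -> np.ndarray:
    """Sparse random foreground; exercises classification on messy inputs."""
    return rng.random(shape) < density


def random_blob_volume(rng: np.random.Generator, shape, n_seeds: int = 4) -> np.ndarray:
    """A few dilated random seed clusters: blobby, multi-component foreground."""
    vol = np.zeros(shape, dtype=bool)
    idx = np.array([rng.integers(2, s - 2, n_seeds) for s in shape]).T
    vol[tuple(idx.T)] = True
    vol = ndimage.binary_dilation(vol, iterations=int(rng.integers(1, 4)))
    # sprinkle extra voxels so shapes are irregular
    vol |= rng.random(shape) < 0.02
    return vol


@pytest.fixture(scope="session")
def small_cohort():
    from uterovasc.synth_cohort import CohortConfig, generate_cohort

    return generate_cohort(CohortConfig(seed=7, n_subjects=60))
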