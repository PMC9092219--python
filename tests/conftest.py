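from dataclasses import replace

import numpy as np
import pytest

from la_recon.synthetic import DESK_PROFILE, generate_la, sample_point_cloud


@pytest.fixture(scope="session")
def desk_la():
    """One coarse synthetic LA geometry shared across tests."""
    return generate_la(replace(DESK_PROFILE, seed=3))


@pytest.fixture(scope="session")
def desk_cloud(desk_la):
    return sample_point_cloud(desk_la, replace(DESK_PROFILE, seed=3))


@pytest.fixture(scope="session")
def desk_cloud_clean(desk_la):
    """Noise-free full-coverage cloud on the same geometry."""
    cfg = replace(DESK_PROFILE, seed=3, noise_sd_mm=0.0, coverage_fraction=1.0, n_points=1500)
    return sample_point_cloud(desk_la, cfg)


def sphere_mask(shape, center, radius):
    """Voxelized ball: centers within `radius` voxels of `center`."""
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij", sparse=True)
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2


@pytest.fixture(scope="session")
def small_mask_pairs():
    """100 seeded random smooth-ish mask pairs (<= 20^3) for metric oracles."""
    rng = np.random.default_rng(2024)
    pairs = []
    while len(pairs) < 100:
        shape = tuple(rng.integers(8, 21, size=3))
        a = sphere_mask(shape, rng.uniform(2, np.array(shape) - 2), rng.uniform(2, 5))
        b = sphere_mask(shape, rng.uniform(2, np.array(shape) - 2), rng.uniform(2, 5))
        # random voxel noise so surfaces are irregular
        a |= rng.random(shape) < 0.02
        b |= rng.random(shape) < 0.02
        if a.any() and b.any():
            pairs.append((a, b))
    return pairs
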