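import numpy as np
import pytest

from centrex import centrality, glm
from centrex.grids import centered_affine


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_mask():
    """4x4x4 all-true mask."""
    return np.ones((4, 4, 4), dtype=bool)


def random_centrality_maps(rng, n_subjects, shape=(4, 4, 4), loc=0.0):
    """Stack of z-like maps sharing a full mask (helper, not a fixture)."""
    mask = np.ones(shape, dtype=bool)
    maps = []
    for i in range(n_subjects):
        vals = rng.normal(loc, 1.0, size=shape)
        maps.append(
            centrality.CentralityMap(
                subject_id=f"sub-{i:03d}", values=vals, mask=mask,
                transform_applied="z_standardized",
            )
        )
    return maps


def make_tmap(t_values, dof=30, voxel_size=2.0, direction="greater"):
    t_values = np.asarray(t_values, dtype=float)
    return glm.ContrastMap(
        t_values=t_values,
        dof=dof,
        direction=direction,
        affine=centered_affine(t_values.shape, voxel_size),
    )
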