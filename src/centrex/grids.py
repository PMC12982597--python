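"""Voxel-grid geometry shared across the pipeline.

All volumes live on a regular grid with an affine mapping voxel indices to
millimetre coordinates (RAS-like: negative first coordinate = left hemisphere).
The default affine centres the grid on the origin so both hemispheres exist.
"""

from __future__ import annotations

import numpy as np


def centered_affine(shape: tuple[int, int, int], voxel_size_mm: float = 2.0) -> np.ndarray:
    """Affine whose origin sits at the geometric centre of the grid.

    Voxel index ``i`` along an axis of length ``n`` maps to
    ``(i - (n - 1) / 2) * voxel_size_mm`` mm.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s <= 0 for s in shape):
        raise ValueError(f"shape must be a positive integer triple, got {shape}")
    if voxel_size_mm <= 0:
        raise ValueError("voxel_size_mm must be positive")
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    aff[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * voxel_size_mm
    return aff


def voxel_centers_mm(shape: tuple[int, int, int], affine: np.ndarray) -> np.ndarray:
    """(V, 3) mm coordinates of every voxel centre, C-order raveled."""
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    return idx @ affine[:3, :3].T + affine[:3, 3]


def mm_to_voxel(coords_mm: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Continuous voxel indices for mm coordinates (inverse affine)."""
    coords_mm = np.atleast_2d(np.asarray(coords_mm, dtype=float))
    inv = np.linalg.inv(affine)
    return coords_mm @ inv[:3, :3].T + inv[:3, 3]


def nearest_voxel(coords_mm: np.ndarray, affine: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Nearest in-grid voxel index triple per coordinate (clipped to the grid)."""
    vox = np.rint(mm_to_voxel(coords_mm, affine)).astype(int)
    return np.clip(vox, 0, np.asarray(shape) - 1)


def grid_bounds_mm(shape: tuple[int, int, int], affine: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(low, high) mm bounds spanned by voxel centres."""
    corners = np.array([[0, 0, 0], [s - 1 for s in shape]], dtype=float)
    mm = corners @ affine[:3, :3].T + affine[:3, 3]
    return mm.min(axis=0), mm.max(axis=0)
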