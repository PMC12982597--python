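"""Voxel-wise binary degree centrality from resting-state time series.

Degree centrality counts, for each gray-matter (GM) voxel, how many other GM
voxels have a time-series Pearson correlation strictly above a threshold
(default 0.25; only positive correlations count). Maps are computed per
subject within a GM mask obtained by thresholding a GM probability volume at
0.20 (inclusive), then standardized within subject before group modelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortDataset",
    "CentralityMap",
    "make_gm_mask",
    "degree_centrality",
    "transform_centrality",
]

REQUIRED_COVARIATES = ("subject_id", "group", "age", "sex", "scanner")


@dataclass
class CohortDataset:
    """Per-subject 4-D time series on a shared grid, plus covariates.

    ``subjects`` is a list of ``(subject_id, volume)`` where ``volume`` has
    shape ``grid_shape + (n_timepoints,)``. ``gm_probability`` is a 3-D volume
    in [0, 1] on the same grid. ``covariates`` must contain one row per
    subject with at least group, age, sex and scanner columns.
    """

    subjects: list[tuple[str, np.ndarray]]
    gm_probability: np.ndarray
    covariates: pd.DataFrame
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ValueError("cohort has no subjects")
        shape = self.subjects[0][1].shape
        if len(shape) != 4 or shape[3] < 3:
            raise ValueError("subject volumes must be 4-D with >=3 timepoints")
        for sid, vol in self.subjects:
            if vol.shape != shape:
                raise ValueError(f"subject {sid} volume shape {vol.shape} != {shape}")
        if self.gm_probability.shape != shape[:3]:
            raise ValueError("gm_probability grid does not match subject volumes")
        missing = [c for c in REQUIRED_COVARIATES if c not in self.covariates.columns]
        if missing:
            raise ValueError(f"covariate table missing columns: {missing}")
        ids = [sid for sid, _ in self.subjects]
        tab = set(self.covariates["subject_id"])
        if set(ids) != tab or self.covariates["subject_id"].duplicated().any():
            raise ValueError("covariate table must list each subject exactly once")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.subjects[0][1].shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.subjects[0][1].shape[3]


@dataclass
class CentralityMap:
    """One subject's degree map; values are NaN outside the mask."""

    subject_id: str
    values: np.ndarray
    mask: np.ndarray
    transform_applied: str = "none"  # none | z_standardized | fisher_like

    def masked_values(self) -> np.ndarray:
        return self.values[self.mask]


def make_gm_mask(gm_probability: np.ndarray, threshold: float = 0.20) -> np.ndarray:
    """Binary GM mask: voxel included iff probability >= threshold (inclusive)."""
    gm = np.asarray(gm_probability, dtype=float)
    if gm.min() < 0 or gm.max() > 1:
        raise ValueError("GM probability values must lie in [0, 1]")
    mask = gm >= threshold
    if not mask.any():
        raise ValueError(f"GM mask is empty at threshold {threshold}")
    return mask


def degree_centrality(
    timeseries: np.ndarray,
    mask: np.ndarray,
    r_threshold: float = 0.25,
    subject_id: str = "",
) -> CentralityMap:
    """Binary degree: count of other masked voxels with Pearson r strictly > threshold.

    Self-connections are excluded. Zero-variance voxels are removed from the
    mask with a warning (correlation is undefined for them); if every masked
    voxel is constant an error is raised.
    """
    ts = np.asarray(timeseries, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if ts.ndim != 4 or ts.shape[:3] != mask.shape:
        raise ValueError("timeseries must be 4-D on the mask's grid")
    if mask.sum() < 2:
        raise ValueError("need at least 2 masked voxels")

    data = ts[mask]  # (V, T)
    centered = data - data.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    good = norms > 0
    if not good.any() or good.sum() < 2:
        raise ValueError("all masked time series are constant; correlation undefined")
    if not good.all():
        warnings.warn(
            f"dropping {int((~good).sum())} zero-variance voxel(s) from the mask",
            stacklevel=2,
        )
        mask = mask.copy()
        mask[tuple(np.argwhere(mask)[~good].T)] = False
        centered, norms = centered[good], norms[good]

    z = centered / norms[:, None]
    r = z @ z.T
    degree = (r > r_threshold).sum(axis=1)
    # the diagonal (r = 1) counts itself whenever the threshold is < 1
    if r_threshold < 1.0:
        degree = degree - 1

    values = np.full(mask.shape, np.nan)
    values[mask] = degree.astype(float)
    return CentralityMap(subject_id=subject_id, values=values, mask=mask, transform_applied="none")


def transform_centrality(cmap: CentralityMap, mode: str = "z_standardized") -> CentralityMap:
    """Standardize a degree map within its mask.

    ``z_standardized`` (default): subtract the within-mask mean and divide by
    the within-mask sample SD (ddof=1), removing per-subject scale so maps are
    comparable across subjects. ``fisher_like``: rescale degree to [0, 1) by
    V-1 and apply atanh (saturated degrees are clipped just below 1 to stay
    finite); kept for fidelity experiments with toolchains that apply a
    literal Fisher transform.
    """
    if cmap.transform_applied != "none":
        raise ValueError(f"map already transformed ({cmap.transform_applied})")
    vals = cmap.masked_values()
    out = np.full(cmap.values.shape, np.nan)
    if mode == "z_standardized":
        sd = vals.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError("degenerate map: within-mask SD is zero")
        out[cmap.mask] = (vals - vals.mean()) / sd
    elif mode == "fisher_like":
        v_max = cmap.mask.sum() - 1
        ratio = np.clip(vals / v_max, None, 1.0 - 1e-12)
        out[cmap.mask] = np.arctanh(ratio)
    else:
        raise ValueError(f"unknown transform mode {mode!r}")
    return replace(cmap, values=out, transform_applied=mode)


def transform_cohort(maps: Sequence[CentralityMap], mode: str = "z_standardized") -> list[CentralityMap]:
    return [transform_centrality(m, mode) for m in maps]
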