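"""Voxel-wise group GLM contrasts, cluster-extent thresholding and conjunctions.

Second-level modelling of standardized centrality maps: per voxel, ordinary
least squares of the map values on a design with group indicators and
age/sex/scanner covariates; one-sided t contrasts per direction; cluster
thresholding at an uncorrected voxel p with an extent rule (default p < 0.001,
k = 20; the lenient p < 0.01 map feeds the transcriptomic association);
minimum-statistic conjunction across two contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .centrality import CentralityMap

__all__ = [
    "DesignMatrix",
    "ContrastMap",
    "build_design",
    "fit_voxelwise_glm",
    "threshold_map",
    "conjunction",
]


@dataclass
class DesignMatrix:
    """Design rows aligned with a stack of subject maps.

    ``contrasts`` maps a label to a contrast vector over ``columns``.
    """

    X: np.ndarray
    columns: list[str]
    subject_ids: list[str]
    contrasts: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.subject_ids), len(self.columns)):
            raise ValueError("design shape does not match labels")

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.X))


@dataclass
class ContrastMap:
    """Voxel t-statistic map with dof and threshold metadata.

    ``t_values`` is NaN outside the analysis mask (and, once thresholded,
    outside surviving clusters). ``direction`` states which tail the contrast
    tests ("greater": positive t supports the effect).
    """

    t_values: np.ndarray
    dof: int
    contrast_label: str = ""
    direction: str = "greater"
    threshold_record: dict | None = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.t_values)


def build_design(
    covariates: pd.DataFrame,
    groups: Sequence[str] | None = None,
    covariate_cols: Sequence[str] = ("age", "sex", "scanner"),
    group_col: str = "group",
) -> DesignMatrix:
    """Intercept + treatment-coded group dummies + covariates (categoricals dummy-coded).

    Pairwise contrasts ``"<A>_gt_<B>"`` are registered for every ordered pair
    of group levels.
    """
    cov = covariates.reset_index(drop=True)
    for col in (group_col, *covariate_cols):
        if col not in cov.columns:
            raise ValueError(f"covariate table missing column {col!r}")
    levels = list(groups) if groups is not None else sorted(cov[group_col].unique())
    cov = cov[cov[group_col].isin(levels)].reset_index(drop=True)
    n = len(cov)
    cols: list[str] = ["intercept"]
    mats: list[np.ndarray] = [np.ones((n, 1))]
    for lev in levels[1:]:
        cols.append(f"{group_col}[{lev}]")
        mats.append((cov[group_col] == lev).to_numpy(float)[:, None])
    for c in covariate_cols:
        if pd.api.types.is_numeric_dtype(cov[c]):
            cols.append(c)
            mats.append(cov[c].to_numpy(float)[:, None])
        else:
            for lev in sorted(cov[c].unique())[1:]:
                cols.append(f"{c}[{lev}]")
                mats.append((cov[c] == lev).to_numpy(float)[:, None])
    X = np.hstack(mats)

    def group_vec(level: str) -> np.ndarray:
        v = np.zeros(len(cols))
        name = f"{group_col}[{level}]"
        if name in cols:
            v[cols.index(name)] = 1.0
        return v

    contrasts = {
        f"{a}_gt_{b}": group_vec(a) - group_vec(b)
        for a in levels
        for b in levels
        if a != b
    }
    return DesignMatrix(
        X=X, columns=cols, subject_ids=list(cov["subject_id"]), contrasts=contrasts
    )


def _collinear_columns(X: np.ndarray, columns: list[str]) -> list[str]:
    _, r = np.linalg.qr(X)
    bad = np.abs(np.diag(r)) < 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    return [c for c, b in zip(columns, bad) if b]


def fit_voxelwise_glm(
    maps: Sequence[CentralityMap],
    design: DesignMatrix,
    contrast: str | np.ndarray,
    affine: np.ndarray | None = None,
) -> ContrastMap:
    """Per-voxel OLS of map values on the design; t for the given contrast.

    dof = n - rank(design). Voxels with zero residual variance are flagged
    missing (NaN). Maps must share a mask and align row-for-row with the
    design's subject order.
    """
    if isinstance(contrast, str):
        label, c = contrast, design.contrasts[contrast]
    else:
        label, c = "custom", np.asarray(contrast, dtype=float)
    by_id = {m.subject_id: m for m in maps}
    if set(by_id) != set(design.subject_ids) or len(maps) != len(design.subject_ids):
        raise ValueError("maps do not align one-to-one with design subjects")
    ordered = [by_id[s] for s in design.subject_ids]
    mask = ordered[0].mask
    for m in ordered[1:]:
        if not np.array_equal(m.mask, mask):
            raise ValueError("all maps must share one mask")

    X = design.X
    n, p = X.shape
    rank = design.rank
    if rank < p:
        raise ValueError(
            f"rank-deficient design; collinear columns: {_collinear_columns(X, design.columns)}"
        )
    dof = n - rank
    if dof <= 0:
        raise ValueError("non-positive degrees of freedom")

    Y = np.stack([m.masked_values() for m in ordered])  # (n, V)
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    rss = (resid**2).sum(axis=0)
    sigma2 = rss / dof
    var_c = float(c @ np.linalg.inv(X.T @ X) @ c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (c @ beta) / np.sqrt(sigma2 * var_c)
    t[sigma2 <= 0] = np.nan

    vol = np.full(mask.shape, np.nan)
    vol[mask] = t
    return ContrastMap(
        t_values=vol,
        dof=dof,
        contrast_label=label,
        direction="greater",
        affine=affine if affine is not None else np.eye(4),
    )


# 18-connectivity: faces + edges (rank-3 structure of connectivity 2)
_CLUSTER_STRUCTURE = ndimage.generate_binary_structure(3, 2)


def label_clusters(supra: np.ndarray) -> tuple[np.ndarray, int]:
    """Connected components of a suprathreshold mask under 18-connectivity."""
    return ndimage.label(supra, structure=_CLUSTER_STRUCTURE)


def threshold_map(cm: ContrastMap, p_voxel: float, k: int = 1) -> ContrastMap:
    """Uncorrected voxel threshold + cluster-extent rule.

    A voxel survives when its one-sided p (t distribution, cm.dof) is < p_voxel
    and it belongs to an 18-connected component of at least k voxels.
    """
    if cm.threshold_record is not None:
        raise ValueError("map is already thresholded")
    if not (0.0 < p_voxel < 1.0):
        raise ValueError("p_voxel must lie in (0, 1)")
    if k < 1:
        raise ValueError("cluster extent k must be >= 1")
    t_crit = stats.t.isf(p_voxel, cm.dof)
    signed = cm.t_values if cm.direction == "greater" else -cm.t_values
    with np.errstate(invalid="ignore"):
        supra = signed > t_crit
    labels, n_lab = label_clusters(supra)
    out = np.full(cm.t_values.shape, np.nan)
    kept = 0
    for lab in range(1, n_lab + 1):
        comp = labels == lab
        if comp.sum() >= k:
            out[comp] = cm.t_values[comp]
            kept += 1
    record = {
        "p_voxel": p_voxel,
        "cluster_extent_k": k,
        "connectivity_rule": "18-connectivity",
        "t_critical": float(t_crit),
        "n_clusters": kept,
    }
    return replace(cm, t_values=out, threshold_record=record)


def conjunction(cm_a: ContrastMap, cm_b: ContrastMap) -> ContrastMap:
    """Minimum-statistic conjunction: t(v) = min(t_a(v), t_b(v)).

    Thresholding the output enforces both contrasts suprathreshold (the
    conjunction null). NaN in either input propagates.
    """
    if cm_a.t_values.shape != cm_b.t_values.shape:
        raise ValueError("contrast maps are on different grids")
    if cm_a.direction != cm_b.direction:
        raise ValueError("conjunction requires contrasts tested in the same direction")
    if not np.array_equal(cm_a.mask, cm_b.mask):
        raise ValueError("contrast maps have different masks")
    # the least-extreme statistic in the tested direction
    if cm_a.direction == "greater":
        t = np.minimum(cm_a.t_values, cm_b.t_values)
    else:
        t = np.maximum(cm_a.t_values, cm_b.t_values)
    return ContrastMap(
        t_values=t,
        dof=min(cm_a.dof, cm_b.dof),
        contrast_label=f"conj({cm_a.contrast_label},{cm_b.contrast_label})",
        direction=cm_a.direction,
        affine=cm_a.affine,
    )
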