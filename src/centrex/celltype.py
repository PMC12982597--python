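"""Cell-type expression profiling of associated genes.

A genes x (cell type, replicate) nonnegative expression matrix is
quantile-normalized across columns; per gene we report absolute expression
(mean and SEM per cell type, plus a +0.001 offset for log display),
specificity (share of the gene's summed cell-type means) and enrichment
(mean in the type over mean outside it).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "quantile_normalize",
    "celltype_profile",
    "specificity",
    "enrichment_score",
    "profile_genes",
]

LOG_OFFSET = 0.001


def _require_celltype_columns(matrix: pd.DataFrame) -> None:
    if not isinstance(matrix.columns, pd.MultiIndex) or matrix.columns.nlevels != 2:
        raise ValueError("matrix columns must be a (cell_type, replicate) MultiIndex")


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the cross-column mean of order statistics.

    Tied values within a column receive the mean of the reference values at
    the tied positions. A single-column matrix is returned unchanged.
    """
    if matrix.isna().any().any():
        raise ValueError("matrix contains missing values")
    vals = matrix.to_numpy(float)
    if vals.shape[1] == 1:
        return matrix.copy()
    reference = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        order = np.argsort(col, kind="mergesort")
        ranked = reference.copy()
        # average reference values over runs of ties
        sorted_col = col[order]
        i = 0
        while i < len(col):
            jx = i
            while jx + 1 < len(col) and sorted_col[jx + 1] == sorted_col[i]:
                jx += 1
            if jx > i:
                ranked[i : jx + 1] = reference[i : jx + 1].mean()
            i = jx + 1
        out[order, j] = ranked
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def celltype_profile(matrix: pd.DataFrame, gene: str) -> pd.DataFrame:
    """Per-cell-type mean, SEM and log-ready (+0.001) expression for one gene.

    With a single replicate the SEM is undefined; it is reported as 0 with
    ``sem_defined = False``.
    """
    _require_celltype_columns(matrix)
    if gene not in matrix.index:
        raise KeyError(f"gene {gene!r} not in matrix")
    row = matrix.loc[gene]
    rows = []
    for ct in row.index.get_level_values(0).unique():
        vals = row.loc[ct].to_numpy(float)
        n = vals.size
        sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        rows.append(
            {
                "cell_type": ct,
                "mean": float(vals.mean()),
                "sem": sem,
                "sem_defined": n > 1,
                "n_replicates": n,
                "log_ready": float(vals.mean()) + LOG_OFFSET,
            }
        )
    return pd.DataFrame(rows).set_index("cell_type")


def specificity(matrix: pd.DataFrame, gene: str) -> pd.Series:
    """Cell-type mean divided by the sum of cell-type means (sums to 1)."""
    _require_celltype_columns(matrix)
    if gene not in matrix.index:
        raise KeyError(f"gene {gene!r} not in matrix")
    means = matrix.loc[gene].groupby(level=0).mean()
    total = means.sum()
    if total <= 0:
        raise ValueError(f"gene {gene!r}: zero total expression; specificity undefined")
    return means / total


def enrichment_score(matrix: pd.DataFrame, gene: str) -> pd.Series:
    """Fold change of the in-type mean over the out-of-type mean per cell type."""
    _require_celltype_columns(matrix)
    means = matrix.loc[gene].groupby(level=0).mean()
    out = {}
    for ct in means.index:
        rest = means.drop(ct).mean()
        out[ct] = float("inf") if rest == 0 else float(means[ct] / rest)
    return pd.Series(out, name=gene)


def profile_genes(
    matrix: pd.DataFrame, genes: list[str], normalize: bool = True
) -> pd.DataFrame:
    """Tidy profile table (gene x cell type rows) for a gene list."""
    _require_celltype_columns(matrix)
    present = [g for g in genes if g in matrix.index]
    mat = quantile_normalize(matrix) if normalize else matrix
    frames = []
    for g in present:
        prof = celltype_profile(mat, g).reset_index()
        prof.insert(0, "gene", g)
        prof["specificity"] = specificity(mat, g).reindex(prof["cell_type"]).to_numpy()
        prof["enrichment"] = enrichment_score(mat, g).reindex(prof["cell_type"]).to_numpy()
        frames.append(prof)
    if not frames:
        return pd.DataFrame(
            columns=["gene", "cell_type", "mean", "sem", "sem_defined", "n_replicates",
                     "log_ready", "specificity", "enrichment"]
        )
    return pd.concat(frames, ignore_index=True)
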