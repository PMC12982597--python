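"""Per-gene spatial association between a contrast map and donor expression.

For each gene, donor expression profiles are aligned onto common observation
units (spatial parcels, or one unit per sample when donors share coordinates),
reduced by PCA to the components explaining >= 95% of variance, and regressed
(weighted least squares, weights = contributing sample counts) against the
image values. Reliability comes from a bootstrap null — genomic rows permuted
relative to the image, the full PCA + regression pipeline re-run, and the
chance likelihood computed as the fraction of resampled R^2 strictly
exceeding the observed R^2 — and from the mean pairwise Pearson correlation
of the gene's profile across donors (donor autocorrelation). Genes pass the
association filter when chance likelihood < 0.001, autocorrelation >= 0.2 and
adjusted R^2 >= 0.15.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ahba import DonorExpressionBundle
from .glm import ContrastMap
from .grids import mm_to_voxel

__all__ = [
    "AlignedGeneData",
    "AlignedUnits",
    "GeneAssociationResult",
    "align_units",
    "pca_regressors",
    "weighted_regression",
    "chance_likelihood",
    "donor_autocorrelation",
    "gene_association",
    "associate_genes",
    "filter_genes",
]

RESULT_COLUMNS = [
    "gene",
    "r2_adjusted",
    "direction",
    "chance_likelihood",
    "autocorrelation",
    "n_components",
    "passes_filter",
]


@dataclass
class AlignedGeneData:
    """One gene's unit x donor expression with aligned image values and weights."""

    gene_symbol: str
    X: np.ndarray  # (n_units, n_donors), complete
    y: np.ndarray  # (n_units,)
    w: np.ndarray  # (n_units,) nonnegative
    donor_ids: list[str]
    unit_provenance: pd.DataFrame | None = None


@dataclass
class AlignedUnits:
    """All genes' expression aligned on common units.

    ``donor_expr`` maps donor_id -> (gene x unit) DataFrame (NaN where the
    donor has no sample in the unit or the gene is missing for the donor).
    ``y``/``w`` are indexed by unit.
    """

    donor_expr: dict[str, pd.DataFrame]
    y: pd.Series
    w: pd.Series
    provenance: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        first = next(iter(self.donor_expr.values()))
        return list(first.index)

    def gene_data(self, gene: str, min_units: int = 3) -> AlignedGeneData:
        """Assemble one gene's complete unit x donor matrix.

        Donor columns that are entirely missing for the gene are dropped;
        remaining rows with any missing donor are dropped.
        """
        cols, ids = [], []
        for donor, df in self.donor_expr.items():
            if gene not in df.index:
                continue
            col = df.loc[gene]
            if col.notna().any():
                cols.append(col)
                ids.append(donor)
        if len(ids) < 2:
            raise ValueError(f"gene {gene!r}: fewer than 2 donors with data")
        X = pd.concat(cols, axis=1)
        keep = X.notna().all(axis=1)
        X = X.loc[keep]
        if len(X) < min_units:
            raise ValueError(f"gene {gene!r}: only {len(X)} usable units (< {min_units})")
        return AlignedGeneData(
            gene_symbol=gene,
            X=X.to_numpy(float),
            y=self.y.loc[X.index].to_numpy(float),
            w=self.w.loc[X.index].to_numpy(float),
            donor_ids=ids,
        )


def _parcel_keys(coords: pd.DataFrame, cm: ContrastMap, edge_voxels: int) -> pd.Series:
    vox = mm_to_voxel(coords[["x", "y", "z"]].to_numpy(float), cm.affine)
    blocks = np.floor(np.rint(vox) / edge_voxels).astype(int)
    return pd.Series(
        [f"{i}_{j}_{k}" for i, j, k in blocks], index=coords.index, name="parcel"
    )


def align_units(
    bundles: list[DonorExpressionBundle],
    image_samples: dict[str, pd.DataFrame],
    cm: ContrastMap,
    parcel_edge_voxels: int = 2,
    mode: str = "parcel",
) -> AlignedUnits:
    """Aggregate donor samples onto shared spatial units.

    mode "parcel" (default): regular blocks of ``parcel_edge_voxels`` per
    axis; a unit's donor value is the mean of that donor's z-scored samples in
    the block, its image value the mean z-scored image value over all
    contributing samples (all donors), and its weight the total contributing
    sample count. Units missing any donor are dropped when a gene's matrix is
    assembled. mode "per_sample": donors must share identical coordinates;
    each retained sample is its own unit (exact-recovery configuration).
    """
    if mode not in ("parcel", "per_sample"):
        raise ValueError(f"unknown alignment mode {mode!r}")
    donor_expr: dict[str, pd.DataFrame] = {}
    y_parts, w_parts = [], []
    prov_rows = []
    ref_units: pd.Index | None = None
    for b in bundles:
        if not (b.normalized and b.gene_level):
            raise ValueError(f"donor {b.donor_id}: bundle must be gene-level and normalized")
        img = image_samples[b.donor_id]
        samples = [s for s in b.expression.columns if s in img.index and bool(img.loc[s, "retained"])]
        if not samples:
            raise ValueError(f"donor {b.donor_id}: no retained samples")
        coords = b.sample_coords.loc[samples]
        if mode == "parcel":
            keys = _parcel_keys(coords, cm, parcel_edge_voxels)
        else:
            keys = pd.Series([f"u{i:05d}" for i in range(len(samples))], index=samples)
            if ref_units is None:
                ref_coords = coords.to_numpy(float)
            elif not np.allclose(coords.to_numpy(float), ref_coords):
                raise ValueError("per_sample mode requires donors to share coordinates")
            ref_units = pd.Index(keys.values)
        expr = b.expression[samples]
        donor_expr[b.donor_id] = expr.T.groupby(keys).mean().T
        zimg = img.loc[samples, "z"].groupby(keys).agg(["sum", "count"])
        y_parts.append(zimg["sum"])
        w_parts.append(zimg["count"])
        for unit, cnt in zimg["count"].items():
            prov_rows.append({"unit": unit, "donor": b.donor_id, "n_samples": int(cnt)})

    y_sum = pd.concat(y_parts, axis=1).sum(axis=1)
    w = pd.concat(w_parts, axis=1).sum(axis=1)
    y = y_sum / w
    units = y.index.sort_values()
    if len(units) < 3:
        raise ValueError(f"only {len(units)} usable units (< 3)")
    donor_expr = {d: df.reindex(columns=units) for d, df in donor_expr.items()}
    return AlignedUnits(
        donor_expr=donor_expr,
        y=y.loc[units],
        w=w.loc[units].astype(float),
        provenance=pd.DataFrame(prov_rows),
    )


def pca_regressors(
    X: np.ndarray, variance_target: float = 0.95
) -> tuple[np.ndarray, int, np.ndarray]:
    """Column-centered PCA scores keeping the fewest components reaching the target.

    Returns (scores (n, k), k, explained variance ratio of all components).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("X must be 2-D with >= 2 donor columns")
    Xc = X - X.mean(axis=0)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    ev = s**2
    total = ev.sum()
    if total <= 0:
        raise ValueError("zero total variance; PCA undefined")
    ratio = ev / total
    k = int(np.searchsorted(np.cumsum(ratio), variance_target - 1e-12) + 1)
    k = min(k, X.shape[1])
    return u[:, :k] * s[:k], k, ratio


def weighted_regression(
    y: np.ndarray, components: np.ndarray, w: np.ndarray
) -> tuple[float, float]:
    """WLS of y on [1, components]; returns (R^2, adjusted R^2).

    R^2 uses weighted sums of squares about the weighted mean; the adjustment
    is the usual small-sample correction 1 - (1 - R^2)(n - 1)/(n - k - 1).
    """
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    S = np.atleast_2d(np.asarray(components, float))
    if S.shape[0] != y.size:
        S = S.T
    n, k = S.shape
    if y.size != n or w.size != n:
        raise ValueError("length mismatch between y, components and weights")
    if not (w >= 0).all() or w.sum() <= 0:
        raise ValueError("weights must be nonnegative and not all zero")
    if n <= k + 1:
        raise ValueError(f"undefined fit: n={n} <= k+1={k + 1}")
    sw = np.sqrt(w)
    A = np.hstack([np.ones((n, 1)), S]) * sw[:, None]
    beta, *_ = np.linalg.lstsq(A, y * sw, rcond=None)
    fitted = (np.hstack([np.ones((n, 1)), S]) @ beta)
    ybar = np.average(y, weights=w)
    sse = float(w @ (y - fitted) ** 2)
    sst = float(w @ (y - ybar) ** 2)
    if sst <= 0:
        raise ValueError("image vector has zero weighted variance")
    r2 = 1.0 - sse / sst
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
    return r2, r2_adj


def _weighted_corr(a: np.ndarray, b: np.ndarray, w: np.ndarray) -> float:
    am = a - np.average(a, weights=w)
    bm = b - np.average(b, weights=w)
    denom = np.sqrt((w @ am**2) * (w @ bm**2))
    return float(w @ (am * bm) / denom) if denom > 0 else 0.0


def _batched_null_r2(
    Xc: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    n_boot: int,
    rng: np.random.Generator,
    variance_target: float,
) -> np.ndarray:
    """R^2 of the PCA+WLS pipeline for n_boot row-permutations of centered X.

    Permuting rows leaves column means at zero, so X is centered once. SVDs
    are batched; resamples are grouped by their selected component count k and
    solved through the weighted normal equations.
    """
    n, d = Xc.shape
    perms = np.argsort(rng.random((n_boot, n)), axis=1)
    Xb = Xc[perms]  # (B, n, d)
    u, s, _ = np.linalg.svd(Xb, full_matrices=False)
    ev = s**2
    ratio = ev / ev.sum(axis=1, keepdims=True)
    cum = np.cumsum(ratio, axis=1)
    ks = (cum < variance_target - 1e-12).sum(axis=1) + 1
    ks = np.minimum(ks, d)
    scores = u * s[:, None, :]  # (B, n, d)

    ybar = np.average(y, weights=w)
    sst = float(w @ (y - ybar) ** 2)
    r2 = np.empty(n_boot)
    for k in np.unique(ks):
        idx = np.where(ks == k)[0]
        S = scores[idx][:, :, :k]  # (m, n, k)
        ones = np.ones((len(idx), n, 1))
        A = np.concatenate([ones, S], axis=2)  # (m, n, k+1)
        Aw = A * w[None, :, None]
        ata = np.einsum("mni,mnj->mij", A, Aw)
        atb = np.einsum("mni,n->mi", Aw, y)
        beta = np.linalg.solve(ata, atb[..., None])[..., 0]
        fitted = np.einsum("mni,mi->mn", A, beta)
        sse = np.einsum("n,mn->m", w, (y[None, :] - fitted) ** 2)
        r2[idx] = 1.0 - sse / sst
    return r2


def chance_likelihood(
    aligned: AlignedGeneData,
    n_boot: int = 1000,
    rng: np.random.Generator | int | None = None,
    variance_target: float = 0.95,
    r2_observed: float | None = None,
) -> float:
    """Fraction of genomic-row resamples whose R^2 strictly exceeds the observed R^2.

    Rows of the expression matrix (all donor columns together) are permuted
    uniformly while the image values and weights stay fixed, and the full
    PCA -> weighted-regression pipeline is re-run per resample.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(rng)
    if r2_observed is None:
        scores, _, _ = pca_regressors(aligned.X, variance_target)
        r2_observed, _ = weighted_regression(aligned.y, scores, aligned.w)
    Xc = aligned.X - aligned.X.mean(axis=0)
    null_r2 = _batched_null_r2(Xc, aligned.y, aligned.w, n_boot, rng, variance_target)
    return float((null_r2 > r2_observed).sum() / n_boot)


def donor_autocorrelation(X: np.ndarray) -> float:
    """Mean Pearson correlation over all unordered donor-column pairs.

    Pairs involving a zero-variance column are skipped; NaN if every pair is
    skipped.
    """
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 donor columns")
    sd = X.std(axis=0)
    vals = []
    for i in range(X.shape[1]):
        for j in range(i + 1, X.shape[1]):
            if sd[i] == 0 or sd[j] == 0:
                continue
            vals.append(float(np.corrcoef(X[:, i], X[:, j])[0, 1]))
    return float(np.mean(vals)) if vals else float("nan")


@dataclass
class GeneAssociationResult:
    gene_symbol: str
    r2_adjusted: float
    direction: int
    chance_likelihood: float
    autocorrelation: float
    n_components: int
    passes_filter: bool


def gene_association(
    aligned: AlignedGeneData,
    n_boot: int = 1000,
    rng: np.random.Generator | int | None = None,
    variance_target: float = 0.95,
    cl_max: float = 0.001,
    ac_min: float = 0.2,
    r2_min: float = 0.15,
) -> GeneAssociationResult:
    """Full per-gene statistics and the pass/fail association filter."""
    scores, k, _ = pca_regressors(aligned.X, variance_target)
    r2, r2_adj = weighted_regression(aligned.y, scores, aligned.w)
    mean_expr = aligned.X.mean(axis=1)
    direction = int(np.sign(_weighted_corr(aligned.y, mean_expr, aligned.w)))
    cl = chance_likelihood(aligned, n_boot, rng, variance_target, r2_observed=r2)
    ac = donor_autocorrelation(aligned.X)
    passes = (cl < cl_max) and (ac >= ac_min) and (r2_adj >= r2_min)
    return GeneAssociationResult(
        gene_symbol=aligned.gene_symbol,
        r2_adjusted=r2_adj,
        direction=direction,
        chance_likelihood=cl,
        autocorrelation=ac,
        n_components=k,
        passes_filter=bool(passes),
    )


def associate_genes(
    units: AlignedUnits,
    genes: list[str] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    variance_target: float = 0.95,
    cl_max: float = 0.001,
    ac_min: float = 0.2,
    r2_min: float = 0.15,
) -> pd.DataFrame:
    """Run the association for every gene; one independent RNG stream per gene.

    Genes that cannot be aligned (too few units/donors) are reported with NaN
    statistics and passes_filter = False.
    """
    genes = list(genes) if genes is not None else units.genes
    streams = np.random.SeedSequence(seed).spawn(len(genes))
    rows = []
    for gene, ss in zip(genes, streams):
        try:
            data = units.gene_data(gene)
            res = gene_association(
                data,
                n_boot=n_boot,
                rng=np.random.default_rng(ss),
                variance_target=variance_target,
                cl_max=cl_max,
                ac_min=ac_min,
                r2_min=r2_min,
            )
            rows.append(
                {
                    "gene": gene,
                    "r2_adjusted": res.r2_adjusted,
                    "direction": res.direction,
                    "chance_likelihood": res.chance_likelihood,
                    "autocorrelation": res.autocorrelation,
                    "n_components": res.n_components,
                    "passes_filter": res.passes_filter,
                }
            )
        except ValueError:
            rows.append(
                {
                    "gene": gene,
                    "r2_adjusted": np.nan,
                    "direction": 0,
                    "chance_likelihood": np.nan,
                    "autocorrelation": np.nan,
                    "n_components": 0,
                    "passes_filter": False,
                }
            )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def filter_genes(
    results: pd.DataFrame,
    cl_max: float = 0.001,
    ac_min: float = 0.2,
    r2_min: float = 0.15,
) -> list[str]:
    """Genes passing the association filter (strict < on chance likelihood,
    inclusive >= on autocorrelation and adjusted R^2), sorted by symbol."""
    ok = (
        (results["chance_likelihood"] < cl_max)
        & (results["autocorrelation"] >= ac_min)
        & (results["r2_adjusted"] >= r2_min)
    )
    return sorted(results.loc[ok.fillna(False), "gene"])
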