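"""Donor expression-bundle preparation and image sampling at tissue coordinates.

Multi-donor microarray bundles (probe x sample expression, probe-to-gene map,
sample coordinates in the image reference frame) are prepared in a fixed
order: restrict to the left hemisphere (x < 0, midline excluded), collapse
probes to one representative per gene (least-skewed pooled distribution),
then z-score each gene within each donor. Contrast maps are sampled at donor
coordinates by averaging suprathreshold voxels inside a cubic window
(default edge 5 mm) and z-scoring the window averages within donor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .glm import ContrastMap
from .grids import voxel_centers_mm

__all__ = [
    "DonorExpressionBundle",
    "select_representative_probe",
    "select_probes",
    "collapse_to_genes",
    "restrict_left_hemisphere",
    "normalize_donor",
    "sample_image_at_coords",
    "prepare_bundles",
]


@dataclass
class DonorExpressionBundle:
    """One donor's expression matrix with probe annotation and sample coordinates.

    ``expression`` is indexed by probe_id (or gene_symbol once collapsed) with
    sample_id columns. ``probe_to_gene`` maps probe_id -> gene_symbol.
    ``sample_coords`` is indexed by sample_id with columns x, y, z (mm).
    """

    donor_id: str
    expression: pd.DataFrame
    probe_to_gene: pd.Series
    sample_coords: pd.DataFrame
    normalized: bool = False
    gene_level: bool = False

    def __post_init__(self) -> None:
        if not set(self.expression.columns) <= set(self.sample_coords.index):
            raise ValueError(f"donor {self.donor_id}: samples lack coordinates")
        if not self.gene_level:
            missing = set(self.expression.index) - set(self.probe_to_gene.index)
            if missing:
                raise ValueError(f"donor {self.donor_id}: probes without gene mapping")

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]


def _pooled_probe_values(bundles: list[DonorExpressionBundle], probe: str) -> np.ndarray:
    return np.concatenate(
        [b.expression.loc[probe].to_numpy(float) for b in bundles if probe in b.expression.index]
    )


def select_representative_probe(bundles: list[DonorExpressionBundle], gene: str) -> str:
    """Probe whose pooled (all donors, all samples) distribution is least skewed.

    Skewness is the bias-corrected (adjusted Fisher-Pearson) sample skewness;
    the probe minimizing |skewness| wins, ties broken by lexicographically
    smallest probe_id.
    """
    probes = sorted(
        {p for b in bundles for p, g in b.probe_to_gene.items() if g == gene}
    )
    if not probes:
        raise KeyError(f"gene {gene!r} has no probes in the bundles")
    if len(probes) == 1:
        return probes[0]
    best, best_skew = None, np.inf
    for p in probes:  # sorted, so first minimum wins ties
        vals = _pooled_probe_values(bundles, p)
        sk = abs(float(stats.skew(vals, bias=False)))
        if not np.isfinite(sk):
            sk = np.inf
        if sk < best_skew:
            best, best_skew = p, sk
    return best if best is not None else probes[0]


def select_probes(bundles: list[DonorExpressionBundle]) -> pd.Series:
    """gene_symbol -> representative probe_id over all genes present."""
    genes = sorted({g for b in bundles for g in b.probe_to_gene.values})
    return pd.Series(
        {g: select_representative_probe(bundles, g) for g in genes}, name="probe_id"
    )


def collapse_to_genes(
    bundle: DonorExpressionBundle, gene_to_probe: pd.Series
) -> DonorExpressionBundle:
    """Keep one representative probe per gene; reindex expression by gene symbol."""
    probes = [p for p in gene_to_probe.values if p in bundle.expression.index]
    expr = bundle.expression.loc[probes].copy()
    probe_to_gene_sel = {p: g for g, p in gene_to_probe.items()}
    expr.index = [probe_to_gene_sel[p] for p in probes]
    expr = expr.sort_index()
    return replace(bundle, expression=expr, gene_level=True)


def restrict_left_hemisphere(bundle: DonorExpressionBundle) -> DonorExpressionBundle:
    """Keep samples with x strictly < 0 (midline samples are excluded)."""
    keep = bundle.sample_coords.index[bundle.sample_coords["x"] < 0]
    keep = [s for s in bundle.expression.columns if s in set(keep)]
    if not keep:
        raise ValueError(f"donor {bundle.donor_id}: no left-hemisphere samples retained")
    return replace(
        bundle,
        expression=bundle.expression[keep],
        sample_coords=bundle.sample_coords.loc[keep],
    )


def normalize_donor(bundle: DonorExpressionBundle) -> DonorExpressionBundle:
    """z-score each gene's expression within this donor: z = (x - mean) / sample SD.

    Genes constant within the donor get NaN rows (missing for that donor,
    excluded downstream) rather than raising.
    """
    if bundle.normalized:
        raise ValueError(f"donor {bundle.donor_id} already normalized")
    if bundle.n_samples < 2:
        raise ValueError(f"donor {bundle.donor_id}: need >=2 samples to normalize")
    x = bundle.expression.to_numpy(float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x - mu) / sd
    z[np.repeat(sd == 0, x.shape[1], axis=1)] = np.nan
    expr = pd.DataFrame(z, index=bundle.expression.index, columns=bundle.expression.columns)
    return replace(bundle, expression=expr, normalized=True)


def sample_image_at_coords(
    cm: ContrastMap,
    coords: pd.DataFrame,
    window_mm: float = 5.0,
) -> pd.DataFrame:
    """Average map voxels inside a cubic window centred at each coordinate.

    A voxel contributes when its centre lies within the axis-aligned cube of
    edge ``window_mm`` (inclusive bounds) and carries a finite map value
    (sub-threshold voxels of a lightly thresholded map are missing, not zero).
    Samples with empty windows are dropped (retained = False); retained raw
    averages are z-scored across samples (per call, i.e. within donor).

    Returns a DataFrame indexed by sample_id with columns raw, z,
    n_voxels_in_window, retained.
    """
    if window_mm <= 0:
        raise ValueError("window_mm must be positive")
    shape = cm.t_values.shape
    centers = voxel_centers_mm(shape, cm.affine)  # (V, 3)
    flat = cm.t_values.ravel()
    finite = np.isfinite(flat)
    half = window_mm / 2.0

    raw = np.full(len(coords), np.nan)
    counts = np.zeros(len(coords), dtype=int)
    pts = coords[["x", "y", "z"]].to_numpy(float)
    for i, p in enumerate(pts):
        inside = np.all(np.abs(centers - p) <= half, axis=1) & finite
        counts[i] = int(inside.sum())
        if counts[i]:
            raw[i] = flat[inside].mean()

    retained = counts > 0
    if not retained.any():
        raise ValueError("all samples fell outside the map; nothing to sample")
    if not retained.all():
        warnings.warn(
            f"dropping {int((~retained).sum())} sample(s) with empty windows", stacklevel=2
        )
    z = np.full(len(coords), np.nan)
    vals = raw[retained]
    sd = vals.std(ddof=1) if vals.size > 1 else 0.0
    if sd == 0:
        raise ValueError("window averages are constant; donor image vector degenerate")
    z[retained] = (vals - vals.mean()) / sd
    return pd.DataFrame(
        {
            "raw": raw,
            "z": z,
            "n_voxels_in_window": counts,
            "retained": retained,
        },
        index=coords.index,
    )


def prepare_bundles(
    bundles: list[DonorExpressionBundle],
    cm: ContrastMap,
    window_mm: float = 5.0,
    restrict_hemisphere: bool = True,
) -> tuple[list[DonorExpressionBundle], dict[str, pd.DataFrame]]:
    """Full preparation: restrict -> select probes -> collapse -> normalize; sample map.

    Returns the gene-level normalized bundles and, per donor, the image sample
    vector at that donor's retained coordinates.
    """
    if restrict_hemisphere:
        bundles = [restrict_left_hemisphere(b) for b in bundles]
    gene_to_probe = select_probes(bundles)
    bundles = [normalize_donor(collapse_to_genes(b, gene_to_probe)) for b in bundles]
    image_samples = {
        b.donor_id: sample_image_at_coords(
            cm, b.sample_coords.loc[list(b.expression.columns)], window_mm
        )
        for b in bundles
    }
    return bundles, image_samples
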