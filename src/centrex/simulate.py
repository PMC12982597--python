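"""Synthetic cohorts, donor atlases, gene sets and cell-type matrices with known truth.

The generator emulates the statistical structure the analysis assumes, at
desk scale, with every planted effect returned as ground-truth labels:

* two-group resting-state cohorts in which a set of "hub" voxels shares a
  latent time series whose gain differs by group — pairwise correlation among
  hub voxels, hence binary degree, rises monotonically with the gain;
* multi-donor expression atlases in which coupled genes track a supplied
  contrast map at the sampled coordinates (effect size ``coupling_beta``,
  noise ``expression_noise_sd``), each gene carrying one untransformed
  representative probe and optionally skewed siblings;
* gene-set collections with one deliberately enriched set;
* cell-type matrices with designated marker genes.

All randomness flows from one integer seed through named generators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .ahba import DonorExpressionBundle
from .centrality import CohortDataset
from .enrichment import GeneSetCollection
from .glm import ContrastMap
from .grids import centered_affine, grid_bounds_mm, nearest_voxel

__all__ = [
    "SimulationConfig",
    "default_hub_voxels",
    "generate_cohort",
    "generate_donor_atlas",
    "generate_gene_sets",
    "generate_celltype_matrix",
    "skew_transform",
]


def default_hub_voxels(grid_shape: tuple[int, int, int]) -> frozenset[tuple[int, int, int]]:
    """A compact left-hemisphere block (so hemisphere-restricted sampling sees it)."""
    nx, ny, nz = grid_shape
    xs = range(1, max(2, nx // 3 + 1))
    ys = range(ny // 4, ny - ny // 4)
    zs = range(nz // 4, nz - nz // 4)
    return frozenset((i, j, k) for i in xs for j in ys for k in zs)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort and atlas.

    Defaults give a desk-scale study: 10x10x10 voxels at 2 mm, 120 timepoints,
    20 subjects per group. Hub voxels carry a Gaussian-tapered gain (peak 1.5
    in patients, none in controls) over unit noise, so the planted degree
    elevation is spatially graded — as group contrast maps of real cohorts
    are — and survives within-subject standardization. Six donors of 800
    samples and 100 genes of which 20 are coupled with beta 1.0 against unit
    expression noise.
    """

    grid_shape: tuple[int, int, int] = (10, 10, 10)
    n_timepoints: int = 120
    n_per_group: tuple[int, int] = (20, 20)  # (patients, controls)
    hub_voxel_set: frozenset[tuple[int, int, int]] | None = None
    shared_signal_gain: tuple[float, float] = (1.5, 0.0)
    hub_envelope: float = 0.6  # Gaussian taper of the hub gain; 0 = flat block
    noise_sd: float = 1.0
    n_donors: int = 6
    n_samples_per_donor: int = 800
    n_genes: int = 100
    n_coupled_genes: int = 20
    coupling_beta: float = 1.0
    expression_noise_sd: float = 1.0
    n_probes_per_gene: int = 2
    skew_severity: float = 1.0
    voxel_size_mm: float = 2.0
    gm_prob: float = 0.6
    shared_donor_coords: bool = False
    confounded_covariates: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.grid_shape) or len(self.grid_shape) != 3:
            raise ValueError("grid_shape must be a positive integer triple")
        if self.n_timepoints < 3:
            raise ValueError("n_timepoints must be >= 3")
        if any(n <= 0 for n in self.n_per_group):
            raise ValueError("n_per_group entries must be positive")
        if any(g < 0 for g in self.shared_signal_gain):
            raise ValueError("shared_signal_gain must be nonnegative")
        if self.noise_sd <= 0 or self.expression_noise_sd <= 0:
            raise ValueError("noise SDs must be positive")
        if not (0 < self.n_coupled_genes <= self.n_genes or self.n_coupled_genes == 0):
            raise ValueError("need 0 <= n_coupled_genes <= n_genes")
        if self.n_probes_per_gene < 1:
            raise ValueError("n_probes_per_gene must be >= 1")
        if self.skew_severity < 0:
            raise ValueError("skew_severity must be >= 0")
        hubs = self.hubs
        shape = np.asarray(self.grid_shape)
        for v in hubs:
            if len(v) != 3 or any(i < 0 or i >= s for i, s in zip(v, shape)):
                raise ValueError(f"hub voxel {v} outside grid {self.grid_shape}")

    @property
    def hubs(self) -> frozenset[tuple[int, int, int]]:
        if self.hub_voxel_set is not None:
            return frozenset(tuple(v) for v in self.hub_voxel_set)
        return default_hub_voxels(self.grid_shape)

    @property
    def affine(self) -> np.ndarray:
        return centered_affine(self.grid_shape, self.voxel_size_mm)


def _hub_index_arrays(hubs: frozenset[tuple[int, int, int]]) -> tuple[np.ndarray, ...]:
    arr = np.array(sorted(hubs))
    return arr[:, 0], arr[:, 1], arr[:, 2]


def hub_gain_envelope(hubs: frozenset[tuple[int, int, int]], envelope: float) -> np.ndarray:
    """Per-hub-voxel gain multiplier: a Gaussian taper about the hub centroid.

    ``envelope`` scales the taper width relative to the hub's maximal extent
    (sigma = envelope * max distance from centroid); 0 gives a flat block.
    A graded gain makes the planted contrast spatially smooth, as group
    t-maps of real cohorts are, so point samples and window averages of the
    map agree.
    """
    arr = np.array(sorted(hubs), dtype=float)
    if envelope <= 0 or len(arr) == 1:
        return np.ones(len(arr))
    c = arr.mean(axis=0)
    dist = np.linalg.norm(arr - c, axis=1)
    sigma = envelope * dist.max()
    if sigma == 0:
        return np.ones(len(arr))
    return np.exp(-(dist**2) / (2.0 * sigma**2))


def generate_cohort(config: SimulationConfig) -> CohortDataset:
    """Two-group cohort: Gaussian noise plus a gain-scaled shared latent at hub voxels.

    Each subject has an independent latent time series added (scaled by the
    group gain) to every hub voxel, which induces within-subject hub-hub
    correlation g^2 / (g^2 + noise_sd^2). Covariates are drawn independently
    of group unless ``confounded_covariates`` is set.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    n_pat, n_con = config.n_per_group
    gains = [config.shared_signal_gain[0]] * n_pat + [config.shared_signal_gain[1]] * n_con
    groups = ["patient"] * n_pat + ["control"] * n_con
    hub_idx = _hub_index_arrays(config.hubs)
    envelope = hub_gain_envelope(config.hubs, config.hub_envelope)

    subjects = []
    rows = []
    for i, (grp, gain) in enumerate(zip(groups, gains)):
        sid = f"sub-{i:03d}"
        ts = rng.normal(0.0, config.noise_sd, size=config.grid_shape + (config.n_timepoints,))
        latent = rng.normal(0.0, 1.0, size=config.n_timepoints)
        ts[hub_idx] += (gain * envelope)[:, None] * latent
        subjects.append((sid, ts))
        age_shift = 8.0 if (config.confounded_covariates and grp == "patient") else 0.0
        scan_p = 0.7 if (config.confounded_covariates and grp == "patient") else 0.5
        rows.append(
            {
                "subject_id": sid,
                "group": grp,
                "age": float(np.clip(rng.normal(45.0 + age_shift, 12.0), 18.0, 80.0)),
                "sex": rng.choice(["F", "M"]),
                "scanner": rng.choice(["A", "B"], p=[scan_p, 1 - scan_p]),
            }
        )
    gm = np.full(config.grid_shape, float(config.gm_prob))
    return CohortDataset(
        subjects=subjects,
        gm_probability=gm,
        covariates=pd.DataFrame(rows),
        affine=config.affine,
    )


def skew_transform(x: np.ndarray, severity: float) -> np.ndarray:
    """Monotone exponential tilt (exp(s*x) - 1) / s; identity at severity 0."""
    if severity < 0:
        raise ValueError("severity must be >= 0")
    if severity == 0:
        return np.asarray(x, float).copy()
    return (np.exp(severity * np.asarray(x, float)) - 1.0) / severity


def _map_values_at(cm: ContrastMap, coords_mm: np.ndarray) -> np.ndarray:
    """Nearest-voxel map value per coordinate; missing voxels contribute 0."""
    vox = nearest_voxel(coords_mm, cm.affine, cm.t_values.shape)
    vals = cm.t_values[vox[:, 0], vox[:, 1], vox[:, 2]]
    return np.nan_to_num(vals, nan=0.0)


def generate_donor_atlas(
    config: SimulationConfig, coupling_map: ContrastMap
) -> tuple[list[DonorExpressionBundle], pd.DataFrame]:
    """Multi-donor probe x sample bundles spatially coupled to a contrast map.

    Coupled genes' latent expression at a sample is
    ``coupling_beta * map(coordinate) + N(0, expression_noise_sd)``; null
    genes are pure noise. Each gene has ``n_probes_per_gene`` probes: the
    designated representative carries the untransformed signal, siblings are
    monotone skew-transformed copies. Returns the bundles and a truth table
    (gene, coupled, representative_probe).
    """
    if coupling_map.t_values.shape != tuple(config.grid_shape):
        raise ValueError("coupling map grid does not match the configured grid")
    if config.coupling_beta != 0 and not np.isfinite(coupling_map.t_values).any():
        raise ValueError("coupling_beta is nonzero but the coupling map is empty")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    genes = [f"GENE{g:04d}" for g in range(config.n_genes)]
    coupled = np.zeros(config.n_genes, dtype=bool)
    coupled[: config.n_coupled_genes] = True
    rep_idx = rng.integers(0, config.n_probes_per_gene, size=config.n_genes)

    probe_ids = []
    probe_gene = []
    for g, gene in enumerate(genes):
        for p in range(config.n_probes_per_gene):
            probe_ids.append(f"P{g:04d}_{p}")
            probe_gene.append(gene)
    probe_to_gene = pd.Series(probe_gene, index=probe_ids, name="gene_symbol")

    low, high = grid_bounds_mm(config.grid_shape, config.affine)
    shared_coords = rng.uniform(low, high, size=(config.n_samples_per_donor, 3))

    bundles = []
    for d in range(config.n_donors):
        donor_id = f"donor{d + 1}"
        coords = (
            shared_coords
            if config.shared_donor_coords
            else rng.uniform(low, high, size=(config.n_samples_per_donor, 3))
        )
        sample_ids = [f"{donor_id}_s{i:04d}" for i in range(config.n_samples_per_donor)]
        map_vals = _map_values_at(coupling_map, coords)
        signal = np.where(coupled[:, None], config.coupling_beta * map_vals[None, :], 0.0)
        latent = signal + rng.normal(
            0.0, config.expression_noise_sd, size=(config.n_genes, config.n_samples_per_donor)
        )
        expr = np.empty((len(probe_ids), config.n_samples_per_donor))
        for g in range(config.n_genes):
            for p in range(config.n_probes_per_gene):
                row = g * config.n_probes_per_gene + p
                if p == rep_idx[g]:
                    expr[row] = latent[g]
                else:
                    expr[row] = skew_transform(latent[g], config.skew_severity)
        bundles.append(
            DonorExpressionBundle(
                donor_id=donor_id,
                expression=pd.DataFrame(expr, index=probe_ids, columns=sample_ids),
                probe_to_gene=probe_to_gene,
                sample_coords=pd.DataFrame(coords, index=sample_ids, columns=["x", "y", "z"]),
            )
        )
    truth = pd.DataFrame(
        {
            "gene": genes,
            "coupled": coupled,
            "representative_probe": [
                f"P{g:04d}_{rep_idx[g]}" for g in range(config.n_genes)
            ],
        }
    )
    return bundles, truth


def generate_gene_sets(
    truth_labels: pd.DataFrame,
    n_sets: int = 10,
    enriched_fraction: float = 1.0,
    set_size: int = 10,
    seed: int = 0,
    namespace: str = "synthetic_process",
) -> tuple[GeneSetCollection, str]:
    """Gene-set collection with one set over-populated with coupled genes.

    The planted set draws ``round(enriched_fraction * set_size)`` members from
    the coupled genes (the rest from null genes); the remaining sets are
    uniform draws from the whole background. Returns (collection, planted label).
    """
    if not 0.0 <= enriched_fraction <= 1.0:
        raise ValueError("enriched_fraction must lie in [0, 1]")
    background = list(truth_labels["gene"])
    if not background:
        raise ValueError("empty background gene list")
    coupled = list(truth_labels.loc[truth_labels["coupled"], "gene"])
    null = list(truth_labels.loc[~truth_labels["coupled"], "gene"])
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))

    n_coupled = min(int(round(enriched_fraction * set_size)), len(coupled))
    planted = list(rng.choice(coupled, size=n_coupled, replace=False)) + list(
        rng.choice(null, size=min(set_size - n_coupled, len(null)), replace=False)
    )
    sets = {"SET_PLANTED": set(planted)}
    for s in range(1, n_sets):
        sets[f"SET{s:03d}"] = set(
            rng.choice(background, size=min(set_size, len(background)), replace=False)
        )
    return GeneSetCollection(sets=sets, namespace=namespace), "SET_PLANTED"


def generate_celltype_matrix(
    genes: Sequence[str],
    cell_types: Sequence[str] = ("neuron", "astrocyte", "microglia", "oligodendrocyte", "endothelial"),
    n_replicates: int = 3,
    n_marker_genes: int = 10,
    marker_factor: float = 10.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Nonnegative genes x (cell type, replicate) matrix with planted markers.

    The first ``n_marker_genes`` genes get ``marker_factor``-fold elevated
    expression in one cell type (round-robin). Returns (matrix, marker truth).
    """
    if len(cell_types) < 2:
        raise ValueError("need at least 2 cell types")
    if n_replicates < 1:
        raise ValueError("need at least 1 replicate per cell type")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    cols = pd.MultiIndex.from_product(
        [list(cell_types), [f"rep{r + 1}" for r in range(n_replicates)]],
        names=["cell_type", "replicate"],
    )
    base = rng.gamma(shape=2.0, scale=1.0, size=(len(genes), len(cols)))
    markers = []
    for i, gene in enumerate(genes[: min(n_marker_genes, len(genes))]):
        ct = cell_types[i % len(cell_types)]
        sel = cols.get_level_values(0) == ct
        base[i, sel] *= marker_factor
        markers.append({"gene": gene, "marker_of": ct})
    matrix = pd.DataFrame(base, index=list(genes), columns=cols)
    return matrix, pd.DataFrame(markers, columns=["gene", "marker_of"])
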