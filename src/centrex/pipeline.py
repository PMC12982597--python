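"""End-to-end pipeline: simulate -> centrality -> GLM -> association -> enrichment -> cell types.

Every numeric threshold of the analysis lives in :class:`PipelineConfig`
(defaults: GM probability 0.20, degree r > 0.25, display p < 0.001 with
cluster extent k = 20, association input p < 0.01, 5 mm sampling window,
PCA variance 95%, 1000 bootstraps, filter chance likelihood < 0.001 /
autocorrelation >= 0.2 / adjusted R^2 >= 0.15, enrichment alpha 0.05). Each
stage writes its outputs plus a JSON provenance sidecar; identical config and
seed reproduce identical bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ahba, association, celltype, centrality, enrichment, glm, io, simulate

__all__ = ["PipelineConfig", "run_pipeline", "PipelineResult"]


@dataclass(frozen=True)
class PipelineConfig:
    gm_threshold: float = 0.20
    r_threshold: float = 0.25
    display_p: float = 0.001
    display_k: int = 20
    assoc_p: float = 0.01
    window_mm: float = 5.0
    pca_variance: float = 0.95
    n_boot: int = 1000
    cl_max: float = 0.001
    ac_min: float = 0.2
    r2_min: float = 0.15
    enrichment_alpha: float = 0.05
    parcel_edge_voxels: int = 2
    alignment_mode: str = "parcel"  # parcel | per_sample
    transform: str = "z_standardized"
    seed: int = 0
    simulation: simulate.SimulationConfig = field(default_factory=simulate.SimulationConfig)

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("gm_threshold", 0.0, 1.0),
            ("display_p", 0.0, 1.0),
            ("assoc_p", 0.0, 1.0),
            ("pca_variance", 0.0, 1.0),
            ("cl_max", 0.0, 1.0),
            ("enrichment_alpha", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not (lo < v < hi):
                raise ValueError(f"{name}={v} outside ({lo}, {hi})")
        if self.display_k < 1 or self.n_boot < 1 or self.parcel_edge_voxels < 1:
            raise ValueError("display_k, n_boot and parcel_edge_voxels must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", {})
        if "grid_shape" in sim:
            sim["grid_shape"] = tuple(sim["grid_shape"])
        if "n_per_group" in sim:
            sim["n_per_group"] = tuple(sim["n_per_group"])
        if "hub_voxel_set" in sim and sim["hub_voxel_set"] is not None:
            sim["hub_voxel_set"] = frozenset(tuple(v) for v in sim["hub_voxel_set"])
        if "shared_signal_gain" in sim:
            sim["shared_signal_gain"] = tuple(sim["shared_signal_gain"])
        return cls(**raw, simulation=simulate.SimulationConfig(**sim))


@dataclass
class PipelineResult:
    """In-memory handles to every stage output plus recovery metrics."""

    cohort: centrality.CohortDataset
    contrast_display: glm.ContrastMap
    contrast_light: glm.ContrastMap
    associations: pd.DataFrame
    passing_genes: list[str]
    enrichment: pd.DataFrame
    celltype_profiles: pd.DataFrame
    truth: pd.DataFrame
    metrics: dict


def _write_tables(outdir: Path, result: PipelineResult, config: PipelineConfig) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cov = outdir / "covariates.tsv"
    result.cohort.covariates.to_csv(cov, sep="\t", index=False)
    assoc = outdir / "associations.tsv"
    result.associations.to_csv(assoc, sep="\t", index=False)
    passing = outdir / "passing_genes.txt"
    passing.write_text("".join(g + "\n" for g in result.passing_genes))
    enr = outdir / "enrichment.tsv"
    result.enrichment.to_csv(enr, sep="\t", index=False)
    prof = outdir / "celltype_profiles.tsv"
    result.celltype_profiles.to_csv(prof, sep="\t", index=False)
    truth = outdir / "truth_labels.tsv"
    result.truth.to_csv(truth, sep="\t", index=False)
    io.save_volume(outdir / "tmap_display.nii", result.contrast_display.t_values,
                   result.contrast_display.affine)
    io.save_volume(outdir / "tmap_light.nii", result.contrast_light.t_values,
                   result.contrast_light.affine)
    for p, stage in [
        (cov, "simulate"), (assoc, "associate"), (passing, "filter"),
        (enr, "enrich"), (prof, "celltype"), (truth, "simulate"),
    ]:
        io.write_sidecar(p, stage, config, extra={"seed": config.seed})


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Simulate a study under ``config`` and run the full analysis on it.

    Stages: cohort simulation; per-subject degree centrality within the GM
    mask; standardization; patients-greater-than-controls GLM with age, sex
    and scanner covariates; dual thresholding (display and lenient
    association input); donor-atlas simulation coupled to the *unthresholded*
    t-map; hemisphere restriction, probe selection and donor normalization;
    window sampling of the light-thresholded map; per-gene PCA + weighted
    regression with the bootstrap chance likelihood and donor
    autocorrelation; the association filter; hypergeometric enrichment of the
    passing list against simulated gene sets; cell-type profiling.
    """
    sim = replace(config.simulation, seed=config.seed)
    cohort = simulate.generate_cohort(sim)
    mask = centrality.make_gm_mask(cohort.gm_probability, config.gm_threshold)
    maps = [
        centrality.transform_centrality(
            centrality.degree_centrality(ts, mask, config.r_threshold, subject_id=sid),
            config.transform,
        )
        for sid, ts in cohort.subjects
    ]
    design = glm.build_design(cohort.covariates, groups=["control", "patient"])
    cm = glm.fit_voxelwise_glm(maps, design, "patient_gt_control", affine=cohort.affine)
    cm_display = glm.threshold_map(cm, config.display_p, config.display_k)
    cm_light = glm.threshold_map(cm, config.assoc_p, 1)

    bundles, truth = simulate.generate_donor_atlas(sim, cm_light)
    prepared, image_samples = ahba.prepare_bundles(bundles, cm_light, config.window_mm)
    units = association.align_units(
        prepared, image_samples, cm_light,
        parcel_edge_voxels=config.parcel_edge_voxels, mode=config.alignment_mode,
    )
    assoc = association.associate_genes(
        units,
        n_boot=config.n_boot,
        seed=config.seed,
        variance_target=config.pca_variance,
        cl_max=config.cl_max,
        ac_min=config.ac_min,
        r2_min=config.r2_min,
    )
    passing = association.filter_genes(assoc, config.cl_max, config.ac_min, config.r2_min)

    background = list(truth["gene"])
    collection, planted_label = simulate.generate_gene_sets(truth, seed=config.seed)
    if passing:
        enr = enrichment.enrich_collection(passing, collection, background, config.enrichment_alpha)
    else:
        enr = pd.DataFrame(
            columns=["namespace", "set", "n_hits", "set_size", "p_raw", "p_bonferroni", "significant"]
        )
    ct_matrix, _ = simulate.generate_celltype_matrix(background, seed=config.seed)
    profiles = celltype.profile_genes(ct_matrix, passing)

    coupled = set(truth.loc[truth["coupled"], "gene"])
    null = set(truth.loc[~truth["coupled"], "gene"])
    hits = set(passing)
    metrics = {
        "n_passing": len(passing),
        "coupled_recovery_rate": len(hits & coupled) / len(coupled) if coupled else float("nan"),
        "null_pass_rate": len(hits & null) / len(null) if null else float("nan"),
        "planted_set_label": planted_label,
        "n_display_clusters": (cm_display.threshold_record or {}).get("n_clusters", 0),
    }
    result = PipelineResult(
        cohort=cohort,
        contrast_display=cm_display,
        contrast_light=cm_light,
        associations=assoc,
        passing_genes=passing,
        enrichment=enr,
        celltype_profiles=profiles,
        truth=truth,
        metrics=metrics,
    )
    if outdir is not None:
        _write_tables(Path(outdir), result, config)
    return result
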