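"""File formats: NIfTI volumes, donor-bundle TSVs, GMT gene sets, provenance sidecars.

Donor bundles follow a three-file schema per donor (expression.tsv:
probe_id x sample_id; probes.tsv: probe_id, gene_symbol; samples.tsv:
sample_id, x, y, z in mm) that also fits real multi-donor atlas exports.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .ahba import DonorExpressionBundle
from .enrichment import GeneSetCollection

__all__ = [
    "save_volume",
    "load_volume",
    "write_donor_bundle",
    "read_donor_bundle",
    "write_gmt",
    "read_gmt",
    "write_sidecar",
]


def save_volume(path: str | Path, data: np.ndarray, affine: np.ndarray) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    # fix the gzip timestamp so identical volumes are byte-identical
    if path.suffix == ".gz":
        with open(path, "wb") as fh:
            import gzip

            with gzip.GzipFile(fileobj=fh, mode="wb", mtime=0) as gz:
                gz.write(img.to_bytes())
    else:
        nib.save(img, str(path))
    return path


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), np.asarray(img.affine)


def write_donor_bundle(bundle: DonorExpressionBundle, directory: str | Path) -> Path:
    d = Path(directory) / bundle.donor_id
    d.mkdir(parents=True, exist_ok=True)
    expr = bundle.expression.copy()
    expr.index.name = "probe_id" if not bundle.gene_level else "gene_symbol"
    expr.to_csv(d / "expression.tsv", sep="\t")
    pd.DataFrame(
        {"probe_id": bundle.probe_to_gene.index, "gene_symbol": bundle.probe_to_gene.values}
    ).to_csv(d / "probes.tsv", sep="\t", index=False)
    coords = bundle.sample_coords.copy()
    coords.index.name = "sample_id"
    coords.to_csv(d / "samples.tsv", sep="\t")
    return d


def read_donor_bundle(directory: str | Path, donor_id: str | None = None) -> DonorExpressionBundle:
    d = Path(directory)
    expr = pd.read_csv(d / "expression.tsv", sep="\t", index_col=0)
    probes = pd.read_csv(d / "probes.tsv", sep="\t")
    coords = pd.read_csv(d / "samples.tsv", sep="\t", index_col="sample_id")
    return DonorExpressionBundle(
        donor_id=donor_id or d.name,
        expression=expr,
        probe_to_gene=pd.Series(
            probes["gene_symbol"].values, index=probes["probe_id"], name="gene_symbol"
        ),
        sample_coords=coords[["x", "y", "z"]],
    )


def write_gmt(collection: GeneSetCollection, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for label in sorted(collection.sets):
            members = "\t".join(sorted(collection.sets[label]))
            fh.write(f"{label}\t{collection.namespace}\t{members}\n")
    return path


def read_gmt(path: str | Path, namespace: str = "") -> GeneSetCollection:
    sets: dict[str, set[str]] = {}
    ns = namespace
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            label, desc, *members = parts
            sets[label] = set(m for m in members if m)
            ns = ns or desc
    return GeneSetCollection(sets=sets, namespace=ns)


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in sorted(obj) if not isinstance(obj, (list, tuple))] \
            if isinstance(obj, (set, frozenset)) else [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    return obj


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_sidecar(
    output_path: str | Path,
    stage: str,
    config,
    inputs: list[str | Path] = (),
    extra: dict | None = None,
) -> Path:
    """JSON provenance sidecar: stage, serialized config, input hashes, version."""
    from . import __version__

    sidecar = Path(str(output_path) + ".json")
    payload = {
        "stage": stage,
        "output": Path(output_path).name,
        "config": _jsonable(config),
        "inputs": {Path(p).name: file_sha256(p) for p in inputs},
        "centrex_version": __version__,
    }
    if extra:
        payload.update(_jsonable(extra))
    sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return sidecar
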