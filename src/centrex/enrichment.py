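"""Hypergeometric over-representation of a gene list against gene-set collections.

The background universe is the full gene list fed into the spatial
association (not the whole genome); Bonferroni correction counts the sets
tested within each namespace, and significance is declared at adjusted
p < 0.05. One-tailed over-representation only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "hypergeometric_enrichment",
    "bonferroni_adjust",
    "enrich_collection",
]


@dataclass
class GeneSetCollection:
    """Named gene sets within one namespace (e.g. a GO sub-ontology)."""

    sets: dict[str, set[str]]
    namespace: str = ""

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class EnrichmentResult:
    set_label: str
    n_hits: int
    set_size: int
    background_size: int
    hit_list_size: int
    p_raw: float
    p_bonferroni: float = field(default=float("nan"))
    significant: bool = False


def hypergeometric_enrichment(
    hits: Iterable[str], gene_set: Iterable[str], background: Iterable[str]
) -> EnrichmentResult:
    """Upper-tail hypergeometric P(X >= k) for the overlap of hits with a set.

    Population N = |background|, successes K = |set ∩ background|, draws
    n = |hits|, observed k = |hits ∩ set|. Hits must lie in the background.
    """
    background = set(background)
    hits = set(hits)
    if not background:
        raise ValueError("background universe is empty")
    if not hits:
        raise ValueError("hit list is empty")
    if not hits <= background:
        raise ValueError("hit list contains genes outside the background universe")
    annotated = set(gene_set) & background
    k = len(hits & annotated)
    N, K, n = len(background), len(annotated), len(hits)
    p_raw = float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(
        set_label="",
        n_hits=k,
        set_size=K,
        background_size=N,
        hit_list_size=n,
        p_raw=min(p_raw, 1.0),
    )


def bonferroni_adjust(p_values: np.ndarray | list[float], alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Multiply by the number of tests, cap at 1; flag strict < alpha."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    adj = np.minimum(p * p.size, 1.0)
    return adj, adj < alpha


def enrich_collection(
    hits: Iterable[str],
    collection: GeneSetCollection,
    background: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test every set in the collection; Bonferroni m = number of sets tested.

    Returns one row per set (namespace, set, n_hits, set_size, p_raw,
    p_bonferroni, significant) sorted by raw p.
    """
    background = set(background)
    hits = set(hits)
    rows = []
    for label, members in collection.sets.items():
        res = hypergeometric_enrichment(hits, members, background)
        rows.append(
            {
                "namespace": collection.namespace,
                "set": label,
                "n_hits": res.n_hits,
                "set_size": res.set_size,
                "p_raw": res.p_raw,
            }
        )
    df = pd.DataFrame(rows)
    adj, sig = bonferroni_adjust(df["p_raw"].to_numpy(), alpha)
    df["p_bonferroni"] = adj
    df["significant"] = sig
    return df.sort_values(["p_raw", "set"], kind="mergesort").reset_index(drop=True)
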