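"""Module candidates: silhouette-selected agglomerative clustering + controls.

A module candidate is one cluster of a gene's variants in embedding space.
The number of clusters k is chosen by scanning k in [k_min, min(k_max, n-1)]
and keeping the k with the highest mean silhouette score (ties broken toward
the smaller k). Genes with fewer than 3 variants cannot be silhouette-scanned
and yield a single whole-gene candidate, keeping candidate counts comparable
to the gene-level control.

Two control definitions bracket the discovery approaches:

``ctrl_gla``  every gene is one module (passive aggregation);
``ctrl_inv``  every single variant is its own module (no inference at all).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score

from .cohort import GeneMap
from .embedding import EmbeddingTable

APPROACHES = ("lcw_sg", "gmf_nmf", "gmf_pca", "ctrl_gla", "ctrl_inv")


@dataclass(frozen=True)
class ModuleCandidate:
    """A gene plus a subset of its variants, tagged with the producing approach."""

    gene_id: str
    variants: frozenset
    approach: str
    module_id: str

    def sorted_variants(self) -> list[str]:
        return sorted(self.variants)


def _make_candidates(
    gene_id: str, approach: str, clusters: list[list[str]]
) -> list[ModuleCandidate]:
    # stable ordering: clusters sorted by their smallest variant id
    clusters = sorted(clusters, key=min)
    return [
        ModuleCandidate(gene_id, frozenset(c), approach, f"{gene_id}:{approach}:{i:03d}")
        for i, c in enumerate(clusters)
    ]


def silhouette_scan(
    X: np.ndarray, k_min: int = 2, k_max: int = 20, linkage: str = "ward"
) -> list[tuple[int, float, np.ndarray]]:
    """Cluster at each k in [k_min, min(k_max, n-1)]; return (k, score, labels).

    Non-finite silhouettes (possible when all points coincide) are mapped to
    -inf so they can never be selected.
    """
    n = X.shape[0]
    results = []
    for k in range(k_min, min(k_max, n - 1) + 1):
        labels = AgglomerativeClustering(n_clusters=k, linkage=linkage).fit_predict(X)
        with np.errstate(invalid="ignore", divide="ignore"):
            score = silhouette_score(X, labels)
        if not np.isfinite(score):
            score = -np.inf
        results.append((k, float(score), labels))
    return results


def select_k(results: list[tuple[int, float, np.ndarray]]) -> tuple[int, float, np.ndarray] | None:
    """Argmax of silhouette; ties (and the scan order) favour the smaller k."""
    best = None
    for k, score, labels in results:
        if score == -np.inf:
            continue
        if best is None or score > best[1]:
            best = (k, score, labels)
    return best


def cluster_embeddings(
    table: EmbeddingTable, k_min: int = 2, k_max: int = 20, linkage: str = "ward"
) -> list[ModuleCandidate]:
    """Silhouette-selected agglomerative clustering of one gene's embeddings.

    Genes with n < 3 vectors (or degenerate all-identical embeddings) return
    one candidate containing every variant.
    """
    order = table.variant_order
    n = len(order)
    if n < 3:
        return _make_candidates(table.gene_id, table.backend, [order])
    X = table.matrix(order)
    if np.allclose(X, X[0]):  # degenerate: all embeddings coincide
        return _make_candidates(table.gene_id, table.backend, [order])
    best = select_k(silhouette_scan(X, k_min, k_max, linkage))
    if best is None:
        return _make_candidates(table.gene_id, table.backend, [order])
    _, _, labels = best
    clusters = [
        [v for v, lab in zip(order, labels) if lab == c] for c in np.unique(labels)
    ]
    return _make_candidates(table.gene_id, table.backend, clusters)


def modules_gla(gene_map: GeneMap) -> list[ModuleCandidate]:
    """One candidate per gene containing every observed variant."""
    return [
        cand
        for gene, vs in gene_map
        for cand in _make_candidates(gene, "ctrl_gla", [list(vs)])
    ]


def modules_inv(gene_map: GeneMap) -> list[ModuleCandidate]:
    """One singleton candidate per observed variant (scored by carrier status)."""
    out: list[ModuleCandidate] = []
    for gene, vs in gene_map:
        out.extend(_make_candidates(gene, "ctrl_inv", [[v] for v in vs]))
    return out
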