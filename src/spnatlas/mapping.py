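"""Nearest-centroid label transfer between taxonomies with support filtering.

A query dataset (cells x genes) is mapped onto a reference taxonomy by
assigning every cell to the reference cluster centroid with the highest
Pearson correlation (or smallest Euclidean distance) over a shared mapping
gene set — the union of the top differentially expressed genes per cluster
comparison, intersected with the genes present in both datasets.
Correspondence tables are cleaned by a reciprocal support filter (clusters
with fewer than three mapped cells removed, default), and summarized as
confusion matrices at cluster, supertype and subclass levels of the
reference hierarchy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceTaxonomy",
    "MappingResult",
    "select_mapping_genes",
    "map_to_nearest_centroid",
    "filter_low_support",
    "build_confusion",
]


@dataclass
class ReferenceTaxonomy:
    """Cluster centroids (clusters x genes) and cluster -> supertype -> subclass map."""

    centroids: pd.DataFrame
    hierarchy: pd.DataFrame  # index cluster, columns supertype, subclass

    def __post_init__(self) -> None:
        missing = set(self.centroids.index) - set(self.hierarchy.index)
        if missing:
            raise ValueError(f"clusters missing from hierarchy map: {sorted(missing)[:5]}")


@dataclass
class MappingResult:
    """Per-cell best cluster and similarity, plus per-cluster summaries."""

    assignments: pd.DataFrame  # index cell; columns: best_cluster, similarity
    query_clusters: pd.Series | None = None  # per cell, optional
    metric: str = "pearson"
    support_filtered: bool = False
    kept_query_clusters: list | None = None
    kept_ref_clusters: list | None = None

    def mapped_cell_counts(self) -> pd.Series:
        """Cells mapped per reference cluster."""
        return self.assignments["best_cluster"].value_counts()


def select_mapping_genes(
    query_markers: pd.DataFrame,
    ref_markers: pd.DataFrame,
    query_genes: list[str],
    ref_genes: list[str],
    n_per_group: int = 50,
) -> list[str]:
    """Union of top DE genes per comparison, intersected with both universes.

    Marker tables need columns ``group``, ``gene`` and ``rank`` (1 = best);
    the top ``n_per_group`` genes of every comparison in both tables are
    pooled and restricted to genes present in both datasets. Raises when
    the universes share no genes.
    """
    shared = set(query_genes) & set(ref_genes)
    if not shared:
        raise ValueError("query and reference share no genes")
    pool: set[str] = set()
    for table in (query_markers, ref_markers):
        for col in ("group", "gene", "rank"):
            if col not in table.columns:
                raise KeyError(f"marker table missing column {col!r}")
        top = table[table["rank"] <= n_per_group]
        pool.update(top["gene"].tolist())
    genes = sorted(pool & shared)
    if not genes:
        raise ValueError("no selected marker genes survive the universe intersection")
    return genes


def map_to_nearest_centroid(
    query_expression: pd.DataFrame,
    reference: ReferenceTaxonomy,
    genes: list[str] | None = None,
    metric: str = "pearson",
    query_clusters: pd.Series | np.ndarray | None = None,
) -> MappingResult:
    """Assign every query cell to its nearest reference cluster centroid.

    Similarity is Pearson correlation over the mapping gene set by default
    (Euclidean distance available). Ties are broken by the lower centroid
    id (stable sort order of the centroid index) and logged; a query cell
    that is constant over the gene set has no defined correlation and falls
    back to Euclidean assignment with a warning.
    """
    if metric not in ("pearson", "euclidean"):
        raise ValueError(f"unknown metric {metric!r}")
    genes = list(genes) if genes is not None else [
        g for g in query_expression.columns if g in reference.centroids.columns
    ]
    if len(genes) < 10:
        raise ValueError("mapping gene set must contain at least 10 genes")
    q = query_expression[genes].to_numpy(dtype=float)
    c = reference.centroids.sort_index()[genes].to_numpy(dtype=float)
    ref_ids = reference.centroids.sort_index().index.to_numpy()

    def euclid_best(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d = np.linalg.norm(rows[:, None, :] - c[None, :, :], axis=2)
        best = d.argmin(axis=1)  # argmin takes first (lowest id) on ties
        return best, -d[np.arange(len(rows)), best]

    if metric == "euclidean":
        best, sim = euclid_best(q)
    else:
        qc = q - q.mean(axis=1, keepdims=True)
        cc = c - c.mean(axis=1, keepdims=True)
        qn = np.linalg.norm(qc, axis=1)
        cn = np.linalg.norm(cc, axis=1)
        if (cn == 0).any():
            raise ValueError("reference centroid constant over the mapping gene set")
        const = qn == 0
        r = np.zeros((q.shape[0], c.shape[0]))
        ok = ~const
        if ok.any():
            r[ok] = (qc[ok] @ cc.T) / np.outer(qn[ok], cn)
        best = r.argmax(axis=1)
        sim = r[np.arange(q.shape[0]), best]
        n_ties = int((np.isclose(r, sim[:, None]).sum(axis=1) > 1).sum())
        if n_ties:
            logger.info("%d query cells tied between centroids; lowest id kept", n_ties)
        if const.any():
            logger.warning(
                "%d query cells constant over mapping genes; Euclidean fallback",
                int(const.sum()),
            )
            b2, s2 = euclid_best(q[const])
            best[const] = b2
            sim[const] = s2
    assignments = pd.DataFrame(
        {"best_cluster": ref_ids[best], "similarity": sim},
        index=query_expression.index,
    )
    qc_series = None
    if query_clusters is not None:
        qc_series = pd.Series(np.asarray(query_clusters), index=query_expression.index)
    return MappingResult(assignments=assignments, query_clusters=qc_series, metric=metric)


def filter_low_support(result: MappingResult, min_cells: int = 3) -> MappingResult:
    """Drop low-support clusters from the correspondence, both directions.

    Reference clusters receiving fewer than ``min_cells`` mapped cells are
    removed; if query cluster labels are attached, query clusters whose
    cells fall below ``min_cells`` after that removal are dropped too.
    Idempotent.
    """
    counts = result.assignments["best_cluster"].value_counts()
    kept_ref = counts[counts >= min_cells].index.tolist()
    keep_cell = result.assignments["best_cluster"].isin(kept_ref)
    kept_query = None
    if result.query_clusters is not None:
        qcounts = result.query_clusters[keep_cell].value_counts()
        kept_query = qcounts[qcounts >= min_cells].index.tolist()
        keep_cell &= result.query_clusters.isin(kept_query)
    return MappingResult(
        assignments=result.assignments[keep_cell],
        query_clusters=(
            result.query_clusters[keep_cell]
            if result.query_clusters is not None else None
        ),
        metric=result.metric,
        support_filtered=True,
        kept_query_clusters=kept_query,
        kept_ref_clusters=sorted(kept_ref),
    )


def build_confusion(
    result: MappingResult,
    reference: ReferenceTaxonomy,
    levels: tuple[str, ...] = ("cluster", "supertype", "subclass"),
) -> dict[str, pd.DataFrame]:
    """Confusion matrices of query clusters vs reference hierarchy levels.

    Counts are aggregated up the reference hierarchy; every level's row
    sums equal the per-query-cluster mapped-cell counts.
    """
    if result.query_clusters is None:
        raise ValueError("query cluster labels are required for a confusion matrix")
    mapped = result.assignments["best_cluster"]
    unknown = set(mapped) - set(reference.hierarchy.index)
    if unknown:
        raise KeyError(f"mapped clusters absent from hierarchy: {sorted(unknown)[:5]}")
    out: dict[str, pd.DataFrame] = {}
    for level in levels:
        if level == "cluster":
            target = mapped
        else:
            if level not in reference.hierarchy.columns:
                raise KeyError(f"hierarchy map has no level {level!r}")
            target = mapped.map(reference.hierarchy[level])
        out[level] = pd.crosstab(result.query_clusters, target)
    return out
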