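"""Normalization, dimensionality reduction, graph clustering and 2D embedding.

The taxonomy is built by iterating a standard single-nucleus workflow:
library-size normalization to 10,000 counts and ``log1p``, selection of the
most variable genes by variance-stabilized dispersion, per-gene scaling,
PCA (30 components by default), KNN-graph community detection at a spectrum
of resolutions (0.5, 1, 2, 3) and a UMAP embedding used for visualization
and constellation node placement. Community detection defaults to Leiden
(seeded, reproducible); Louvain is available.

Doublet-like clusters are flagged by detection of mutually incompatible
marker programmes (for example neuronal plus glial markers) within one
cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scanpy as sc
from anndata import AnnData
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingSpace",
    "MultiResolutionClustering",
    "normalize_select_scale",
    "reduce_dimensions",
    "cluster_multiresolution",
    "embed_2d",
    "flag_doublet_clusters",
    "standard_pipeline",
]

DEFAULT_RESOLUTIONS = (0.5, 1.0, 2.0, 3.0)
NORMALIZATION_TARGET = 10_000.0


@dataclass
class EmbeddingSpace:
    """Principal-component coordinates plus the gene set they were built on."""

    pc_coordinates: np.ndarray
    n_components: int
    variable_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.pc_coordinates)):
            raise ValueError("embedding contains non-finite values")


@dataclass
class MultiResolutionClustering:
    """Cluster assignments per resolution (dense integer labels)."""

    resolutions: tuple[float, ...]
    assignments: dict[float, np.ndarray]

    def n_clusters(self, resolution: float) -> int:
        return int(np.unique(self.assignments[resolution]).size)


def normalize_select_scale(
    adata: AnnData, n_variable: int = 2000, target_sum: float = NORMALIZATION_TARGET
) -> AnnData:
    """Normalize, log-transform, pick variable genes, scale them.

    Returns a copy whose ``X`` holds log1p library-size-normalized
    expression over all genes, with ``var['highly_variable']`` marking the
    ``n_variable`` genes ranked by variance-stabilized dispersion and
    ``obsm['X_scaled']`` holding the per-gene centered, unit-variance
    (clipped at 10) matrix over those genes.
    """
    ad = adata.copy()
    ad.layers["counts"] = np.asarray(ad.X).copy()
    if n_variable > ad.n_vars:
        logger.warning(
            "n_variable=%d exceeds gene count %d; clamping", n_variable, ad.n_vars
        )
        n_variable = ad.n_vars
    sc.pp.normalize_total(ad, target_sum=target_sum)
    sc.pp.log1p(ad)
    sc.pp.highly_variable_genes(ad, n_top_genes=n_variable, flavor="seurat")
    hv = ad.var["highly_variable"].to_numpy()
    scaled = sc.pp.scale(np.asarray(ad.X[:, hv]), max_value=10.0, copy=True)
    ad.obsm["X_scaled"] = scaled
    ad.uns["variable_genes"] = ad.var_names[hv].tolist()
    return ad


def reduce_dimensions(
    x: np.ndarray | AnnData, n_components: int = 30,
    variable_genes: list[str] | None = None,
) -> EmbeddingSpace:
    """Project the scaled matrix onto its top principal components.

    Uses a full (deterministic) SVD; components are unique up to sign.
    If the requested component count exceeds the matrix rank budget it is
    clamped with a warning.
    """
    from sklearn.decomposition import PCA

    if isinstance(x, AnnData):
        variable_genes = variable_genes or x.uns.get("variable_genes", [])
        x = x.obsm["X_scaled"]
    x = np.asarray(x, dtype=float)
    max_comp = min(x.shape)
    if n_components > max_comp:
        logger.warning(
            "n_components=%d exceeds min(n_obs, n_vars)=%d; clamping",
            n_components, max_comp,
        )
        n_components = max_comp
    pcs = PCA(n_components=n_components, svd_solver="full").fit_transform(x)
    return EmbeddingSpace(
        pc_coordinates=pcs, n_components=n_components,
        variable_genes=list(variable_genes or []),
    )


def _knn_graph(x: np.ndarray, k_neighbors: int) -> igraph.Graph:
    n = x.shape[0]
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be < n nuclei ({n})")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(x)
    _, idx = nn.kneighbors(x)
    edges = [(i, int(j)) for i in range(n) for j in idx[i, 1:]]
    g = igraph.Graph(n=n, edges=edges, directed=False)
    g.simplify()
    return g


def cluster_multiresolution(
    embedding: EmbeddingSpace,
    k_neighbors: int = 15,
    resolutions: tuple[float, ...] = DEFAULT_RESOLUTIONS,
    seed: int = 0,
    method: str = "leiden",
) -> MultiResolutionClustering:
    """Modularity-based community detection on the KNN graph per resolution."""
    g = _knn_graph(embedding.pc_coordinates, k_neighbors)
    assignments: dict[float, np.ndarray] = {}
    for res in resolutions:
        if method == "leiden":
            part = leidenalg.find_partition(
                g,
                leidenalg.RBConfigurationVertexPartition,
                resolution_parameter=res,
                seed=seed,
                n_iterations=2,
            )
            labels = np.asarray(part.membership)
        elif method == "louvain":
            labels = np.asarray(
                g.community_multilevel(resolution=res).membership
            )
        else:
            raise ValueError(f"unknown method {method!r}")
        # dense relabeling in order of first appearance
        _, dense = np.unique(labels, return_inverse=True)
        assignments[res] = dense
    return MultiResolutionClustering(resolutions=tuple(resolutions),
                                     assignments=assignments)


def embed_2d(embedding: EmbeddingSpace, seed: int = 0,
             n_neighbors: int = 15, min_dist: float = 0.5) -> np.ndarray:
    """Seed-deterministic UMAP of the PC space (visualization only)."""
    import umap

    reducer = umap.UMAP(
        n_components=2, n_neighbors=n_neighbors, min_dist=min_dist,
        random_state=seed,
    )
    return np.asarray(reducer.fit_transform(embedding.pc_coordinates), dtype=float)


def flag_doublet_clusters(
    adata: AnnData,
    cluster_assignment: np.ndarray,
    incompatible_marker_sets: list[list[str]],
    detection_threshold: float = 0.5,
) -> list[object]:
    """Flag clusters co-detecting two or more incompatible marker programmes.

    ``adata.X`` must be (log-)normalized expression; a gene counts as
    detected in a nucleus when its value is positive. A cluster is flagged
    when its mean detection fraction exceeds ``detection_threshold`` in at
    least two of the supplied mutually exclusive marker sets.
    """
    if len(incompatible_marker_sets) < 2:
        raise ValueError("need at least two incompatible marker sets")
    seen: set[str] = set()
    for s in incompatible_marker_sets:
        if seen & set(s):
            raise ValueError("marker sets overlap: " + str(sorted(seen & set(s))))
        seen |= set(s)
    x = np.asarray(adata.X)
    clusters = np.asarray(cluster_assignment)
    idx_sets = []
    for s in incompatible_marker_sets:
        idx = adata.var_names.get_indexer(s)
        if (idx < 0).any():
            missing = [g for g, i in zip(s, idx) if i < 0]
            raise KeyError(f"marker genes absent from matrix: {missing}")
        idx_sets.append(idx)
    flagged = []
    for cid in pd.unique(clusters):
        sel = clusters == cid
        n_hot = sum(
            float((x[np.ix_(sel, idx)] > 0).mean()) > detection_threshold
            for idx in idx_sets
        )
        if n_hot >= 2:
            flagged.append(cid)
    return flagged


def standard_pipeline(
    adata: AnnData,
    n_variable: int = 2000,
    n_components: int = 30,
    k_neighbors: int = 15,
    resolutions: tuple[float, ...] = DEFAULT_RESOLUTIONS,
    seed: int = 0,
    compute_umap: bool = True,
) -> tuple[AnnData, EmbeddingSpace, MultiResolutionClustering]:
    """Convenience chain: normalize -> PCA -> multi-resolution clustering -> UMAP.

    The 2D embedding (if computed) lands in ``adata.obsm['X_umap']`` and the
    per-resolution labels in ``adata.obs['leiden_<res>']``.
    """
    ad = normalize_select_scale(adata, n_variable=n_variable)
    emb = reduce_dimensions(ad, n_components=n_components)
    clustering = cluster_multiresolution(
        emb, k_neighbors=k_neighbors, resolutions=resolutions, seed=seed
    )
    for res, labels in clustering.assignments.items():
        ad.obs[f"leiden_{res:g}"] = pd.Categorical(labels.astype(str))
    if compute_umap:
        ad.obsm["X_umap"] = embed_2d(emb, seed=seed)
    ad.obsm["X_pca"] = emb.pc_coordinates
    return ad, emb, clustering
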