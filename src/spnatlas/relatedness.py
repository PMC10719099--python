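"""Constellation relatedness graphs and per-nucleus KNN heterogeneity scores.

Type relatedness is summarized by pooling, for every nucleus, its 15
nearest neighbors in the reduced (PC) space and tabulating them by type:
row *t* of the fraction matrix is the distribution over types of all
neighbor slots belonging to type *t*'s nuclei, so rows sum to one and the
diagonal is the self-fraction. The constellation graph draws one node per
type (placed at its mean 2D embedding position, area proportional to
``log(n_nuclei)``) and an undirected edge wherever either directed
fraction strictly exceeds the edge threshold (default 5%); the width drawn
at each endpoint is that endpoint's fraction normalized by the global
maximum off-diagonal fraction (which is drawn at 100% of the node width).

The heterogeneity score of a nucleus is its mean Euclidean distance to its
K nearest neighbors (K = 15) in a 100-dimensional reduced space,
Z-standardized over nuclei; high values mark locally heterogeneous
neighborhoods irrespective of type identity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .clustering import EmbeddingSpace

__all__ = [
    "ConstellationGraph",
    "HeterogeneityScore",
    "compute_neighbor_fractions",
    "build_constellation",
    "compute_heterogeneity",
]


def _knn_exclude_self(x: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """k nearest neighbors per row with the query point itself removed.

    Queries k+1 and drops the row's own index wherever it lands (exact
    duplicates can displace it from the zero-distance slot); remaining
    distance ties keep the backend's stable index order.
    """
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
    dist, idx = nn.kneighbors(x)
    n = x.shape[0]
    out_d = np.empty((n, k))
    out_i = np.empty((n, k), dtype=int)
    rows = np.arange(n)
    for i in rows:
        mask = idx[i] != i
        if mask.sum() == k + 1:  # self not in the list at all
            mask[-1] = False
        out_d[i] = dist[i][mask][:k]
        out_i[i] = idx[i][mask][:k]
    return out_d, out_i


@dataclass
class ConstellationNode:
    type_id: object
    centroid_2d: tuple[float, float]
    n_nuclei: int
    area: float  # proportional to log(n_nuclei)


@dataclass
class ConstellationEdge:
    source: object
    target: object
    fraction_source_to_target: float
    fraction_target_to_source: float
    width_at_source: float  # node-width fraction in [0, 1]
    width_at_target: float


@dataclass
class ConstellationGraph:
    nodes: list[ConstellationNode]
    edges: list[ConstellationEdge]
    k_neighbors: int = 15
    edge_threshold: float = 0.05

    def to_json(self) -> str:
        return json.dumps(
            {
                "k_neighbors": self.k_neighbors,
                "edge_threshold": self.edge_threshold,
                "nodes": [asdict(n) for n in self.nodes],
                "edges": [asdict(e) for e in self.edges],
            },
            indent=1,
        )


def compute_neighbor_fractions(
    embedding: EmbeddingSpace | np.ndarray,
    type_assignment: np.ndarray | pd.Series,
    k_neighbors: int = 15,
) -> pd.DataFrame:
    """Types x types matrix of pooled nearest-neighbor fractions.

    For each nucleus its ``k_neighbors`` nearest neighbors (self excluded,
    distance ties broken by stable index order) are tabulated by type; row
    *t* is the distribution of type *t*'s pooled neighbor slots, so every
    row sums to one.
    """
    x = embedding.pc_coordinates if isinstance(embedding, EmbeddingSpace) else np.asarray(embedding)
    labels = np.asarray(type_assignment)
    n = x.shape[0]
    if labels.shape[0] != n:
        raise ValueError("type assignment length does not match embedding rows")
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be < n nuclei ({n})")
    types, inv = np.unique(labels, return_inverse=True)
    if any((inv == t).sum() == 0 for t in range(len(types))):
        raise ValueError("empty type encountered")
    _, neigh = _knn_exclude_self(x, k_neighbors)
    counts = np.zeros((len(types), len(types)), dtype=float)
    neigh_types = inv[neigh]  # n x k
    for t in range(len(types)):
        rows = neigh_types[inv == t].ravel()
        counts[t] = np.bincount(rows, minlength=len(types))
    fractions = counts / counts.sum(axis=1, keepdims=True)
    return pd.DataFrame(fractions, index=types, columns=types)


def build_constellation(
    fractions: pd.DataFrame,
    embedding_2d: np.ndarray,
    type_assignment: np.ndarray | pd.Series,
    edge_threshold: float = 0.05,
    k_neighbors: int = 15,
) -> ConstellationGraph:
    """Assemble the constellation graph from the neighbor-fraction matrix.

    An undirected edge between *a* and *b* exists iff
    ``max(fraction(a->b), fraction(b->a))`` strictly exceeds
    ``edge_threshold``. Drawn widths are fractions normalized by the global
    maximum off-diagonal fraction, clipped to 1, so the strongest directed
    relationship spans 100% of its node's width.
    """
    if not 0.0 < edge_threshold < 1.0:
        raise ValueError("edge_threshold must be in (0, 1)")
    labels = np.asarray(type_assignment)
    xy = np.asarray(embedding_2d, dtype=float)
    if xy.shape[0] != labels.shape[0]:
        raise ValueError("embedding_2d rows do not match type assignment")
    types = fractions.index.tolist()
    nodes = []
    for t in types:
        sel = labels == t
        n_t = int(sel.sum())
        c = xy[sel].mean(axis=0)
        nodes.append(
            ConstellationNode(
                type_id=t, centroid_2d=(float(c[0]), float(c[1])),
                n_nuclei=n_t, area=float(np.log(n_t)),
            )
        )
    f = fractions.to_numpy()
    off = f - np.diag(np.diag(f))
    global_max = off.max()
    edges = []
    for i in range(len(types)):
        for j in range(i + 1, len(types)):
            fij, fji = f[i, j], f[j, i]
            if max(fij, fji) > edge_threshold:
                scale = global_max if global_max > 0 else 1.0
                edges.append(
                    ConstellationEdge(
                        source=types[i], target=types[j],
                        fraction_source_to_target=float(fij),
                        fraction_target_to_source=float(fji),
                        width_at_source=float(min(fij / scale, 1.0)),
                        width_at_target=float(min(fji / scale, 1.0)),
                    )
                )
    return ConstellationGraph(
        nodes=nodes, edges=edges, k_neighbors=k_neighbors,
        edge_threshold=edge_threshold,
    )


@dataclass
class HeterogeneityScore:
    """Raw mean-KNN distances and their Z-standardization."""

    mean_knn_distance: np.ndarray
    z_score: np.ndarray
    k_neighbors: int


def compute_heterogeneity(
    embedding: EmbeddingSpace | np.ndarray, k_neighbors: int = 15
) -> HeterogeneityScore:
    """Z-scored mean distance to the K nearest neighbors per nucleus.

    Computed in the reduced space supplied (conventionally 100 PCs).
    Raises on degenerate data where every nucleus has the same mean
    distance (zero variance leaves the Z-score undefined).
    """
    x = embedding.pc_coordinates if isinstance(embedding, EmbeddingSpace) else np.asarray(embedding, dtype=float)
    n = x.shape[0]
    if n < k_neighbors + 1:
        raise ValueError("need at least k_neighbors + 1 nuclei")
    dist, _ = _knn_exclude_self(x, k_neighbors)
    raw = dist.mean(axis=1)
    sd = raw.std()
    if sd == 0:
        raise ValueError("degenerate data: mean KNN distances have zero variance")
    return HeterogeneityScore(
        mean_knn_distance=raw, z_score=(raw - raw.mean()) / sd,
        k_neighbors=k_neighbors,
    )
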