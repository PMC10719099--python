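"""Type centroids, taxonomy dendrogram, gene-module scores and LIM groups.

The cell-type taxonomy is a three-level hierarchy (division / subclass /
type). Types are characterized by their centroid — the arithmetic mean of
(log-normalized) marker-gene expression over member nuclei — and the tree
over types is built by average-linkage agglomerative clustering on
``1 - Pearson correlation`` between centroids, the common distance for
transcriptomic dendrograms. Type ids are assigned sequentially in tree
leaf order. Divisions come from cutting the first splits of the tree, with
an optional user-supplied override table mirroring curation steps such as
reassigning modulatory types by neurotransmitter identity.

Gene-module scores follow the expression-bin control convention: the mean
expression of a gene set minus the mean of expression-matched control
genes sampled per bin (25 bins, 100 controls per set gene by default).
Five LIM groups partition hindbrain reticulospinal types by their scores
for Lmx1b and the paralogous pairs Lhx2/9, Lhx3/4 and Lhx1/5, with a
combined Lhx1/5+Lhx3/4 group for types whose two leading (positive)
medians are those pairs within a configurable ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

__all__ = [
    "TaxonomyTree",
    "LIMGroupAssignment",
    "LIM_GROUPS",
    "compute_type_centroids",
    "build_taxonomy_tree",
    "score_gene_module",
    "assign_lim_group",
    "assign_divisions",
]

LIM_GROUPS = ("Lmx1b", "Lhx2/9", "Lhx3/4", "Lhx1/5")
COMBINED_GROUP = "Lhx1/5+Lhx3/4"


def compute_type_centroids(
    expression: pd.DataFrame | AnnData,
    type_assignment: np.ndarray | pd.Series,
    marker_genes: list[str] | None = None,
) -> pd.DataFrame:
    """Mean expression per type over the marker-gene panel.

    ``expression`` is nuclei x genes (log-normalized); rows of the result
    are types, columns the marker genes (all genes when omitted).
    """
    if isinstance(expression, AnnData):
        expression = pd.DataFrame(
            np.asarray(expression.X), index=expression.obs_names,
            columns=expression.var_names,
        )
    labels = np.asarray(type_assignment)
    if labels.shape[0] != expression.shape[0]:
        raise ValueError("type assignment length does not match nucleus count")
    if marker_genes is not None:
        missing = [g for g in marker_genes if g not in expression.columns]
        if missing:
            raise KeyError(f"marker genes absent from matrix: {missing[:5]}")
        expression = expression[marker_genes]
    counts = pd.Series(labels).value_counts()
    if (counts == 0).any():
        raise ValueError("empty type encountered")
    return expression.groupby(labels).mean()


@dataclass
class TaxonomyTree:
    """Average-linkage dendrogram over type centroids.

    ``linkage`` is a scipy linkage matrix over ``types`` (input order);
    ``leaf_order`` gives the dendrogram leaf sequence and ``type_ids`` the
    sequential 1-based id of each type in tree order.
    """

    types: list[str]
    linkage: np.ndarray
    leaf_order: list[str]
    type_ids: dict[str, int]

    def to_newick(self) -> str:
        root = hierarchy.to_tree(self.linkage)

        def rec(n, parent_dist: float) -> str:
            if n.is_leaf():
                return f"{self.types[n.id]}:{parent_dist - n.dist:.6g}"
            inner = f"({rec(n.left, n.dist)},{rec(n.right, n.dist)})"
            return f"{inner}:{parent_dist - n.dist:.6g}"

        return f"({rec(root.left, root.dist)},{rec(root.right, root.dist)});"


def build_taxonomy_tree(
    centroids: pd.DataFrame, metric: str = "correlation", linkage_method: str = "average"
) -> TaxonomyTree:
    """Agglomerative dendrogram over type centroids.

    Default distance is ``1 - Pearson correlation`` between centroid rows
    with average linkage; both are pluggable. Deterministic given inputs.
    """
    if centroids.shape[0] < 2:
        raise ValueError("need at least two types to build a tree")
    if centroids.index.duplicated().any():
        raise ValueError("duplicate type ids in centroid matrix")
    d = pdist(centroids.to_numpy(dtype=float), metric=metric)
    z = hierarchy.linkage(d, method=linkage_method)
    leaves = hierarchy.leaves_list(z)
    types = centroids.index.tolist()
    leaf_order = [types[i] for i in leaves]
    return TaxonomyTree(
        types=types,
        linkage=z,
        leaf_order=leaf_order,
        type_ids={t: i + 1 for i, t in enumerate(leaf_order)},
    )


def score_gene_module(
    expression: pd.DataFrame | AnnData,
    gene_set: list[str],
    n_control_bins: int = 25,
    n_control_per_gene: int = 100,
    seed: int = 0,
    control_pool: list[str] | None = None,
) -> np.ndarray:
    """Per-nucleus module score with expression-matched controls.

    Genes are ranked by mean expression and split into ``n_control_bins``
    equal-occupancy bins; for each set gene, ``n_control_per_gene`` control
    genes are drawn (without replacement) from the non-set genes of its
    bin — falling back to the whole bin when the set exhausts it — and the
    score is the mean expression of the set minus the mean expression of
    the pooled controls. Seed-deterministic. ``control_pool`` optionally
    restricts binning and control sampling to an explicit gene universe
    (plus the set genes); genes outside both the set and the pool cannot
    influence the score.
    """
    if isinstance(expression, AnnData):
        expression = pd.DataFrame(
            np.asarray(expression.X), index=expression.obs_names,
            columns=expression.var_names,
        )
    if len(gene_set) == 0:
        raise ValueError("gene_set is empty")
    missing = [g for g in gene_set if g not in expression.columns]
    if missing:
        raise KeyError(f"gene_set members absent from matrix: {missing[:5]}")
    if len(gene_set) > expression.shape[1]:
        raise ValueError("gene_set larger than the available gene pool")
    if control_pool is not None:
        universe = pd.Index(pd.unique(list(control_pool) + list(gene_set)))
        expression = expression[[g for g in expression.columns if g in set(universe)]]
    rng = np.random.default_rng(seed)
    x = expression.to_numpy(dtype=float)
    gene_index = pd.Index(expression.columns)
    means = x.mean(axis=0)
    order = np.argsort(means, kind="stable")
    n_bins = min(n_control_bins, expression.shape[1])
    bins = np.empty(expression.shape[1], dtype=int)
    bins[order] = np.arange(expression.shape[1]) * n_bins // expression.shape[1]

    set_idx = gene_index.get_indexer(gene_set)
    in_set = np.zeros(expression.shape[1], dtype=bool)
    in_set[set_idx] = True
    rank = np.empty(expression.shape[1], dtype=int)
    rank[order] = np.arange(expression.shape[1])
    non_set = np.flatnonzero(~in_set)
    controls: set[int] = set()
    for gi in set_idx:
        same_bin = np.flatnonzero(bins == bins[gi])
        pool = same_bin[~in_set[same_bin]]
        if pool.size == 0 and non_set.size > 0:
            # the set monopolizes this bin: nearest non-set genes by rank
            near = non_set[np.argsort(np.abs(rank[non_set] - rank[gi]), kind="stable")]
            pool = near[:n_control_per_gene]
        elif pool.size == 0:
            pool = same_bin  # gene set covers the whole universe: self-controls
        take = min(n_control_per_gene, pool.size)
        controls.update(rng.choice(pool, size=take, replace=False).tolist())
    ctrl_idx = np.fromiter(controls, dtype=int)
    return x[:, set_idx].mean(axis=1) - x[:, ctrl_idx].mean(axis=1)


@dataclass
class LIMGroupAssignment:
    """Per-type LIM group plus the per-nucleus module scores used."""

    group_of_type: dict[object, str | None]
    nucleus_scores: pd.DataFrame
    combined_ratio: float


def assign_lim_group(
    nucleus_scores: pd.DataFrame,
    type_assignment: np.ndarray | pd.Series,
    combined_ratio: float = 0.75,
) -> LIMGroupAssignment:
    """Assign each type to one of the five LIM groups from module scores.

    ``nucleus_scores`` has one column per base group in :data:`LIM_GROUPS`.
    Per type, the group with the highest median score wins; when the two
    leading medians are Lhx1/5 and Lhx3/4, both positive, and their ratio
    is at least ``combined_ratio``, the type goes to the combined
    Lhx1/5+Lhx3/4 group (a heuristic, flagged in the output). Types with no
    positive median are left unassigned with a warning.
    """
    missing = [g for g in LIM_GROUPS if g not in nucleus_scores.columns]
    if missing:
        raise KeyError(f"score columns missing: {missing}")
    labels = np.asarray(type_assignment)
    if labels.shape[0] != nucleus_scores.shape[0]:
        raise ValueError("type assignment length does not match score rows")
    result: dict[object, str | None] = {}
    for tid in pd.unique(labels):
        med = nucleus_scores.loc[labels == tid, list(LIM_GROUPS)].median()
        ranked = med.sort_values(ascending=False)
        if ranked.iloc[0] <= 0:
            logger.warning("type %r has no positive LIM module score; unassigned", tid)
            result[tid] = None
            continue
        top_two = set(ranked.index[:2])
        if (
            top_two == {"Lhx1/5", "Lhx3/4"}
            and ranked.iloc[1] > 0
            and ranked.iloc[1] / ranked.iloc[0] >= combined_ratio
        ):
            result[tid] = COMBINED_GROUP
        else:
            result[tid] = str(ranked.index[0])
    return LIMGroupAssignment(
        group_of_type=result, nucleus_scores=nucleus_scores,
        combined_ratio=combined_ratio,
    )


def assign_divisions(
    tree: TaxonomyTree, n_divisions: int = 3,
    overrides: dict[str, int] | None = None,
) -> dict[str, int]:
    """Division of each type from the first splits of the taxonomy tree.

    Cuts the dendrogram into ``n_divisions`` groups; ``overrides`` is an
    explicit type -> division table for curation adjustments (for example
    the neurotransmitter-based fine-tuning of the modulatory division).
    Division numbers are renumbered 1..n in tree leaf order.
    """
    raw = hierarchy.fcluster(tree.linkage, t=n_divisions, criterion="maxclust")
    by_type = dict(zip(tree.types, raw.tolist()))
    # renumber in leaf order so division 1 is the leftmost branch
    renumber: dict[int, int] = {}
    for t in tree.leaf_order:
        renumber.setdefault(by_type[t], len(renumber) + 1)
    out = {t: renumber[c] for t, c in by_type.items()}
    if overrides:
        out.update(overrides)
    return out
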