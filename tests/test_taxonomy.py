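"""Centroids, taxonomy tree, module scores and LIM-group assignment."""

import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import squareform

import spnatlas as sa
from spnatlas.taxonomy import COMBINED_GROUP, LIM_GROUPS


def _frame(x, genes=None):
    genes = genes or [f"g{i}" for i in range(np.asarray(x).shape[1])]
    return pd.DataFrame(np.asarray(x, dtype=float),
                        index=[f"n{i}" for i in range(np.asarray(x).shape[0])],
                        columns=genes)


# ---------------------------------------------------------------------------
# centroids
# ---------------------------------------------------------------------------

def test_centroid_of_identical_nuclei_is_the_profile():
    x = _frame(np.tile([1.0, 2.0, 3.0], (4, 1)))
    cent = sa.compute_type_centroids(x, np.repeat("a", 4))
    np.testing.assert_allclose(cent.loc["a"], [1.0, 2.0, 3.0])


def test_centroid_is_arithmetic_mean():
    x = _frame([[0.0], [2.0]])
    cent = sa.compute_type_centroids(x, ["a", "a"])
    assert cent.loc["a", "g0"] == 1.0


def test_centroids_match_brute_force_groupby(rng):
    x = _frame(rng.normal(size=(10, 10)))
    labels = rng.choice(["a", "b", "c"], size=10)
    cent = sa.compute_type_centroids(x, labels)
    for t in np.unique(labels):
        expected = x.to_numpy()[labels == t].mean(axis=0)
        np.testing.assert_allclose(cent.loc[t], expected, atol=1e-14)


# ---------------------------------------------------------------------------
# tree
# ---------------------------------------------------------------------------

def test_identical_centroids_merge_first_at_height_zero():
    cent = pd.DataFrame(
        [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [9.0, 1.0, 4.0]],
        index=["a", "b", "c"],
    )
    tree = sa.build_taxonomy_tree(cent, metric="euclidean")
    first = tree.linkage[0]
    assert {int(first[0]), int(first[1])} == {0, 1}
    assert first[2] == 0.0


def test_nearest_collinear_pair_merges_first():
    cent = pd.DataFrame([[0.0, 0.0], [1.0, 0.0], [11.0, 0.0]],
                        index=["a", "b", "c"])
    tree = sa.build_taxonomy_tree(cent, metric="euclidean")
    assert {int(tree.linkage[0][0]), int(tree.linkage[0][1])} == {0, 1}


def _average_linkage_oracle(dist: np.ndarray):
    """O(n^3) average-linkage agglomeration; returns merge heights."""
    clusters = {i: [i] for i in range(dist.shape[0])}
    heights = []
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters.pop(b)
    return np.array(heights)


def test_tree_agrees_with_average_linkage_oracle(rng):
    cent = pd.DataFrame(rng.normal(size=(6, 8)),
                        index=[f"t{i}" for i in range(6)])
    tree = sa.build_taxonomy_tree(cent)
    d = squareform(
        __import__("scipy.spatial.distance", fromlist=["pdist"]).pdist(
            cent.to_numpy(), metric="correlation"
        )
    )
    np.testing.assert_allclose(
        np.sort(tree.linkage[:, 2]), np.sort(_average_linkage_oracle(d)),
        atol=1e-12,
    )


def test_tree_isomorphic_under_type_permutation(rng):
    cent = pd.DataFrame(rng.normal(size=(8, 12)),
                        index=[f"t{i}" for i in range(8)])
    tree_a = sa.build_taxonomy_tree(cent)
    perm = rng.permutation(8)
    tree_b = sa.build_taxonomy_tree(cent.iloc[perm])
    np.testing.assert_allclose(
        np.sort(tree_a.linkage[:, 2]), np.sort(tree_b.linkage[:, 2]), atol=1e-12
    )
    # same set of leaves adjacent at the first merge
    def first_pair(t):
        i, j = int(t.linkage[0][0]), int(t.linkage[0][1])
        return {t.types[i], t.types[j]}
    assert first_pair(tree_a) == first_pair(tree_b)


def test_newick_export_is_parseable_with_all_leaves(rng):
    cent = pd.DataFrame(rng.normal(size=(5, 6)),
                        index=[f"type_{i}" for i in range(5)])
    tree = sa.build_taxonomy_tree(cent)
    parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick",
                               preserve_underscores=True)
    leaves = {l.taxon.label for l in parsed.leaf_node_iter()}
    assert leaves == set(cent.index)


def test_duplicate_type_ids_rejected():
    cent = pd.DataFrame(np.eye(3), index=["a", "a", "b"])
    with pytest.raises(ValueError, match="duplicate"):
        sa.build_taxonomy_tree(cent)


def test_type_ids_sequential_in_leaf_order(rng):
    cent = pd.DataFrame(rng.normal(size=(7, 9)),
                        index=[f"t{i}" for i in range(7)])
    tree = sa.build_taxonomy_tree(cent)
    assert [tree.type_ids[t] for t in tree.leaf_order] == list(range(1, 8))


def test_divisions_from_first_splits(rng):
    # three well-separated groups of centroids
    cent = pd.DataFrame(
        np.vstack([
            rng.normal(0, 0.1, size=(3, 5)),
            rng.normal(10, 0.1, size=(3, 5)),
            rng.normal(-10, 0.1, size=(2, 5)),
        ]),
        index=[f"t{i}" for i in range(8)],
    )
    tree = sa.build_taxonomy_tree(cent, metric="euclidean")
    div = sa.assign_divisions(tree, n_divisions=3)
    assert set(div.values()) == {1, 2, 3}
    groups = [set(t for t, d in div.items() if d == k) for k in (1, 2, 3)]
    expected = [{"t0", "t1", "t2"}, {"t3", "t4", "t5"}, {"t6", "t7"}]
    assert set(map(frozenset, groups)) == set(map(frozenset, expected))
    # override table wins
    div2 = sa.assign_divisions(tree, n_divisions=3, overrides={"t0": 3})
    assert div2["t0"] == 3


# ---------------------------------------------------------------------------
# module scores
# ---------------------------------------------------------------------------

def test_module_score_self_subtraction_is_zero(rng):
    x = _frame(rng.lognormal(size=(20, 50)))
    s = sa.score_gene_module(x, list(x.columns), n_control_per_gene=100, seed=0)
    np.testing.assert_allclose(s, 0.0, atol=1e-12)


def test_module_score_zero_for_uniform_nucleus(rng):
    x = _frame(rng.lognormal(size=(10, 30)))
    x.iloc[0] = 2.5  # uniform expression across all genes
    s = sa.score_gene_module(x, ["g0", "g5", "g7"], seed=1)
    assert abs(s[0]) < 1e-12


def test_module_score_recovers_planted_programme(rng):
    """A module up-regulated 2x (log scale) in half the nuclei splits on score sign."""
    n, g, msize = 200, 500, 30
    mu = rng.uniform(1.0, 8.0, size=g)
    mu[:msize] = 5.0  # programme genes share a baseline expression level
    x = rng.normal(mu, 0.5, size=(n, g))
    hot = np.arange(n) < n // 2
    x[np.ix_(hot, np.arange(msize))] += np.log(2)
    module = [f"g{i}" for i in range(msize)]
    s = sa.score_gene_module(_frame(x), module, seed=2)
    called_hot = s > 0
    accuracy = max((called_hot == hot).mean(), (called_hot == ~hot).mean())
    assert accuracy >= 0.95


def test_module_score_invariant_to_genes_outside_set_and_pool(rng):
    x = _frame(rng.lognormal(size=(30, 60)))
    module = ["g0", "g1", "g2"]
    pool = [f"g{i}" for i in range(3, 40)]
    s1 = sa.score_gene_module(x, module, control_pool=pool, seed=5)
    extra = _frame(rng.lognormal(size=(30, 10)),
                   genes=[f"extra{i}" for i in range(10)])
    s2 = sa.score_gene_module(pd.concat([x, extra], axis=1), module,
                              control_pool=pool, seed=5)
    np.testing.assert_allclose(s1, s2, atol=1e-12)


def test_module_score_tracks_scanpy_oracle(rng):
    """Independent cross-check against the ecosystem module-score routine."""
    import scanpy as sc
    from anndata import AnnData

    n, g, msize = 200, 500, 30
    mu = rng.uniform(1.0, 8.0, size=g)
    mu[:msize] = 5.0
    x = rng.normal(mu, 0.5, size=(n, g))
    hot = np.arange(n) < n // 2
    x[np.ix_(hot, np.arange(msize))] += np.log(2)
    genes = [f"g{i}" for i in range(g)]
    ours = sa.score_gene_module(_frame(x, genes), genes[:msize], seed=3)
    ad = AnnData(X=x.astype(np.float32),
                 obs=pd.DataFrame(index=[f"n{i}" for i in range(n)]),
                 var=pd.DataFrame(index=genes))
    sc.tl.score_genes(ad, genes[:msize], ctrl_size=100, n_bins=25,
                      score_name="oracle", random_state=0)
    r = np.corrcoef(ours, ad.obs["oracle"])[0, 1]
    assert r > 0.9


def test_module_score_errors():
    x = _frame(np.ones((5, 4)))
    with pytest.raises(ValueError):
        sa.score_gene_module(x, [])
    with pytest.raises(KeyError):
        sa.score_gene_module(x, ["nope"])


# ---------------------------------------------------------------------------
# LIM groups
# ---------------------------------------------------------------------------

def _scores(rows):
    return pd.DataFrame(rows, columns=list(LIM_GROUPS))


def test_exclusive_expression_forces_group():
    scores = _scores([[-.1, 0.8, -.2, -.3]] * 5)
    out = sa.assign_lim_group(scores, np.repeat("t", 5))
    assert out.group_of_type["t"] == "Lhx2/9"


def test_zero_expression_leaves_type_unassigned(caplog):
    scores = _scores([[-.2, -.1, -.4, -.3]] * 4)
    with caplog.at_level("WARNING"):
        out = sa.assign_lim_group(scores, np.repeat("t", 4))
    assert out.group_of_type["t"] is None


def test_combined_group_requires_two_leading_positive_pairs():
    # Lhx1/5 and Lhx3/4 both positive and close -> combined
    close = _scores([[-.5, -.5, 0.72, 0.8]] * 5)
    out = sa.assign_lim_group(close, np.repeat("t", 5))
    assert out.group_of_type["t"] == COMBINED_GROUP
    # ratio below the criterion -> plain argmax
    far = _scores([[-.5, -.5, 0.2, 0.8]] * 5)
    out = sa.assign_lim_group(far, np.repeat("t", 5))
    assert out.group_of_type["t"] == "Lhx1/5"


def test_five_group_synthetic_atlas_fully_recovered(rng):
    """Types planted with group-specific LIM programmes are all recovered."""
    spec = {
        "tA": "Lmx1b", "tB": "Lhx2/9", "tC": "Lhx3/4", "tD": "Lhx1/5",
        "tE": COMBINED_GROUP,
    }
    rows, labels = [], []
    for t, grp in spec.items():
        for _ in range(40):
            base = rng.normal(-0.5, 0.1, size=4)
            if grp == COMBINED_GROUP:
                base[2] = rng.normal(0.8, 0.05)
                base[3] = rng.normal(0.8, 0.05)
            else:
                base[list(LIM_GROUPS).index(grp)] = rng.normal(0.8, 0.05)
            rows.append(base)
            labels.append(t)
    out = sa.assign_lim_group(_scores(rows), np.array(labels))
    assert {t: out.group_of_type[t] for t in spec} == spec
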