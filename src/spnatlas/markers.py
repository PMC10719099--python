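"""Marker/differential-expression calling and projection-proportion tables.

Genes are pre-gated before testing: a gene is tested only if detected in at
least 25% of nuclei in one of the two groups (``min_pct``) and the natural
log fold change between group means (computed on library-normalized means
with a pseudo-count of 1) is at least 0.25 in magnitude. The default test
is a two-part hurdle: a two-proportion z-test on detection plus a
Wilcoxon rank-sum on the positive expression values, combined by
Stouffer's method; a plain rank-sum over all values is available.
Benjamini–Hochberg correction runs over the tested genes of each
comparison, and significance requires adjusted p < 0.05.

Projection proportions tabulate, per type, the cervical- (GFP),
dual- (GFP+/mScarlet+) and lumbar- (mScarlet) projecting composition; the
series scaling helper multiplies per-region counts by the number of
section series (4 when one of four coronal series was quantified) and
reports percentages of the brain-wide total.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "differential_expression",
    "find_all_markers",
    "projection_proportions",
    "scale_series_counts",
]

CHANNEL_TO_TARGET = {"GFP": "cervical", "dual": "dual", "mScarlet": "lumbar"}


def _as_frame(expression) -> pd.DataFrame:
    if isinstance(expression, AnnData):
        return pd.DataFrame(
            np.asarray(expression.X), index=expression.obs_names,
            columns=expression.var_names,
        )
    return expression


def _ranksum_z(a: np.ndarray, b: np.ndarray) -> float | None:
    """Signed normal-approximation rank-sum statistic with tie correction."""
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        return None
    ranks = stats.rankdata(np.concatenate([a, b]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    tie = stats.tiecorrect(ranks)
    sd = np.sqrt(tie * n1 * n2 * (n1 + n2 + 1) / 12.0)
    if sd == 0:
        return None
    return float((u - n1 * n2 / 2.0) / sd)


def _detection_z(k1: int, n1: int, k2: int, n2: int) -> float | None:
    """Two-proportion z statistic on detection counts (pooled variance)."""
    pool = (k1 + k2) / (n1 + n2)
    if pool in (0.0, 1.0):
        return None
    sd = np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
    return float((k1 / n1 - k2 / n2) / sd)


def _gene_p(x1: np.ndarray, x2: np.ndarray, test: str) -> float:
    if test == "wilcoxon":
        z = _ranksum_z(x1, x2)
        return float(2 * stats.norm.sf(abs(z))) if z is not None else 1.0
    # hurdle: detection + positive-part rank-sum, Stouffer-combined
    zs = []
    zd = _detection_z(int((x1 > 0).sum()), len(x1), int((x2 > 0).sum()), len(x2))
    if zd is not None:
        zs.append(zd)
    zc = _ranksum_z(x1[x1 > 0], x2[x2 > 0])
    if zc is not None:
        zs.append(zc)
    if not zs:
        return 1.0
    z = sum(zs) / np.sqrt(len(zs))
    return float(2 * stats.norm.sf(abs(z)))


def differential_expression(
    expression: pd.DataFrame | AnnData,
    group1: np.ndarray | list,
    group2: np.ndarray | list,
    min_pct: float = 0.25,
    logfc_threshold: float = 0.25,
    test: str = "hurdle",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Gated two-group differential expression over log-normalized values.

    ``group1`` / ``group2`` are disjoint row labels (or boolean masks) of
    ``expression``. Returns one row per gene with ``log_fold_change``
    (natural log), detection proportions, raw and BH-adjusted p values
    (NaN for genes excluded by the gates), and the ``significant`` flag.
    """
    if test not in ("hurdle", "wilcoxon"):
        raise ValueError(f"unknown test {test!r}")
    df = _as_frame(expression)

    def rows(sel) -> pd.DataFrame:
        sel = np.asarray(sel)
        if sel.dtype == bool:
            return df.loc[sel]
        return df.loc[sel]

    g1, g2 = rows(group1), rows(group2)
    if g1.empty or g2.empty:
        raise ValueError("both groups must be non-empty")
    overlap = set(g1.index) & set(g2.index)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:5]}")

    x1, x2 = g1.to_numpy(dtype=float), g2.to_numpy(dtype=float)
    pct1 = (x1 > 0).mean(axis=0)
    pct2 = (x2 > 0).mean(axis=0)
    lfc = np.log(np.expm1(x1).mean(axis=0) + 1) - np.log(np.expm1(x2).mean(axis=0) + 1)
    tested = (np.maximum(pct1, pct2) >= min_pct) & (np.abs(lfc) >= logfc_threshold)

    pvals = np.full(df.shape[1], np.nan)
    for j in np.flatnonzero(tested):
        pvals[j] = _gene_p(x1[:, j], x2[:, j], test)
    padj = np.full(df.shape[1], np.nan)
    if tested.any():
        padj[tested] = multipletests(pvals[tested], method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "log_fold_change": lfc,
            "pct_group1": pct1,
            "pct_group2": pct2,
            "tested": tested,
            "p_value": pvals,
            "p_adjusted": padj,
            "significant": tested & (padj < alpha),
        },
        index=df.columns,
    )


def find_all_markers(
    expression: pd.DataFrame | AnnData,
    type_assignment: np.ndarray | pd.Series,
    min_pct: float = 0.25,
    logfc_threshold: float = 0.25,
    test: str = "hurdle",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-vs-rest marker calling per type.

    BH correction runs within each comparison separately. Singleton types
    are skipped with a warning. The result stacks per-type tables with a
    ``group`` column plus a 1-based ``rank`` (by raw p, ties by descending
    fold change) over that group's tested genes.
    """
    df = _as_frame(expression)
    labels = np.asarray(type_assignment)
    if pd.unique(labels).size < 2:
        raise ValueError("need at least two types")
    out = []
    for tid in pd.unique(labels):
        sel = labels == tid
        if sel.sum() < 2:
            logger.warning("type %r has a single nucleus; skipped", tid)
            continue
        res = differential_expression(
            df, sel, ~sel, min_pct=min_pct, logfc_threshold=logfc_threshold,
            test=test, alpha=alpha,
        )
        res = res.reset_index(names="gene")
        res.insert(0, "group", tid)
        order = res[res["tested"]].sort_values(
            ["p_value", "log_fold_change"], ascending=[True, False]
        ).index
        res["rank"] = np.nan
        res.loc[order, "rank"] = np.arange(1, len(order) + 1)
        out.append(res)
    return pd.concat(out, ignore_index=True)


def projection_proportions(
    nucleus_meta: pd.DataFrame,
    type_assignment: np.ndarray | pd.Series | None = None,
    channel_column: str = "sort_channel",
) -> pd.DataFrame:
    """Per-type cervical / dual / lumbar composition from sort channels.

    Sort channels GFP, dual and mScarlet correspond to cervical-, dual- and
    lumbar-projecting nuclei. Returns counts, per-type proportions (summing
    to 1) and the pooled dual-or-lumbar proportion.
    """
    if channel_column not in nucleus_meta:
        raise KeyError(f"metadata lacks {channel_column!r}")
    channels = nucleus_meta[channel_column].astype(str)
    if channels.empty:
        raise ValueError("channel column is empty")
    unknown = set(channels.unique()) - set(CHANNEL_TO_TARGET)
    if unknown:
        raise ValueError(f"unknown sort channel labels: {sorted(unknown)}")
    labels = (
        np.asarray(type_assignment)
        if type_assignment is not None
        else np.zeros(len(nucleus_meta), dtype=int)
    )
    target = channels.map(CHANNEL_TO_TARGET).to_numpy()
    tab = pd.crosstab(labels, target)
    for col in ("cervical", "dual", "lumbar"):
        if col not in tab:
            tab[col] = 0
    tab = tab[["cervical", "dual", "lumbar"]]
    tab.columns = [f"n_{c}" for c in tab.columns]
    totals = tab.sum(axis=1)
    out = tab.copy()
    for c in ("cervical", "dual", "lumbar"):
        out[f"p_{c}"] = tab[f"n_{c}"] / totals
    out["p_dual_or_lumbar"] = out["p_dual"] + out["p_lumbar"]
    out["n_total"] = totals
    return out


def scale_series_counts(
    region_counts: dict | pd.Series, series_multiplier: int = 4
) -> pd.DataFrame:
    """Scale per-region section-series counts to whole-brain totals.

    When only one of N section series was quantified, raw counts are
    multiplied by N (default 4). Percentages are of the brain-wide scaled
    total.
    """
    counts = pd.Series(region_counts, dtype=float)
    if series_multiplier < 1:
        raise ValueError("series_multiplier must be >= 1")
    if (counts < 0).any():
        raise ValueError("negative region counts")
    scaled = counts * series_multiplier
    return pd.DataFrame(
        {
            "raw_count": counts,
            "scaled_total": scaled,
            "percent_of_total": 100.0 * scaled / scaled.sum(),
        }
    )
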