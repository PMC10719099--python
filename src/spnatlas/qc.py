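"""Nucleus quality control and first-/second-order cluster classification.

Retrograde viral labeling marks projection neurons directly (first-order)
but can also label non-projecting cells indirectly. Direct labeling leaves
a strong fluorescent-protein (XFP) transcript signal, so clusters whose
XFP-positive fraction falls below a cutoff (default 10%) are classified as
second-order and can be removed. The per-nucleus QC gate retains nuclei
with strictly less than ``max_mito_fraction`` mitochondrial counts and
strictly more than ``min_genes`` genes detected.

XFP positivity is defined on the *raw* count matrix (a single transcript
suffices), so raw XFP counts travel in the per-nucleus metadata rather
than in the cleaned expression matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData

logger = logging.getLogger(__name__)

__all__ = [
    "QCThresholds",
    "ClusterOrderCall",
    "apply_qc_filter",
    "call_xfp_positive",
    "classify_cluster_order",
    "pool_rois",
]


@dataclass
class QCThresholds:
    max_mito_fraction: float = 0.05
    min_genes: int = 2000
    xfp_cluster_cutoff: float = 0.10

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must be in [0, 1]")
        if not 0.0 < self.xfp_cluster_cutoff < 1.0:
            raise ValueError("xfp_cluster_cutoff must be in (0, 1)")
        if self.min_genes < 0:
            raise ValueError("min_genes must be non-negative")


@dataclass
class ClusterOrderCall:
    """Per-cluster XFP order call (``order`` is 'first' or 'second')."""

    cluster_id: object
    n_nuclei: int
    n_xfp_pos: int
    xfp_fraction: float
    order: str
    override_applied: bool = False
    override_justification: str | None = None


def apply_qc_filter(
    adata: AnnData, thresholds: QCThresholds | None = None
) -> tuple[AnnData, pd.DataFrame]:
    """Retain nuclei passing the mitochondrial-fraction and gene-count gates.

    Both comparisons are strict: a nucleus is kept iff
    ``mito_fraction < max_mito_fraction`` and ``genes_detected > min_genes``.
    Returns the filtered copy and a per-reason removal report.
    """
    t = thresholds or QCThresholds()
    for col in ("mito_fraction", "genes_detected"):
        if col not in adata.obs:
            raise KeyError(f"metadata column {col!r} required for QC")
    mito_ok = adata.obs["mito_fraction"].to_numpy() < t.max_mito_fraction
    genes_ok = adata.obs["genes_detected"].to_numpy() > t.min_genes
    keep = mito_ok & genes_ok
    report = pd.DataFrame(
        {
            "n_input": [adata.n_obs],
            "n_retained": [int(keep.sum())],
            "n_removed_mito": [int((~mito_ok).sum())],
            "n_removed_genes": [int((~genes_ok).sum())],
            "n_removed_total": [int((~keep).sum())],
        }
    )
    if keep.sum() == 0:
        logger.warning("QC filter removed every nucleus")
    return adata[keep].copy(), report


def call_xfp_positive(adata: AnnData, xfp_column: str = "xfp_count") -> np.ndarray:
    """Flag nuclei carrying at least one raw XFP transcript count."""
    if xfp_column not in adata.obs:
        raise KeyError(
            f"metadata column {xfp_column!r} with raw XFP counts is required"
        )
    xfp = adata.obs[xfp_column]
    if xfp.isna().any():
        bad = adata.obs_names[xfp.isna()][0]
        raise ValueError(f"missing xfp_count for nucleus {bad!r}")
    return (xfp.to_numpy() >= 1)


def classify_cluster_order(
    xfp_positive: np.ndarray,
    cluster_assignment: np.ndarray | pd.Series,
    thresholds: QCThresholds | None = None,
    overrides: dict[object, str] | None = None,
) -> list[ClusterOrderCall]:
    """Classify each cluster as first- or second-order from its XFP+ fraction.

    A cluster is second-order iff its XFP-positive fraction is strictly
    below ``xfp_cluster_cutoff`` (a fraction exactly at the cutoff is
    first-order) and the cluster is not in ``overrides``. Overrides are an
    explicit mapping ``cluster_id -> justification string`` for clusters
    kept as first-order despite a sub-cutoff fraction (for example a type
    with independent anatomical evidence of direct projection); each
    applied override is logged.
    """
    t = thresholds or QCThresholds()
    overrides = overrides or {}
    flags = np.asarray(xfp_positive, dtype=bool)
    clusters = np.asarray(cluster_assignment)
    if flags.shape[0] != clusters.shape[0]:
        raise ValueError("xfp_positive and cluster_assignment lengths differ")
    calls: list[ClusterOrderCall] = []
    for cid in pd.unique(clusters):
        sel = clusters == cid
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"cluster {cid!r} is empty")
        n_pos = int(flags[sel].sum())
        frac = n_pos / n
        second = frac < t.xfp_cluster_cutoff
        override = second and cid in overrides
        if override:
            logger.info(
                "override: cluster %r kept first-order at XFP+ fraction %.3f (%s)",
                cid, frac, overrides[cid],
            )
        calls.append(
            ClusterOrderCall(
                cluster_id=cid,
                n_nuclei=n,
                n_xfp_pos=n_pos,
                xfp_fraction=frac,
                order="first" if (not second or override) else "second",
                override_applied=override,
                override_justification=overrides.get(cid) if override else None,
            )
        )
    return calls


def pool_rois(
    roi_labels: np.ndarray | pd.Series, pooling: dict[str, str]
) -> np.ndarray:
    """Map dissection labels onto pooled analysis regions.

    Bordering dissections can be pooled before per-cluster fraction
    computation (for example PONS and MED analysed together as
    'hindbrain'); labels absent from ``pooling`` pass through unchanged.
    """
    arr = np.asarray(roi_labels).astype(object)
    return np.array([pooling.get(x, x) for x in arr], dtype=object)
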