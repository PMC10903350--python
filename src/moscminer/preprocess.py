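"""Per-omics preprocessing: raw inputs to gene-anchored, imputed matrices.

Expression: drop all-zero genes, library-size normalize (scanpy) and log1p.
Methylation: average CpG beta values over promoter-window clusters (TSS
+/- ``window_half``), mean-impute cells with no observed member site, drop
clusters observed nowhere.
Accessibility: sum peak signal overlapping each gene body (any overlap) to a
per-gene activity score.
Finally, min-max normalization rescales expression and accessibility features
to [0, 1] so all omics share the beta-value range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .types import (
    ACCESSIBILITY,
    EXPRESSION,
    METHYLATION,
    GeneAnnotation,
    OmicsMatrix,
    SiteMatrix,
)

logger = logging.getLogger(__name__)

#: Omics whose value range is rescaled to match methylation betas.
MINMAX_KINDS = (EXPRESSION, ACCESSIBILITY)


@dataclass
class PreprocessConfig:
    """Tunable preprocessing constants.

    window_half
        Half-width in bp of the promoter window around the TSS used to
        group CpG sites into a cluster (window = [TSS - w, TSS + w)).
    expr_target_sum
        Library-size normalization target; ``None`` uses the median library
        size across cells.
    minmax_fit
        ``train_only`` fits min/max on training cells inside cross-validation;
        ``all`` fits on the whole dataset.
    """

    window_half: int = 2000
    expr_target_sum: Optional[float] = None
    minmax_fit: str = "train_only"

    def __post_init__(self) -> None:
        if self.window_half <= 0:
            raise ValueError("window_half must be positive")
        if self.minmax_fit not in ("train_only", "all"):
            raise ValueError(f"bad minmax_fit {self.minmax_fit!r}")


@dataclass
class CpGCluster:
    """CpG sites within one gene's promoter window."""

    gene_id: str
    window: tuple[str, int, int]  # chrom, start, end (0-based half-open)
    member_sites: list[int]  # indices into the SiteMatrix site list


# ---------------------------------------------------------------------------
# Expression


def filter_zero_genes(expr: OmicsMatrix) -> OmicsMatrix:
    """Remove genes without a single read count across all cells."""
    if expr.omics_kind != EXPRESSION:
        raise ValueError("filter_zero_genes expects an expression matrix")
    keep = np.flatnonzero((expr.values != 0).any(axis=0))
    if keep.size == 0:
        raise ValueError("empty expression matrix: every gene lacks counts")
    if keep.size < expr.n_features:
        logger.info("dropped %d all-zero genes", expr.n_features - keep.size)
    return expr.subset_features(keep)


def normalize_expression(expr: OmicsMatrix, config: Optional[PreprocessConfig] = None) -> OmicsMatrix:
    """Library-size normalize counts then log1p, via scanpy.

    Each cell's counts are scaled to ``target_sum`` (median library size by
    default), then transformed with log(1 + x).
    """
    import anndata as ad
    import scanpy as sc

    config = config or PreprocessConfig()
    lib = expr.values.sum(axis=1)
    if np.any(lib == 0):
        bad = [expr.cells[i] for i in np.flatnonzero(lib == 0)[:5]]
        raise ValueError(f"cannot normalize cells with zero library size: {bad}")
    adata = ad.AnnData(X=expr.values.copy())
    sc.pp.normalize_total(adata, target_sum=config.expr_target_sum)
    sc.pp.log1p(adata)
    return OmicsMatrix(
        cells=list(expr.cells),
        feature_ids=list(expr.feature_ids),
        anchor_genes=list(expr.anchor_genes),
        values=np.asarray(adata.X, dtype=float),
        omics_kind=EXPRESSION,
    )


# ---------------------------------------------------------------------------
# Methylation


def build_cpg_clusters(
    meth: SiteMatrix, ann: GeneAnnotation, config: Optional[PreprocessConfig] = None
) -> list[CpGCluster]:
    """Group CpG sites into per-gene promoter clusters.

    The window is [TSS - window_half, TSS + window_half), half-open on the
    right; a CpG may join several genes' clusters when windows overlap.
    Genes with no in-window CpG yield no cluster.
    """
    config = config or PreprocessConfig()
    w = config.window_half
    by_chrom: dict[str, list[int]] = {}
    for idx, (chrom, start, _end) in enumerate(meth.sites):
        by_chrom.setdefault(chrom, []).append(idx)
    sorted_pos: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, idxs in by_chrom.items():
        pos = np.array([meth.sites[i][1] for i in idxs])
        order = np.argsort(pos, kind="stable")
        sorted_pos[chrom] = (pos[order], np.array(idxs)[order])

    clusters: list[CpGCluster] = []
    for gene in ann:
        if gene.chrom not in sorted_pos:
            logger.debug("gene %s: chromosome %s has no CpG sites", gene.gene_id, gene.chrom)
            continue
        pos, idxs = sorted_pos[gene.chrom]
        lo, hi = gene.tss - w, gene.tss + w
        a, b = np.searchsorted(pos, [lo, hi], side="left")
        members = sorted(idxs[a:b].tolist())
        if members:
            clusters.append(CpGCluster(gene.gene_id, (gene.chrom, lo, hi), members))
    return clusters


def cluster_methylation(meth: SiteMatrix, clusters: list[CpGCluster]) -> OmicsMatrix:
    """Average observed member betas per cluster per cell, then mean-impute.

    Cells with no observed member site receive the cluster's mean over cells
    where it is observed; clusters unobserved in every cell are eliminated.
    """
    if not clusters:
        raise ValueError("no CpG clusters to aggregate")
    n = len(meth.cells)
    obs_vals = np.where(meth.mask, meth.values, 0.0)
    cols = []
    gene_ids = []
    for cl in clusters:
        m = cl.member_sites
        counts = meth.mask[:, m].sum(axis=1)
        sums = obs_vals[:, m].sum(axis=1)
        observed = counts > 0
        if not observed.any():
            continue
        col = np.zeros(n)
        col[observed] = sums[observed] / counts[observed]
        col[~observed] = col[observed].mean()
        cols.append(col)
        gene_ids.append(cl.gene_id)
    if not cols:
        raise ValueError("all CpG clusters unobserved in every cell")
    values = np.column_stack(cols)
    return OmicsMatrix(
        cells=list(meth.cells),
        feature_ids=list(gene_ids),
        anchor_genes=list(gene_ids),
        values=values,
        omics_kind=METHYLATION,
    )


# ---------------------------------------------------------------------------
# Accessibility


def aggregate_accessibility(acc: SiteMatrix, ann: GeneAnnotation) -> OmicsMatrix:
    """Sum peak signal overlapping each gene body into a gene-activity score.

    A peak contributes when it overlaps the body interval by at least 1 bp.
    Genes without any overlapping peak are dropped.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for idx, (chrom, start, end) in enumerate(acc.sites):
        trees.setdefault(chrom, IntervalTree()).addi(start, end, idx)

    cols = []
    gene_ids = []
    for gene in ann:
        tree = trees.get(gene.chrom)
        if tree is None:
            continue
        hits = sorted(iv.data for iv in tree.overlap(gene.body_start, gene.body_end))
        if not hits:
            continue
        cols.append(acc.values[:, hits].sum(axis=1))
        gene_ids.append(gene.gene_id)
    if not cols:
        raise ValueError("no gene body overlaps any accessibility peak")
    return OmicsMatrix(
        cells=list(acc.cells),
        feature_ids=list(gene_ids),
        anchor_genes=list(gene_ids),
        values=np.column_stack(cols),
        omics_kind=ACCESSIBILITY,
    )


# ---------------------------------------------------------------------------
# Min-max normalization


@dataclass
class MinMaxStats:
    feature_min: np.ndarray
    feature_max: np.ndarray


def minmax_normalize(
    matrix: OmicsMatrix, fit_stats: Optional[MinMaxStats] = None
) -> tuple[OmicsMatrix, MinMaxStats]:
    """Rescale each feature to [0, 1] as (x - min) / (max - min).

    When ``fit_stats`` is supplied (transforming held-out cells with training
    statistics) outputs are clipped to [0, 1]; a constant feature maps to 0.
    """
    clip = fit_stats is not None
    if fit_stats is None:
        fit_stats = MinMaxStats(matrix.values.min(axis=0), matrix.values.max(axis=0))
    span = fit_stats.feature_max - fit_stats.feature_min
    safe = np.where(span > 0, span, 1.0)
    values = (matrix.values - fit_stats.feature_min) / safe
    values[:, span == 0] = 0.0
    if clip:
        values = np.clip(values, 0.0, 1.0)
    out = OmicsMatrix(
        cells=list(matrix.cells),
        feature_ids=list(matrix.feature_ids),
        anchor_genes=list(matrix.anchor_genes),
        values=values,
        omics_kind=matrix.omics_kind,
    )
    return out, fit_stats
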