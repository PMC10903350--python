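"""Synthetic single-cell multi-omics generator with planted subtype markers.

Emulates the statistical shape of joint profiling experiments: negative-
binomial expression counts (overdispersed), beta-distributed CpG methylation
with missing observations, and sparse non-negative accessibility peak counts
inside gene bodies. A configurable subset of genes per omics carries
subtype-shifted signal ("planted markers"), disjoint across omics by
default so that integrating the layers is provably better than any single
one. Every draw derives from one seed, so fixtures are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import preprocess
from .feature_select import align_labels, intersect_by_gene
from .preprocess import PreprocessConfig
from .types import (
    ACCESSIBILITY,
    EXPRESSION,
    METHYLATION,
    GeneAnnotation,
    GeneRecord,
    MultiOmicsDataset,
    OmicsMatrix,
    SiteMatrix,
)

logger = logging.getLogger(__name__)

_CHROM = "chrS"
_GENE_LEN = 10_000
_GENE_SPACING = 30_000  # start-to-start; keeps promoter windows disjoint


@dataclass
class SimulationConfig:
    """Knobs of the generator.

    effect_size is the planted mean shift in units of the within-class SD of
    the affected feature; meth_missing_rate is the per-site per-cell chance
    a beta value is unobserved; expr_dispersion is the negative-binomial
    dispersion (var = mu + dispersion * mu^2).
    """

    n_cells: int = 600
    n_genes: int = 120
    n_subtypes: int = 4
    markers_per_omics: int = 10
    effect_size: float = 3.0
    meth_missing_rate: float = 0.3
    cpgs_per_promoter: int = 12
    peaks_per_gene: int = 3
    expr_dispersion: float = 0.5
    class_proportions: Optional[list[float]] = None
    disjoint_markers: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        needed = self.markers_per_omics * (3 if self.disjoint_markers else 1)
        if needed > self.n_genes:
            raise ValueError(
                f"markers_per_omics={self.markers_per_omics} needs {needed} genes, "
                f"only {self.n_genes} available"
            )
        if self.class_proportions is not None:
            if len(self.class_proportions) != self.n_subtypes:
                raise ValueError("class_proportions length must equal n_subtypes")
            if abs(sum(self.class_proportions) - 1.0) > 1e-8:
                raise ValueError("class_proportions must sum to 1")


def generate_annotation(sim: SimulationConfig) -> GeneAnnotation:
    """Non-overlapping gene bodies on one synthetic chromosome, alternating strands."""
    records = []
    for i in range(sim.n_genes):
        start = 50_000 + i * _GENE_SPACING
        strand = "+" if i % 2 == 0 else "-"
        records.append(GeneRecord(f"gene{i:04d}", _CHROM, strand, start, start + _GENE_LEN))
    return GeneAnnotation(records=records)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial via gamma-Poisson; dispersion 0 degenerates to Poisson."""
    if dispersion <= 0:
        return rng.poisson(mean).astype(float)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam).astype(float)


def generate_multiomics(
    sim: SimulationConfig,
) -> tuple[OmicsMatrix, SiteMatrix, SiteMatrix, dict[str, str], dict]:
    """Generate (expression counts, methylation sites, accessibility peaks, labels, truth).

    Planted marker genes are elevated (expression/accessibility) or
    hyper-methylated in one subtype each, rotating over subtypes, with the
    shift calibrated to ``effect_size`` within-class SDs. The truth record
    lists the planted genes and their target subtype per omics.
    """
    rng = np.random.default_rng(sim.seed)
    ann = generate_annotation(sim)
    genes = [r.gene_id for r in ann]
    n, G, S = sim.n_cells, sim.n_genes, sim.n_subtypes

    props = sim.class_proportions or [1.0 / S] * S
    labels_int = rng.choice(S, size=n, p=props)
    cells = [f"cell{i:04d}" for i in range(n)]
    labels = {c: f"subtype{labels_int[i]}" for i, c in enumerate(cells)}

    # planted marker genes, disjoint across omics when requested
    perm = rng.permutation(G)
    mpo = sim.markers_per_omics
    if sim.disjoint_markers:
        marker_idx = {
            EXPRESSION: perm[:mpo],
            METHYLATION: perm[mpo : 2 * mpo],
            ACCESSIBILITY: perm[2 * mpo : 3 * mpo],
        }
    else:
        marker_idx = {k: perm[:mpo] for k in (EXPRESSION, METHYLATION, ACCESSIBILITY)}
    truth = {
        "genes": {k: [genes[i] for i in idx] for k, idx in marker_idx.items()},
        "target_subtype": {},
    }

    # --- expression: NB counts, marker genes elevated in one rotating subtype.
    # The shift is calibrated on the log1p scale (where the model sees the
    # data): within-class SD there is ~sqrt(log(1 + dispersion + 1/mu)), so a
    # multiplicative shift exp(effect_size * sd_log) plants effect_size
    # within-class SDs in the preprocessed feature.
    base_mu = rng.uniform(5.0, 40.0, size=G)
    mu = np.tile(base_mu, (n, 1))
    for j, gi in enumerate(marker_idx[EXPRESSION]):
        target = j % S
        sd_log = np.sqrt(np.log1p(sim.expr_dispersion + 1.0 / base_mu[gi]))
        mu[labels_int == target, gi] = base_mu[gi] * np.exp(sim.effect_size * sd_log)
        truth["target_subtype"].setdefault(EXPRESSION, {})[genes[gi]] = f"subtype{target}"
    expr_counts = _nb_counts(rng, mu, sim.expr_dispersion)
    expr = OmicsMatrix(
        cells=cells, feature_ids=list(genes), anchor_genes=list(genes),
        values=expr_counts, omics_kind=EXPRESSION,
    )

    # --- methylation: beta-distributed sites in each promoter window.
    # Single-cell CpG calls are near-binary, so site betas are strongly
    # bimodal (low concentration). The planted shift is effect_size SDs of
    # the cluster-mean feature (site SD shrunk by sqrt(observed sites)),
    # directed away from the nearer [0, 1] boundary (hypo- or
    # hyper-methylation) so the effect is not clipped.
    kappa = 1.0  # beta concentration; within-class site SD = sqrt(t(1-t)/(kappa+1))
    sites: list[tuple[str, int, int]] = []
    site_theta = np.zeros((n, 0))
    theta_cols = []
    by_id = ann.by_id()
    meth_markers = set(marker_idx[METHYLATION].tolist())
    for gi, gene in enumerate(genes):
        rec = by_id[gene]
        w = PreprocessConfig().window_half
        pos = np.sort(rng.integers(rec.tss - w, rec.tss + w, size=sim.cpgs_per_promoter))
        base_t = rng.uniform(0.35, 0.65)
        theta = np.full(n, base_t)
        if gi in meth_markers:
            j = list(marker_idx[METHYLATION]).index(gi)
            target = j % S
            site_sd = np.sqrt(base_t * (1 - base_t) / (kappa + 1))
            n_obs = max(sim.cpgs_per_promoter * (1.0 - sim.meth_missing_rate), 1.0)
            direction = 1.0 if base_t <= 0.5 else -1.0
            shifted = np.clip(
                base_t + direction * sim.effect_size * site_sd / np.sqrt(n_obs), 0.02, 0.98
            )
            theta = np.where(labels_int == target, shifted, base_t)
            truth["target_subtype"].setdefault(METHYLATION, {})[gene] = f"subtype{target}"
        for p in pos:
            sites.append((_CHROM, int(p), int(p) + 1))
            theta_cols.append(theta)
    theta_mat = np.column_stack(theta_cols)
    a = theta_mat * kappa
    b = (1 - theta_mat) * kappa
    meth_vals = rng.beta(a, b)
    mask = rng.random(meth_vals.shape) >= sim.meth_missing_rate
    meth = SiteMatrix(
        cells=cells, sites=sites, values=np.where(mask, meth_vals, 0.0),
        mask=mask, omics_kind=METHYLATION,
    )

    # --- accessibility: sparse Poisson peaks in gene bodies
    peak_sites: list[tuple[str, int, int]] = []
    lam_cols = []
    acc_markers = set(marker_idx[ACCESSIBILITY].tolist())
    for gi, gene in enumerate(genes):
        rec = by_id[gene]
        starts = np.sort(
            rng.integers(rec.body_start, rec.body_end - 200, size=sim.peaks_per_gene)
        )
        base_lam = rng.uniform(1.0, 4.0)
        lam = np.full(n, base_lam)
        if gi in acc_markers:
            j = list(marker_idx[ACCESSIBILITY]).index(gi)
            target = j % S
            # calibrate so the per-gene sum shifts by effect_size gene-level SDs
            gene_sd = np.sqrt(sim.peaks_per_gene * base_lam)
            lam = np.where(
                labels_int == target,
                base_lam + sim.effect_size * gene_sd / sim.peaks_per_gene,
                base_lam,
            )
            truth["target_subtype"].setdefault(ACCESSIBILITY, {})[gene] = f"subtype{target}"
        for s in starts:
            peak_sites.append((_CHROM, int(s), int(s) + 200))
            lam_cols.append(lam)
    lam_mat = np.column_stack(lam_cols)
    acc_vals = rng.poisson(lam_mat).astype(float)
    acc = SiteMatrix(
        cells=cells, sites=peak_sites, values=acc_vals,
        mask=np.ones_like(acc_vals, dtype=bool), omics_kind=ACCESSIBILITY,
    )
    return expr, meth, acc, labels, truth


def preprocess_generated(
    expr: OmicsMatrix,
    meth: SiteMatrix,
    acc: SiteMatrix,
    labels: dict[str, str],
    ann: GeneAnnotation,
    config: Optional[PreprocessConfig] = None,
) -> MultiOmicsDataset:
    """Full preprocessing chain: per-omics transforms, gene intersection, labels."""
    config = config or PreprocessConfig()
    expr_g = preprocess.normalize_expression(preprocess.filter_zero_genes(expr), config)
    clusters = preprocess.build_cpg_clusters(meth, ann, config)
    meth_g = preprocess.cluster_methylation(meth, clusters)
    acc_g = preprocess.aggregate_accessibility(acc, ann)
    dataset = intersect_by_gene([expr_g, meth_g, acc_g])
    return align_labels(dataset, labels)


def easy_fixture(seed: int = 0) -> tuple[MultiOmicsDataset, dict]:
    """The canonical separable fixture: 600 cells, 120 genes, 4 subtypes,
    10 disjoint planted markers per omics at effect size 3 SD, fully
    preprocessed. Returns (dataset, truth record)."""
    sim = SimulationConfig(
        n_cells=600, n_genes=120, n_subtypes=4, markers_per_omics=10,
        effect_size=3.0, seed=seed,
    )
    ann = generate_annotation(sim)
    expr, meth, acc, labels, truth = generate_multiomics(sim)
    return preprocess_generated(expr, meth, acc, labels, ann), truth
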