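"""Shared domain containers for gene-anchored single-cell multi-omics data.

All genomic coordinates are 0-based, half-open; format-specific conventions
(GTF 1-based inclusive, BED 0-based half-open) are converted at the parser
boundary and never leak past it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

EXPRESSION = "expression"
METHYLATION = "methylation"
ACCESSIBILITY = "accessibility"

#: Canonical concatenation order of omics layers throughout the package.
OMICS_ORDER = (EXPRESSION, METHYLATION, ACCESSIBILITY)


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    body_start: int  # 0-based inclusive
    body_end: int  # 0-based exclusive

    @property
    def tss(self) -> int:
        """Transcription start site: interval start on '+', interval end on '-'."""
        return self.body_start if self.strand == "+" else self.body_end


@dataclass
class GeneAnnotation:
    """Per-gene strand-aware gene-body intervals anchoring all omics to genes."""

    records: list[GeneRecord]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.gene_id in seen:
                raise ValueError(f"duplicate gene_id {rec.gene_id!r}")
            seen.add(rec.gene_id)
            if rec.body_start >= rec.body_end:
                raise ValueError(
                    f"gene {rec.gene_id!r}: body_start {rec.body_start} >= body_end {rec.body_end}"
                )
            if rec.strand not in ("+", "-"):
                raise ValueError(f"gene {rec.gene_id!r}: unknown strand {rec.strand!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_id(self) -> dict[str, GeneRecord]:
        return {r.gene_id: r for r in self.records}


@dataclass
class SiteMatrix:
    """Cells x genomic-sites value matrix for methylation or accessibility.

    A CpG site is the degenerate interval [start, start+1). ``mask`` marks
    observed entries; it is meaningful for methylation (missing beta values)
    and all-True for accessibility, whose absent entries are true zeros.
    """

    cells: list[str]
    sites: list[tuple[str, int, int]]
    values: np.ndarray  # (n_cells, n_sites) float
    mask: np.ndarray  # (n_cells, n_sites) bool
    omics_kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n, k = len(self.cells), len(self.sites)
        if self.values.shape != (n, k) or self.mask.shape != (n, k):
            raise ValueError(
                f"shape mismatch: {self.values.shape} vs ({n} cells, {k} sites)"
            )
        if self.omics_kind not in (METHYLATION, ACCESSIBILITY):
            raise ValueError(f"bad omics_kind {self.omics_kind!r} for SiteMatrix")
        obs = self.values[self.mask]
        if not np.all(np.isfinite(obs)):
            raise ValueError("non-finite observed values")
        if self.omics_kind == METHYLATION and obs.size:
            if obs.min() < 0 or obs.max() > 1:
                raise ValueError("methylation beta values must lie in [0, 1]")
        if self.omics_kind == ACCESSIBILITY and obs.size and obs.min() < 0:
            raise ValueError("accessibility values must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class OmicsMatrix:
    """Cells x features matrix with every feature anchored to a gene."""

    cells: list[str]
    feature_ids: list[str]
    anchor_genes: list[str]
    values: np.ndarray  # (n_cells, n_features) float
    omics_kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, k = len(self.cells), len(self.feature_ids)
        if len(self.anchor_genes) != k:
            raise ValueError("anchor_genes length must match feature_ids")
        if self.values.shape != (n, k):
            raise ValueError(
                f"shape mismatch: {self.values.shape} vs ({n} cells, {k} features)"
            )
        if len(set(self.feature_ids)) != k:
            raise ValueError("duplicated feature_id")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("OmicsMatrix values must be finite (impute first)")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def subset_features(self, idx: np.ndarray) -> "OmicsMatrix":
        idx = np.asarray(idx)
        return OmicsMatrix(
            cells=list(self.cells),
            feature_ids=[self.feature_ids[i] for i in idx],
            anchor_genes=[self.anchor_genes[i] for i in idx],
            values=self.values[:, idx],
            omics_kind=self.omics_kind,
        )

    def subset_cells(self, idx: np.ndarray) -> "OmicsMatrix":
        idx = np.asarray(idx)
        return OmicsMatrix(
            cells=[self.cells[i] for i in idx],
            feature_ids=list(self.feature_ids),
            anchor_genes=list(self.anchor_genes),
            values=self.values[idx, :],
            omics_kind=self.omics_kind,
        )


@dataclass
class MultiOmicsDataset:
    """Co-indexed OmicsMatrix set over one shared cell list, with optional labels."""

    omics: list[OmicsMatrix]
    labels: Optional[dict[str, str]] = None

    def __post_init__(self) -> None:
        if not self.omics:
            raise ValueError("need at least one omics matrix")
        cells = self.omics[0].cells
        for m in self.omics[1:]:
            if m.cells != cells:
                raise ValueError("omics matrices must share an identical cell ordering")
        if self.labels is not None:
            missing = set(self.labels) - set(cells)
            if missing:
                raise ValueError(f"labels for unknown cells: {sorted(missing)[:5]}")

    @property
    def cells(self) -> list[str]:
        return self.omics[0].cells

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def omics_kinds(self) -> list[str]:
        return [m.omics_kind for m in self.omics]

    def class_inventory(self) -> list[str]:
        if self.labels is None:
            raise ValueError("dataset carries no labels")
        return sorted(set(self.labels.values()))

    def label_array(self) -> np.ndarray:
        """Integer-encoded labels in cell order, indices into class_inventory()."""
        inv = {c: i for i, c in enumerate(self.class_inventory())}
        return np.array([inv[self.labels[c]] for c in self.cells], dtype=int)

    def matrix(self, omics_kind: str) -> OmicsMatrix:
        for m in self.omics:
            if m.omics_kind == omics_kind:
                return m
        raise KeyError(omics_kind)

    def subset_cells(self, idx: np.ndarray) -> "MultiOmicsDataset":
        mats = [m.subset_cells(idx) for m in self.omics]
        labels = None
        if self.labels is not None:
            kept = set(mats[0].cells)
            labels = {c: s for c, s in self.labels.items() if c in kept}
        return MultiOmicsDataset(omics=mats, labels=labels)

    def select_omics(self, kinds: list[str]) -> "MultiOmicsDataset":
        mats = [self.matrix(k) for k in kinds]
        return MultiOmicsDataset(omics=mats, labels=self.labels)


def sort_omics(matrices: list[OmicsMatrix]) -> list[OmicsMatrix]:
    """Order matrices canonically: expression, methylation, accessibility."""
    rank = {k: i for i, k in enumerate(OMICS_ORDER)}
    return sorted(matrices, key=lambda m: rank.get(m.omics_kind, len(rank)))
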