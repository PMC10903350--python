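"""Cross-omics feature selection: keep features whose anchor gene is shared.

A feature survives only if its anchor gene carries a feature in every omics
layer, so the integrated dataset rests on gene-level biological links rather
than unrelated coordinates.
"""

from __future__ import annotations

import logging

import numpy as np

from .types import MultiOmicsDataset, OmicsMatrix, sort_omics

logger = logging.getLogger(__name__)


def intersect_by_gene(matrices: list[OmicsMatrix]) -> MultiOmicsDataset:
    """Retain features anchored to genes present in every omics matrix.

    Matrices are reordered to the canonical omics order and to a shared
    canonical cell ordering (that of the first matrix). One gene may keep
    several features within one omics; duplicates are logged, not collapsed.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    matrices = sort_omics(matrices)
    cell_set = set(matrices[0].cells)
    for m in matrices[1:]:
        if set(m.cells) != cell_set:
            raise ValueError("matrices do not share the same cell set")
    canonical = matrices[0].cells
    aligned = []
    for m in matrices:
        if m.cells != canonical:
            order = {c: i for i, c in enumerate(m.cells)}
            m = m.subset_cells(np.array([order[c] for c in canonical]))
        aligned.append(m)

    common = set(aligned[0].anchor_genes)
    for m in aligned[1:]:
        common &= set(m.anchor_genes)
    if not common:
        raise ValueError("no common genes across omics")

    out = []
    for m in aligned:
        keep = np.flatnonzero(np.isin(m.anchor_genes, sorted(common)))
        kept = m.subset_features(keep)
        n_dup = kept.n_features - len(set(kept.anchor_genes))
        logger.info(
            "%s: kept %d/%d features (%d genes, %d duplicate anchors)",
            m.omics_kind, kept.n_features, m.n_features, len(set(kept.anchor_genes)), n_dup,
        )
        out.append(kept)
    return MultiOmicsDataset(omics=out)


def align_labels(
    dataset: MultiOmicsDataset, labels: dict[str, str], strict: bool = True
) -> MultiOmicsDataset:
    """Attach a cell -> subtype map to the dataset.

    In strict mode every dataset cell must be labeled; labels for unknown
    cells are dropped with a warning in either mode.
    """
    cells = set(dataset.cells)
    unknown = set(labels) - cells
    if unknown:
        logger.warning("ignoring labels for %d unknown cells", len(unknown))
    kept = {c: s for c, s in labels.items() if c in cells}
    if strict:
        missing = sorted(cells - set(kept))
        if missing:
            raise ValueError(f"{len(missing)} cells lack labels, e.g. {missing[:5]}")
    return MultiOmicsDataset(omics=dataset.omics, labels=kept)
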