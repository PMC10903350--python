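"""Readers and writers for annotations, omics matrices, labels and configs.

Supported on-disk formats: Ensembl-dialect GTF and BED6 for gene annotations;
CSV/TSV and MatrixMarket triplets (with ``features.tsv``/``barcodes.tsv``
sidecars) for matrices; 2-column TSV for cell labels; JSON for metrics; YAML
for run configs. Internally every coordinate is 0-based half-open; GTF's
1-based inclusive convention is converted here and nowhere else.

Site identifiers in matrix files are genomic: a CpG site is ``chrom:pos``
(0-based position) and an accessibility peak is ``chrom:start-end``
(0-based half-open).
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path
from typing import Any, Optional, Union

import numpy as np
import pandas as pd
import yaml

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

_GTF_GENE_ID = re.compile(r'gene_id "([^"]+)"')


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Gene annotations


def read_annotation(path: Union[str, Path], format: Optional[str] = None) -> GeneAnnotation:
    """Read a gene annotation from GTF or BED6.

    GTF coordinates (1-based inclusive) are converted to 0-based half-open;
    only ``gene`` features are used and duplicate gene_ids keep the first
    occurrence with a warning. Records with an unknown strand symbol are
    rejected and reported.
    """
    path = Path(path)
    if format is None:
        format = "bed" if path.suffix.lower() == ".bed" else "gtf"
    if format == "gtf":
        return _read_gtf(path)
    if format == "bed":
        return _read_bed(path)
    raise ValueError(f"unknown annotation format {format!r}")


def _read_gtf(path: Path) -> GeneAnnotation:
    records: list[GeneRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "gene":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates {start!r}/{end!r}")
            if strand not in ("+", "-"):
                logger.warning("%s:%d: rejected record with unknown strand %r", path, lineno, strand)
                continue
            m = _GTF_GENE_ID.search(attrs)
            if m is None:
                raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
            gene_id = m.group(1)
            if gene_id in seen:
                logger.warning("%s:%d: duplicate gene_id %r, keeping first", path, lineno, gene_id)
                continue
            seen.add(gene_id)
            # GTF is 1-based inclusive: [start, end] -> 0-based half-open [start-1, end)
            records.append(GeneRecord(gene_id, chrom, strand, start_i - 1, end_i))
    if not records:
        logger.warning("%s: no gene records found", path)
    return GeneAnnotation(records=records)


def _read_bed(path: Path) -> GeneAnnotation:
    records: list[GeneRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: BED6 requires 6 fields, got {len(fields)}")
            chrom, start, end, name, _score, strand = fields[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates {start!r}/{end!r}")
            if strand not in ("+", "-"):
                logger.warning("%s:%d: rejected record with unknown strand %r", path, lineno, strand)
                continue
            if name in seen:
                logger.warning("%s:%d: duplicate gene_id %r, keeping first", path, lineno, name)
                continue
            seen.add(name)
            records.append(GeneRecord(name, chrom, strand, start_i, end_i))
    if not records:
        logger.warning("%s: no gene records found", path)
    return GeneAnnotation(records=records)


def write_annotation_bed(ann: GeneAnnotation, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for r in ann:
            fh.write(f"{r.chrom}\t{r.body_start}\t{r.body_end}\t{r.gene_id}\t0\t{r.strand}\n")


# ---------------------------------------------------------------------------
# Site identifiers


def parse_site_id(site_id: str) -> tuple[str, int, int]:
    """``chr1:123`` -> ('chr1', 123, 124); ``chr1:100-200`` -> ('chr1', 100, 200)."""
    chrom, _, coords = site_id.rpartition(":")
    if not chrom:
        raise ParseError(f"bad site id {site_id!r}")
    if "-" in coords:
        start_s, end_s = coords.split("-", 1)
        start, end = int(start_s), int(end_s)
    else:
        start = int(coords)
        end = start + 1
    if start >= end:
        raise ParseError(f"bad site id {site_id!r}: empty interval")
    return chrom, start, end


def format_site_id(chrom: str, start: int, end: int) -> str:
    if end == start + 1:
        return f"{chrom}:{start}"
    return f"{chrom}:{start}-{end}"


# ---------------------------------------------------------------------------
# Matrices


def read_matrix(
    path: Union[str, Path],
    format: str,
    omics_kind: str,
    cells_in: str = "columns",
    features_path: Optional[Union[str, Path]] = None,
    barcodes_path: Optional[Union[str, Path]] = None,
) -> Union[SiteMatrix, OmicsMatrix]:
    """Read a raw omics matrix.

    Expression matrices come back as gene-anchored :class:`OmicsMatrix`
    (feature == anchor gene); methylation and accessibility come back as
    :class:`SiteMatrix` with coordinates parsed from the site IDs. Empty
    cells in a methylation file are recorded as unobserved in the mask;
    for expression/accessibility they are true zeros.
    """
    path = Path(path)
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        if cells_in == "rows":
            df = df.T
        bad = df.map(lambda v: isinstance(v, str))
        if bad.to_numpy().any():
            i, j = np.argwhere(bad.to_numpy())[0]
            raise ParseError(
                f"{path}: non-numeric cell at feature {df.index[i]!r}, cell {df.columns[j]!r}"
            )
        feature_ids = [str(f) for f in df.index]
        cells = [str(c) for c in df.columns]
        values = df.to_numpy(dtype=float).T  # -> cells x features
    elif format == "mtx_triplet":
        from scipy.io import mmread

        features_path = Path(features_path) if features_path else path.parent / "features.tsv"
        barcodes_path = Path(barcodes_path) if barcodes_path else path.parent / "barcodes.tsv"
        mat = mmread(path).tocsr()  # features x barcodes, cellranger orientation
        feature_ids = [l.split("\t")[0] for l in Path(features_path).read_text().splitlines() if l]
        cells = [l.split("\t")[0] for l in Path(barcodes_path).read_text().splitlines() if l]
        if mat.shape != (len(feature_ids), len(cells)):
            raise ParseError(
                f"{path}: matrix shape {mat.shape} does not match sidecars "
                f"({len(feature_ids)} features, {len(cells)} barcodes)"
            )
        values = np.asarray(mat.todense(), dtype=float).T
    else:
        raise ValueError(f"unknown matrix format {format!r}")

    if omics_kind == EXPRESSION:
        values = np.nan_to_num(values, nan=0.0)
        return OmicsMatrix(
            cells=cells,
            feature_ids=feature_ids,
            anchor_genes=list(feature_ids),
            values=values,
            omics_kind=EXPRESSION,
        )

    sites = [parse_site_id(f) for f in feature_ids]
    if omics_kind == METHYLATION:
        mask = np.isfinite(values)
        values = np.where(mask, values, 0.0)
    elif omics_kind == ACCESSIBILITY:
        values = np.nan_to_num(values, nan=0.0)
        mask = np.ones_like(values, dtype=bool)
    else:
        raise ValueError(f"unknown omics_kind {omics_kind!r}")
    return SiteMatrix(cells=cells, sites=sites, values=values, mask=mask, omics_kind=omics_kind)


_FLOAT_FMT = "%.12g"


def write_raw_matrix(matrix: OmicsMatrix, path: Union[str, Path]) -> None:
    """Raw input-format TSV (features x cells), no anchor column."""
    df = pd.DataFrame(matrix.values.T, index=matrix.feature_ids, columns=matrix.cells)
    df.to_csv(path, sep="\t", index_label="feature_id", float_format=_FLOAT_FMT)


def write_omics_matrix(matrix: OmicsMatrix, path: Union[str, Path]) -> None:
    """Gene-level matrix as TSV: feature_id, anchor_gene, then one column per cell."""
    df = pd.DataFrame(matrix.values.T, index=matrix.feature_ids, columns=matrix.cells)
    df.insert(0, "anchor_gene", matrix.anchor_genes)
    df.to_csv(path, sep="\t", index_label="feature_id", float_format=_FLOAT_FMT)


def read_omics_matrix(path: Union[str, Path], omics_kind: str) -> OmicsMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    anchors = [str(a) for a in df.pop("anchor_gene")]
    return OmicsMatrix(
        cells=[str(c) for c in df.columns],
        feature_ids=[str(f) for f in df.index],
        anchor_genes=anchors,
        values=df.to_numpy(dtype=float).T,
        omics_kind=omics_kind,
    )


def write_site_matrix(matrix: SiteMatrix, path: Union[str, Path]) -> None:
    """Site-level matrix as TSV; unobserved methylation entries are left empty."""
    vals = matrix.values.T.astype(object)
    vals[~matrix.mask.T] = np.nan
    ids = [format_site_id(*s) for s in matrix.sites]
    df = pd.DataFrame(vals, index=ids, columns=matrix.cells)
    df.to_csv(path, sep="\t", index_label="site_id", float_format=_FLOAT_FMT)


def read_site_matrix(path: Union[str, Path], omics_kind: str) -> SiteMatrix:
    out = read_matrix(path, format="tsv", omics_kind=omics_kind)
    assert isinstance(out, SiteMatrix)
    return out


# ---------------------------------------------------------------------------
# Labels, metrics, configs


def read_labels(path: Union[str, Path]) -> dict[str, str]:
    """2-column TSV (cell_id, subtype), with or without a header row."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: label table needs 2 columns")
    if list(df.iloc[0])[:2] == ["cell_id", "subtype"]:
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_labels(labels: dict[str, str], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("cell_id\tsubtype\n")
        for cell, subtype in labels.items():
            fh.write(f"{cell}\t{subtype}\n")


def write_metrics_json(metrics: dict[str, Any], path: Union[str, Path]) -> None:
    def _clean(v):
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, dict):
            return {k: _clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [_clean(x) for x in v]
        return v

    with open(path, "w") as fh:
        json.dump(_clean(metrics), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_metrics_json(path: Union[str, Path]) -> dict[str, Any]:
    with open(path) as fh:
        return json.load(fh)


def read_config_yaml(path: Union[str, Path]) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def write_config_yaml(cfg: dict[str, Any], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def write_outputs(obj: Any, path: Union[str, Path]) -> None:
    """Dispatch writer: matrices to TSV, dicts (metrics/configs) to JSON."""
    if isinstance(obj, OmicsMatrix):
        write_omics_matrix(obj, path)
    elif isinstance(obj, SiteMatrix):
        write_site_matrix(obj, path)
    elif isinstance(obj, GeneAnnotation):
        write_annotation_bed(obj, path)
    elif isinstance(obj, dict):
        write_metrics_json(obj, path)
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    else:
        raise TypeError(f"no writer for {type(obj).__name__}")


def write_dataset(dataset: MultiOmicsDataset, out_dir: Union[str, Path]) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for m in dataset.omics:
        write_omics_matrix(m, out_dir / f"{m.omics_kind}.tsv")
    if dataset.labels is not None:
        write_labels(dataset.labels, out_dir / "labels.tsv")
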