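"""Marker-candidate discovery from learned attention scores.

The top features by mean attention in each omics are candidate subtype
markers; their cross-omics overlap is computed on anchor genes, and a
one-way ANOVA on the normalized abundances checks that each candidate
actually differs between subtypes (raw p < 0.01 by default; no
multiple-testing correction unless requested).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .attention_net import AttentionModelParams, AttentionReport, _validated_views, extract_attention
from .types import MultiOmicsDataset

logger = logging.getLogger(__name__)


@dataclass
class MarkerTable:
    """Ranked marker candidates per omics plus cross-omics gene overlaps."""

    tables: dict[str, pd.DataFrame]  # kind -> [feature_id, anchor_gene, mean_attention, rank]
    overlap: Optional[dict] = None


def rank_markers(report: AttentionReport, top_k: int = 30) -> MarkerTable:
    """Top ``top_k`` features per omics by mean attention.

    Sorting is by descending mean attention with ties broken by feature_id
    lexicographic order; ranks run 1..top_k. If top_k exceeds the feature
    count the full ranking is returned with a warning.
    """
    tables = {}
    for kind in report.omics_kinds:
        mean = report.mean_alpha[kind]
        df = pd.DataFrame(
            {
                "feature_id": report.feature_ids[kind],
                "anchor_gene": report.anchor_genes[kind],
                "mean_attention": mean,
            }
        )
        if top_k > len(df):
            logger.warning("%s: top_k=%d exceeds %d features; returning all", kind, top_k, len(df))
        df = df.sort_values(
            ["mean_attention", "feature_id"], ascending=[False, True], kind="stable"
        ).head(top_k)
        df["rank"] = np.arange(1, len(df) + 1)
        tables[kind] = df.reset_index(drop=True)
    return MarkerTable(tables=tables)


def overlap_markers(table: MarkerTable) -> dict:
    """All 2- and 3-way anchor-gene intersections of the per-omics top lists."""
    gene_sets = {k: set(df["anchor_gene"]) for k, df in table.tables.items()}
    out: dict = {"sets": {k: sorted(v) for k, v in gene_sets.items()}, "intersections": {}}
    kinds = list(gene_sets)
    for r in (2, 3):
        for combo in combinations(kinds, r):
            inter = set.intersection(*(gene_sets[k] for k in combo))
            out["intersections"]["&".join(combo)] = {
                "genes": sorted(inter),
                "count": len(inter),
            }
    return out


def one_way_anova(values: np.ndarray, labels: Sequence) -> tuple[float, float]:
    """Classic one-way ANOVA F and p for one feature across subtype groups.

    F = (SSB / (g-1)) / (SSW / (n-g)) with p from the F distribution.
    Degenerate cases (a single group, no residual degrees of freedom, or
    zero within-variance with equal means) return NaN.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    n, g = len(values), len(groups)
    if g < 2 or any(len(grp) < 1 for grp in groups) or n - g < 1:
        return float("nan"), float("nan")
    grand = values.mean()
    ssb = sum(len(grp) * (grp.mean() - grand) ** 2 for grp in groups)
    ssw = sum(((grp - grp.mean()) ** 2).sum() for grp in groups)
    df_b, df_w = g - 1, n - g
    if ssw == 0:
        if ssb == 0:
            return float("nan"), float("nan")  # all values identical
        return float("inf"), 0.0
    F = (ssb / df_b) / (ssw / df_w)
    p = float(sps.f.sf(F, df_b, df_w))
    return float(F), p


def marker_report(
    dataset: MultiOmicsDataset,
    model: AttentionModelParams,
    top_k: int = 30,
    alpha_threshold: float = 0.01,
    bh_correct: bool = False,
) -> tuple[MarkerTable, pd.DataFrame]:
    """Rank markers, compute overlaps, and ANOVA-test each top feature.

    ANOVA runs on the min-max-normalized abundances of each top feature
    across the labeled subtypes; ``significant`` flags raw p below
    ``alpha_threshold`` (or BH-adjusted p when ``bh_correct``).
    """
    if dataset.labels is None:
        raise ValueError("marker_report requires subtype labels")
    report = extract_attention(model, dataset)
    table = rank_markers(report, top_k=top_k)
    table.overlap = overlap_markers(table)

    X = _validated_views(model, dataset)
    labels = np.array([dataset.labels[c] for c in dataset.cells])
    rows = []
    for kind, df in table.tables.items():
        feat_index = {f: i for i, f in enumerate(model.feature_ids[kind])}
        for _, row in df.iterrows():
            col = X[kind][:, feat_index[row["feature_id"]]]
            F, p = one_way_anova(col, labels)
            rows.append(
                {
                    "omics": kind,
                    "feature_id": row["feature_id"],
                    "anchor_gene": row["anchor_gene"],
                    "rank": row["rank"],
                    "mean_attention": row["mean_attention"],
                    "F": F,
                    "p_value": p,
                }
            )
    anova = pd.DataFrame(rows)
    if bh_correct and len(anova):
        ok = anova["p_value"].notna()
        adj = np.full(len(anova), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = sps.false_discovery_control(anova.loc[ok, "p_value"])
        anova["p_adjusted"] = adj
        anova["significant"] = anova["p_adjusted"] < alpha_threshold
    else:
        anova["significant"] = anova["p_value"] < alpha_threshold
    return table, anova
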