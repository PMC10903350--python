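"""Preprocessing transforms against stated rules and brute-force interval oracles."""

import numpy as np
import pytest

from moscminer import preprocess as pp
from moscminer.types import (
    ACCESSIBILITY,
    EXPRESSION,
    METHYLATION,
    GeneAnnotation,
    GeneRecord,
    OmicsMatrix,
    SiteMatrix,
)


def expr_matrix(values, cells=None, genes=None):
    values = np.asarray(values, dtype=float)
    cells = cells or [f"c{i}" for i in range(values.shape[0])]
    genes = genes or [f"g{j}" for j in range(values.shape[1])]
    return OmicsMatrix(cells=cells, feature_ids=genes, anchor_genes=list(genes),
                       values=values, omics_kind=EXPRESSION)


class TestFilterZeroGenes:
    def test_all_zero_gene_removed(self):
        m = expr_matrix([[0, 1], [0, 0]], genes=["A", "B"])
        out = pp.filter_zero_genes(m)
        assert out.feature_ids == ["B"]
        assert out.cells == m.cells

    def test_identity_when_no_zero_genes(self):
        m = expr_matrix([[1, 2], [3, 0]])
        out = pp.filter_zero_genes(m)
        assert out.feature_ids == m.feature_ids

    def test_single_cell_zero_gene(self):
        m = expr_matrix([[0, 5]], genes=["A", "B"])
        assert pp.filter_zero_genes(m).feature_ids == ["B"]

    def test_empty_result_is_fatal(self):
        with pytest.raises(ValueError, match="empty expression"):
            pp.filter_zero_genes(expr_matrix([[0, 0]]))


class TestNormalizeExpression:
    def test_median_library_target_hand_value(self):
        # libraries 100 and 200 -> median target 150; count 10 in cell 1 ->
        # 10 * 150/100 = 15 -> log1p(15) = 2.7726
        m = expr_matrix([[10, 90], [150, 50]])
        out = pp.normalize_expression(m)
        assert out.values[0, 0] == pytest.approx(np.log1p(15.0), abs=1e-4)
        assert out.values[0, 0] == pytest.approx(2.7726, abs=1e-4)

    def test_equal_libraries_reduce_to_log1p(self):
        m = expr_matrix([[10, 90], [40, 60]])
        out = pp.normalize_expression(m)
        np.testing.assert_allclose(out.values, np.log1p(m.values), atol=1e-6)

    def test_zero_count_stays_zero(self):
        m = expr_matrix([[0, 100], [50, 50]])
        assert pp.normalize_expression(m).values[0, 0] == 0.0

    def test_zero_library_is_fatal(self):
        with pytest.raises(ValueError, match="zero library"):
            pp.normalize_expression(expr_matrix([[0, 0], [1, 2]]))

    def test_fixed_target_sum(self):
        m = expr_matrix([[10, 90]])
        cfg = pp.PreprocessConfig(expr_target_sum=1000.0)
        out = pp.normalize_expression(m, cfg)
        assert out.values[0, 0] == pytest.approx(np.log1p(100.0), abs=1e-4)


def site_matrix(positions, values, mask=None, kind=METHYLATION, chrom="chr1"):
    values = np.asarray(values, dtype=float)
    mask = np.ones_like(values, dtype=bool) if mask is None else np.asarray(mask, bool)
    sites = [(chrom, p, p + 1) for p in positions]
    cells = [f"c{i}" for i in range(values.shape[0])]
    return SiteMatrix(cells=cells, sites=sites, values=np.where(mask, values, 0.0),
                      mask=mask, omics_kind=kind)


def one_gene(tss=10_000, strand="+", chrom="chr1", gid="gA"):
    if strand == "+":
        return GeneAnnotation([GeneRecord(gid, chrom, strand, tss, tss + 5000)])
    return GeneAnnotation([GeneRecord(gid, chrom, strand, tss - 5000, tss)])


class TestCpGClusters:
    def test_window_membership(self):
        meth = site_matrix([8500, 11500, 13000], [[0.1, 0.2, 0.3]])
        clusters = pp.build_cpg_clusters(meth, one_gene(tss=10_000))
        assert len(clusters) == 1
        assert clusters[0].member_sites == [0, 1]

    def test_half_open_boundaries(self):
        meth = site_matrix([8000, 12000], [[0.1, 0.2]])
        clusters = pp.build_cpg_clusters(meth, one_gene(tss=10_000))
        # tss - 2000 included, tss + 2000 excluded
        assert clusters[0].member_sites == [0]

    def test_gene_without_cpgs_yields_no_cluster(self):
        meth = site_matrix([500_000], [[0.5]])
        assert pp.build_cpg_clusters(meth, one_gene(tss=10_000)) == []

    def test_absent_chromosome_skipped(self):
        meth = site_matrix([10_000], [[0.5]], chrom="chr9")
        assert pp.build_cpg_clusters(meth, one_gene(chrom="chr1")) == []

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            n_genes = int(rng.integers(1, 20))
            n_sites = int(rng.integers(1, 200))
            genes = []
            for i in range(n_genes):
                tss = int(rng.integers(0, 50_000))
                strand = "+" if rng.random() < 0.5 else "-"
                if strand == "+":
                    genes.append(GeneRecord(f"g{i}", "chr1", "+", tss, tss + 1000))
                else:
                    genes.append(GeneRecord(f"g{i}", "chr1", "-", max(tss - 1000, 0), max(tss, 1)))
            ann = GeneAnnotation(genes)
            pos = rng.integers(0, 50_000, n_sites).tolist()
            meth = site_matrix(pos, rng.random((2, n_sites)))
            got = {c.gene_id: set(c.member_sites) for c in pp.build_cpg_clusters(meth, ann)}
            expected = {}
            for g in genes:
                members = {j for j, p in enumerate(pos) if g.tss - 2000 <= p < g.tss + 2000}
                if members:
                    expected[g.gene_id] = members
            assert got == expected


class TestClusterMethylation:
    def test_mean_of_observed_members(self):
        meth = site_matrix([9000, 9100], [[0.2, 0.8]])
        clusters = pp.build_cpg_clusters(meth, one_gene(tss=10_000))
        out = pp.cluster_methylation(meth, clusters)
        assert out.values[0, 0] == pytest.approx(0.5)

    def test_mean_imputation_with_single_observation(self):
        meth = site_matrix([9000], [[0.2], [0.0]], mask=[[True], [False]])
        clusters = pp.build_cpg_clusters(meth, one_gene(tss=10_000))
        out = pp.cluster_methylation(meth, clusters)
        assert out.values[1, 0] == pytest.approx(0.2)

    def test_fully_unobserved_cluster_dropped(self):
        meth = site_matrix([9000, 30_000], [[0.0, 0.4], [0.0, 0.6]],
                           mask=[[False, True], [False, True]])
        ann = GeneAnnotation([
            GeneRecord("gA", "chr1", "+", 10_000, 12_000),
            GeneRecord("gB", "chr1", "+", 30_000, 32_000),
        ])
        clusters = pp.build_cpg_clusters(meth, ann)
        out = pp.cluster_methylation(meth, clusters)
        assert out.feature_ids == ["gB"]

    def test_output_has_no_missing_and_stays_in_unit_interval(self):
        rng = np.random.default_rng(31)
        pos = rng.integers(8000, 12_000, 40).tolist()
        vals = rng.random((30, 40))
        mask = rng.random((30, 40)) > 0.5
        meth = site_matrix(pos, vals, mask=mask)
        clusters = pp.build_cpg_clusters(meth, one_gene(tss=10_000))
        out = pp.cluster_methylation(meth, clusters)
        assert np.isfinite(out.values).all()
        assert out.values.min() >= 0 and out.values.max() <= 1


class TestAggregateAccessibility:
    def test_overlap_sum(self):
        acc = SiteMatrix(
            cells=["c1"],
            sites=[("chr1", 1500, 1600), ("chr1", 1800, 1900), ("chr1", 2500, 2600)],
            values=np.array([[3.0, 2.0, 7.0]]),
            mask=np.ones((1, 3), bool),
            omics_kind=ACCESSIBILITY,
        )
        ann = GeneAnnotation([GeneRecord("gA", "chr1", "+", 1000, 2000)])
        out = pp.aggregate_accessibility(acc, ann)
        assert out.values[0, 0] == 5.0

    def test_gene_without_peaks_absent(self):
        acc = SiteMatrix(cells=["c1"], sites=[("chr1", 9000, 9100)],
                         values=np.array([[1.0]]), mask=np.ones((1, 1), bool),
                         omics_kind=ACCESSIBILITY)
        ann = GeneAnnotation([
            GeneRecord("gA", "chr1", "+", 1000, 2000),
            GeneRecord("gB", "chr1", "+", 8500, 9500),
        ])
        out = pp.aggregate_accessibility(acc, ann)
        assert out.feature_ids == ["gB"]

    def test_matches_bruteforce_overlap_sum(self):
        rng = np.random.default_rng(41)
        for _ in range(50):
            n_genes = int(rng.integers(1, 15))
            n_peaks = int(rng.integers(1, 100))
            genes = []
            for i in range(n_genes):
                s = int(rng.integers(0, 40_000))
                genes.append(GeneRecord(f"g{i}", "chr1", "+", s, s + int(rng.integers(500, 5000))))
            ann = GeneAnnotation(genes)
            starts = rng.integers(0, 45_000, n_peaks)
            ends = starts + rng.integers(50, 800, n_peaks)
            vals = rng.poisson(2.0, (3, n_peaks)).astype(float)
            acc = SiteMatrix(
                cells=["a", "b", "c"],
                sites=[("chr1", int(s), int(e)) for s, e in zip(starts, ends)],
                values=vals, mask=np.ones_like(vals, bool), omics_kind=ACCESSIBILITY,
            )
            expected = {}
            for g in genes:
                hits = [j for j in range(n_peaks)
                        if starts[j] < g.body_end and ends[j] > g.body_start]
                if hits:
                    expected[g.gene_id] = vals[:, hits].sum(axis=1)
            if not expected:
                with pytest.raises(ValueError, match="no gene body overlaps"):
                    pp.aggregate_accessibility(acc, ann)
                continue
            out = pp.aggregate_accessibility(acc, ann)
            got = dict(zip(out.feature_ids, out.values.T))
            assert set(got) == set(expected)
            for gid, exp in expected.items():
                np.testing.assert_allclose(got[gid], exp)


class TestMinMax:
    def test_closed_form(self):
        m = expr_matrix([[2], [4], [6]])
        out, _ = pp.minmax_normalize(m)
        np.testing.assert_allclose(out.values[:, 0], [0, 0.5, 1])

    def test_constant_feature_maps_to_zero(self):
        m = expr_matrix([[5], [5]])
        out, _ = pp.minmax_normalize(m)
        np.testing.assert_array_equal(out.values, 0.0)

    def test_test_values_clipped_with_train_stats(self):
        train = expr_matrix([[0], [10]])
        _, stats = pp.minmax_normalize(train)
        test = expr_matrix([[20], [-5]])
        out, _ = pp.minmax_normalize(test, fit_stats=stats)
        np.testing.assert_allclose(out.values[:, 0], [1.0, 0.0])

    def test_fitting_split_lands_in_unit_interval(self):
        rng = np.random.default_rng(51)
        m = expr_matrix(rng.normal(3, 10, (20, 6)))
        out, _ = pp.minmax_normalize(m)
        assert out.values.min() >= 0 and out.values.max() <= 1


def test_pipeline_is_deterministic():
    """Identical raw inputs produce bitwise-identical preprocessed outputs."""
    from moscminer.synthetic_data import SimulationConfig, generate_annotation, generate_multiomics, preprocess_generated

    sim = SimulationConfig(n_cells=40, n_genes=12, n_subtypes=2, markers_per_omics=2, seed=9)
    ann = generate_annotation(sim)
    a = preprocess_generated(*generate_multiomics(sim)[:4], ann)
    b = preprocess_generated(*generate_multiomics(sim)[:4], ann)
    for ma, mb in zip(a.omics, b.omics):
        np.testing.assert_array_equal(ma.values, mb.values)
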