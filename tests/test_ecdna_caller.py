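"""ecDNA caller: binning, reference peak, candidate logic, TSS filter, merge."""

import numpy as np
import pandas as pd
import pytest

from linehet import ecdna_caller as ec
from linehet.io_formats import FragmentSet, GeneModels, midpoints_in_tss_windows


def frags_of(rows, sizes):
    return FragmentSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "barcode", "dup_count"]),
        sizes,
    )


def matrix_of(relative, chrom="chr1", bin_size=100_000):
    """Bin-coverage matrix with prescribed relative coverage (reference 1)."""
    relative = np.asarray(relative, dtype=float)
    n_cells, n_bins = relative.shape
    bins = pd.DataFrame(
        {"chrom": chrom, "start": np.arange(n_bins) * bin_size,
         "end": (np.arange(n_bins) + 1) * bin_size}
    )
    m = ec.BinCoverageMatrix(
        bins, relative.copy(),
        np.array([f"b{i:03d}" for i in range(n_cells)], dtype=object),
    )
    m.reference = np.ones(n_cells)
    m.relative = relative
    return m


class TestBinCoverage:
    def test_partial_last_bin(self):
        fs = frags_of([("chr1", 10, 160, "A", 1)], {"chr1": 250_000})
        m = ec.bin_coverage(fs)
        assert len(m.bins) == 3
        assert m.bins["end"].iloc[-1] == 250_000

    def test_chr21_bin_count(self):
        fs = frags_of([("chr21", 10, 160, "A", 1)], {"chr21": 46_709_983})
        m = ec.bin_coverage(fs)
        assert len(m.bins) == 468  # ceil(46,709,983 / 1e5)

    def test_normalized_formula(self):
        rows = [("chr1", 100, 250, "A", 1)] * 30  # 30 fragments in bin 0
        rows += [("chr1", 150_000 + i, 150_150 + i, "A", 1) for i in range(9_970)]
        fs = frags_of(rows, {"chr1": 1_000_000})
        m = ec.bin_coverage(fs)
        assert m.normalized[0, 0] == pytest.approx(30 / 10_000 * 10_000)

    def test_per_chromosome_sum_is_ten_thousand(self, ecdna_bench):
        m = ecdna_bench["matrix"]
        chroms = m.bins["chrom"].to_numpy()
        for c in np.unique(chroms):
            sums = m.normalized[:, chroms == c].sum(axis=1)
            has_frags = sums > 0
            np.testing.assert_allclose(sums[has_frags], 10_000.0, atol=1e-8)


class TestReferenceCoverage:
    def test_constant_coverage_returns_constant(self):
        v = np.full(100, 7.0)
        assert ec.reference_coverage(v) == pytest.approx(7.0)

    def test_unimodal_sample(self, rng):
        v = np.clip(rng.normal(4.0, 0.5, 400), 0.1, None)
        assert ec.reference_coverage(v) == pytest.approx(4.0, rel=0.1)

    def test_bimodal_takes_lowest_mode(self, rng):
        v = np.r_[rng.normal(5.0, 0.3, 300), rng.normal(10.0, 0.3, 150)]
        assert ec.reference_coverage(v) == pytest.approx(5.0, rel=0.1)

    def test_too_few_bins_is_nan(self):
        assert np.isnan(ec.reference_coverage(np.full(10, 3.0)))


class TestCandidateFragments:
    def test_threshold_and_cell_count(self):
        rel = np.ones((40, 5))
        rel[:20, 2] = 6.5  # 20 cells high in bin 2 -> retained (> 15 cells)
        rel[:10, 4] = 6.5  # only 10 cells -> dropped
        cands = ec.candidate_fragments(matrix_of(rel))
        assert len(cands) == 1
        assert list(cands[0].bin_indices) == [2]

    def test_strict_threshold_excludes_marginal_coverage(self):
        rel = np.full((40, 5), 5.9)
        assert ec.candidate_fragments(matrix_of(rel)) == []
        rel6 = np.full((40, 5), 6.0)
        assert ec.candidate_fragments(matrix_of(rel6)) == []  # strict ">"

    def test_consecutive_bins_merge(self):
        rel = np.ones((40, 50))
        for b in (10, 11, 12, 40):
            rel[:20, b] = 8.0
        cands = ec.candidate_fragments(matrix_of(rel))
        assert [list(c.bin_indices) for c in cands] == [[10, 11, 12], [40]]

    def test_chromosome_boundary_not_merged(self):
        rel = np.ones((40, 6))
        rel[:20, 2] = 8.0
        rel[:20, 3] = 8.0
        m = matrix_of(rel)
        m.bins.loc[3:, "chrom"] = "chr2"  # bins 3..5 on another chromosome
        cands = ec.candidate_fragments(m)
        assert len(cands) == 2


class TestTssFilter:
    def make_gene_models(self, tss_positions):
        return GeneModels(
            pd.DataFrame(
                {"gene_id": [f"g{i}" for i in range(len(tss_positions))],
                 "chrom": "chr1", "start": tss_positions,
                 "end": [t + 500 for t in tss_positions], "strand": "+"}
            )
        )

    def place(self, mids, barcode="b000"):
        return [("chr1", m - 75, m + 75, barcode, 1) for m in mids]

    def test_score_arithmetic_kept_and_removed(self):
        """5 of 100 mids inner -> 0.05 kept; 30 of 100 -> 0.3 removed."""
        tss = 50_000
        gm = self.make_gene_models([tss])
        rel = np.ones((40, 2))
        rel[:20, 0] = 8.0
        m = matrix_of(rel)

        def run(n_inner):
            mids = [tss + i for i in range(-25, -25 + n_inner)]  # inside ±50
            mids += [tss + 300 + 7 * i for i in range(100 - n_inner)]  # outer only
            fs = frags_of(self.place(mids), {"chr1": 200_000})
            cands = ec.candidate_fragments(m)
            out = ec.tss_filter(cands, fs, gm, m)
            return cands[0].tss_score, out

        score, kept = run(5)
        assert score == pytest.approx(0.05)
        assert len(kept) == 1
        score, kept = run(30)
        assert score == pytest.approx(0.30)
        assert kept == []

    def test_region_without_tss_scores_zero(self):
        gm = self.make_gene_models([150_000])  # TSS outside candidate bin 0
        rel = np.ones((40, 2))
        rel[:20, 0] = 8.0
        fs = frags_of(self.place([10_000, 20_000, 30_000]), {"chr1": 200_000})
        m = matrix_of(rel)
        cands = ec.candidate_fragments(m)
        out = ec.tss_filter(cands, fs, gm, m)
        assert out[0].tss_score == 0.0

    def test_matches_bruteforce_overlap_oracle(self, rng):
        """Window counting equals a per-fragment brute-force midpoint check
        on 1,000 random fragments."""
        sizes = {"chr1": 500_000}
        tss_pos = sorted(rng.choice(400_000, 25, replace=False) + 50_000)
        gm = self.make_gene_models(tss_pos)
        starts = rng.integers(0, 499_800, 1000)
        fs = frags_of(
            [("chr1", s, s + 150, "b000", 1) for s in starts], sizes
        )
        rel = np.ones((40, 5))
        rel[:20, :] = 8.0  # one candidate spanning all bins
        m = matrix_of(rel)
        cands = ec.candidate_fragments(m)
        assert len(cands) == 1
        ec.tss_filter(cands, fs, gm, m)

        mids = sorted((s + s + 150) // 2 for s in starts)
        c = cands[0]
        tss_in = [t for t in tss_pos if c.start <= t < c.end]

        def brute(half):
            return sum(
                1 for mid in mids
                if c.start <= mid < c.end
                and any(t - half <= mid <= t + half for t in tss_in)
            )

        expected = brute(50) / brute(2000)
        assert c.tss_score == pytest.approx(expected, abs=1e-12)


class TestMergeCorrelated:
    def two_fragment_matrix(self, rng, same_chrom=True, correlated=True):
        n = 200
        carrier = rng.random(n) < 0.4
        rel = np.ones((n, 12))
        a = 8.0 + rng.normal(0, 0.5, carrier.sum())
        b = a + rng.normal(0, 0.5, carrier.sum()) if correlated else (
            8.0 + rng.normal(0, 0.5, carrier.sum())
        )
        rel[carrier, 2] = a
        rel[carrier, 4] = b
        if not correlated:
            other = rng.random(n) < 0.4
            rel[:, 4] = 1.0
            rel[other, 4] = 8.0 + rng.normal(0, 0.5, other.sum())
        m = matrix_of(rel)
        if not same_chrom:
            m.bins.loc[4:, "chrom"] = "chr2"
        return m

    def test_nearby_correlated_fragments_merge(self, rng):
        m = self.two_fragment_matrix(rng)
        cands = ec.candidate_fragments(m)
        assert len(cands) == 2
        for c in cands:
            c.tss_score = 0.0
        regions = ec.merge_correlated(cands, m)
        assert len(regions) == 1
        assert regions[0].merged_from != []
        assert (regions[0].start, regions[0].end) == (200_000, 500_000)

    def test_different_chromosomes_never_merge(self, rng):
        m = self.two_fragment_matrix(rng, same_chrom=False)
        cands = ec.candidate_fragments(m)
        for c in cands:
            c.tss_score = 0.0
        regions = ec.merge_correlated(cands, m)
        assert len(regions) == 2
        assert all(r.merged_from == [] for r in regions)

    def test_uncorrelated_fragments_stay_separate(self, rng):
        m = self.two_fragment_matrix(rng, correlated=False)
        cands = ec.candidate_fragments(m)
        for c in cands:
            c.tss_score = 0.0
        regions = ec.merge_correlated(cands, m)
        assert len(regions) == 2

    def test_single_fragment_passes_through(self, rng):
        rel = np.ones((100, 5))
        rel[:40, 2] = 8.0
        cands = ec.candidate_fragments(matrix_of(rel))
        cands[0].tss_score = 0.1
        regions = ec.merge_correlated(cands, matrix_of(rel))
        assert len(regions) == 1
        assert regions[0].tss_score == 0.1

    def test_dropout_amplicon_two_fragments_one_region(self, atac_dropout):
        """A zeroed middle bin yields 2 candidate fragments pre-merge and
        exactly one region after correlation merging."""
        m = atac_dropout["matrix"]
        params = atac_dropout["params"]
        cands = ec.candidate_fragments(m, params)
        assert len(cands) >= 2
        cands = ec.tss_filter(
            cands, atac_dropout["fragments"], atac_dropout["gene_models"], m, params
        )
        regions = ec.merge_correlated(
            cands, m, params, atac_dropout["fragments"], atac_dropout["gene_models"]
        )
        assert len(regions) == 1
        assert regions[0].start == 5_000_000 and regions[0].end == 5_500_000


class TestEndToEnd:
    def test_benchmark_recovery(self, ecdna_bench):
        assert ecdna_bench["n_recovered"] == ecdna_bench["n_true_amplicons"] == 3
        assert ecdna_bench["n_false_cnv"] == 0
        assert ecdna_bench["n_false_control"] == 0
        assert ecdna_bench["n_false_background"] == 0

    def test_emitted_regions_satisfy_thresholds(self, ecdna_bench):
        params = ecdna_bench["params"]
        for r in ecdna_bench["regions"]:
            assert r.tss_score < params.tss_max
            assert len(r.supporting_cells) > params.min_cells

    def test_supporting_cells_match_truth(self, ecdna_bench):
        truth = ecdna_bench["truth"]
        for r in ecdna_bench["regions"]:
            spec = next(
                row for _, row in truth.ecdna_regions.iterrows()
                if row["chrom"] == r.chrom and row["start"] < r.end
                and r.start < row["end"]
            )
            true_cells = set(truth.ecdna_cells[spec["name"]])
            called = set(r.supporting_cells.index)
            jacc = len(called & true_cells) / len(called | true_cells)
            assert jacc > 0.8

    def test_record_order_invariance(self, atac_dropout):
        frags = atac_dropout["fragments"]
        rng = np.random.default_rng(5)
        shuffled = FragmentSet(
            frags.records.sample(frac=1.0, random_state=7), dict(frags.chrom_sizes)
        )
        params = atac_dropout["params"]
        gm = atac_dropout["gene_models"]
        r1, _ = ec.call_ecdna(frags, gm, params)
        r2, _ = ec.call_ecdna(shuffled, gm, params)
        assert [(r.chrom, r.start, r.end) for r in r1] == [
            (r.chrom, r.start, r.end) for r in r2
        ]


class TestRegionStatistics:
    def test_oncogene_enrichment_worked_example(self, rng):
        # 20-gene universe with 5 oncogenes; the region holds 4, all oncogenes
        genes = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(20)], "chrom": "chr1",
             "start": np.arange(20) * 100_000 + 10_000,
             "end": np.arange(20) * 100_000 + 12_000, "strand": "+"}
        )
        gm = GeneModels(genes)
        rel = np.ones((100, 20))
        rel[:40, 0:4] = 8.0
        m = matrix_of(rel)
        cands = ec.candidate_fragments(m)
        for c in cands:
            c.tss_score = 0.0
        regions = ec.merge_correlated(cands, m)
        report = ec.region_statistics(
            regions, m, gm, oncogene_list=[f"g{i}" for i in range(4)] + ["g10"]
        )
        assert report["oncogene_p"][0] == pytest.approx(5 / 4845)
        assert regions[0].contains_oncogene

    def test_constant_coverage_spearman_missing(self, rng):
        from linehet.io_formats import CountMatrix
        import scipy.sparse as sp

        genes = pd.DataFrame(
            {"gene_id": ["g0"], "chrom": "chr1", "start": [10_000],
             "end": [20_000], "strand": "+"}
        )
        rel = np.ones((100, 3))
        rel[:40, 0] = 8.0
        m = matrix_of(rel)
        cands = ec.candidate_fragments(m)
        cands[0].tss_score = 0.0
        regions = ec.merge_correlated(cands, m)
        # region coverage is 8.0 in every supporting cell -> no rank spread
        rna = CountMatrix(
            sp.csr_matrix(rng.poisson(5.0, (40, 1))),
            m.cell_ids[:40], np.array(["g0"], dtype=object),
        )
        report = ec.region_statistics(regions, m, GeneModels(genes), counts_rna=rna)
        assert "expression_spearman" not in report.columns or report[
            "expression_spearman"
        ].isna().all()

    def test_expression_coupled_amplicon_high_spearman(self, rng):
        from linehet.io_formats import CountMatrix
        import scipy.sparse as sp

        genes = pd.DataFrame(
            {"gene_id": ["g0"], "chrom": "chr1", "start": [10_000],
             "end": [20_000], "strand": "+"}
        )
        n = 200
        dosage = np.where(rng.random(n) < 0.4, rng.uniform(7, 12, n), 1.0)
        rel = np.ones((n, 3))
        rel[:, 0] = dosage
        m = matrix_of(rel)
        cands = ec.candidate_fragments(m)
        cands[0].tss_score = 0.0
        regions = ec.merge_correlated(cands, m)
        expr = rng.poisson(5.0 * dosage)  # expression proportional to dosage
        background = rng.poisson(5.0, (n, 30))  # stabilizes library size
        rna = CountMatrix(
            sp.csr_matrix(np.column_stack([expr, background])),
            m.cell_ids,
            np.array(["g0"] + [f"bg{j}" for j in range(30)], dtype=object),
        )
        report = ec.region_statistics(regions, m, GeneModels(genes), counts_rna=rna)
        assert report["expression_spearman"][0] >= 0.8
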