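"""Embedding, graph clustering, markers, pattern calls, line assignment."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from linehet import cluster_core as cc
from linehet.io_formats import CountMatrix


def counts_from(rows):
    rows = np.asarray(rows)
    return CountMatrix(
        sp.csr_matrix(rows),
        np.array([f"c{i}" for i in range(rows.shape[0])], dtype=object),
        np.array([f"g{j}" for j in range(rows.shape[1])], dtype=object),
    )


def blob_embedding(rng, centers, n_per, n_dim=10, sd=1.0):
    coords = np.vstack(
        [rng.standard_normal((n_per, n_dim)) * sd + np.asarray(c) for c in centers]
    )
    return cc.Embedding(coords, "rna", n_dim, coords.var(axis=0))


class TestEmbed:
    def test_duplicate_cells_identical_rows(self, rng):
        base = rng.poisson(5.0, (80, 120))
        base[40:] = base[:40]  # second half duplicates the first
        emb = cc.embed(counts_from(base), n_components=10)
        np.testing.assert_allclose(emb.coords[:40], emb.coords[40:], atol=1e-6)

    def test_rank_one_input_concentrates_variance(self):
        lib = np.arange(1, 61)[:, None]
        cm = counts_from(lib * np.ones((1, 40), dtype=int) * 5)
        # after library-size normalization this is constant; add one
        # informative gene so PCA has a single axis of variation
        X = np.asarray(cm.counts.todense())
        X[:, 0] += np.arange(60) * 20
        emb = cc.embed(counts_from(X), n_components=10)
        var = emb.component_variance
        assert var[0] / var.sum() > 0.99

    def test_cell_permutation_equivariance(self, rng):
        X = rng.poisson(4.0, (70, 90))
        perm = rng.permutation(70)
        emb = cc.embed(counts_from(X), n_components=8)
        emb_p = cc.embed(counts_from(X[perm]), n_components=8)
        # float32 pipeline arithmetic leaves summation-order noise
        np.testing.assert_allclose(emb.coords[perm], emb_p.coords, atol=1e-2)

    def test_too_few_cells_errors(self, rng):
        cm = counts_from(rng.poisson(4.0, (10, 50)))
        with pytest.raises(ValueError):
            cc.embed(cm, n_components=30)

    def test_atac_lsi_shape(self):
        import pandas as pd

        from linehet.io_formats import FragmentSet

        rng = np.random.default_rng(1)
        n = 60
        rows = []
        for i in range(n):
            pos = rng.integers(0, 1_900_000, size=300)
            for p in pos:
                rows.append(("chr1", p, p + 150, f"b{i:03d}", 1))
        fs = FragmentSet(
            pd.DataFrame(rows, columns=["chrom", "start", "end", "barcode", "dup_count"]),
            {"chr1": 2_000_000},
        )
        emb = cc.embed(fs, modality="atac", n_components=10, bin_size=100_000)
        assert emb.modality == "atac"
        assert emb.coords.shape[0] == n
        # columns ordered by decreasing variance
        assert np.all(np.diff(emb.component_variance) <= 1e-9)


class TestClusterGraph:
    def test_two_blobs_recovered(self, rng):
        emb = blob_embedding(rng, [np.r_[20.0, np.zeros(9)], np.zeros(10)], 200)
        clus = cc.cluster_graph(emb, resolution=0.3, seed=0)
        assert clus.n_clusters == 2
        truth = np.repeat([0, 1], 200)
        agree = max((clus.labels == truth).mean(), (clus.labels == 1 - truth).mean())
        assert agree >= 0.99

    def test_single_blob_one_cluster(self, rng):
        emb = blob_embedding(rng, [np.zeros(10)], 200)
        clus = cc.cluster_graph(emb, resolution=0.3, seed=0)
        assert clus.n_clusters == 1

    def test_seed_determinism(self, rng):
        emb = blob_embedding(rng, [np.zeros(10), np.r_[8.0, np.zeros(9)]], 100)
        a = cc.cluster_graph(emb, seed=3)
        b = cc.cluster_graph(emb, seed=3)
        assert np.array_equal(a.labels, b.labels)

    def test_permutation_invariance_up_to_relabel(self, rng):
        emb = blob_embedding(rng, [np.zeros(10), np.r_[20.0, np.zeros(9)]], 150)
        perm = rng.permutation(emb.n_cells)
        emb_p = cc.Embedding(
            emb.coords[perm], "rna", emb.n_components, emb.component_variance
        )
        a = cc.cluster_graph(emb, seed=0)
        b = cc.cluster_graph(emb_p, seed=0)
        # same partition after undoing the permutation (labels may swap)
        ct = pd.crosstab(a.labels[perm], b.labels)
        assert (ct.to_numpy() > 0).sum() == a.n_clusters

    def test_k_too_large_errors(self, rng):
        emb = blob_embedding(rng, [np.zeros(5)], 10, n_dim=5)
        with pytest.raises(ValueError):
            cc.cluster_graph(emb, k_neighbors=10)


class TestFindMarkers:
    def make_two_cluster_data(self, rng, n=60, n_genes=30, n_marked=5):
        X = rng.poisson(5.0, (2 * n, n_genes))
        X[:n, :n_marked] += rng.poisson(40.0, (n, n_marked))  # cluster 0 markers
        cm = counts_from(X)
        clus = cc.Clustering(np.repeat([0, 1], n), 0.3, 0.0)
        return cm, clus

    def test_marker_detected_and_null_gene_not(self, rng):
        cm, clus = self.make_two_cluster_data(rng)
        table = cc.find_markers(cm, clus)
        m0 = table[(table["cluster"] == 0) & (table["gene"] == "g0")].iloc[0]
        assert m0["is_marker"]
        null = table[(table["cluster"] == 0) & (table["gene"] == "g20")].iloc[0]
        assert not null["is_marker"]

    def test_lfc_antisymmetry_two_clusters(self, rng):
        cm, clus = self.make_two_cluster_data(rng)
        table = cc.find_markers(cm, clus)
        wide = table.pivot(index="gene", columns="cluster", values="log2_fold_change")
        np.testing.assert_allclose(wide[0], -wide[1], atol=1e-9)

    def test_bh_adjustment_matches_hand_stepup(self, rng):
        cm, clus = self.make_two_cluster_data(rng, n_genes=5, n_marked=1)
        table = cc.find_markers(cm, clus)
        sub = table[table["cluster"] == 0].reset_index(drop=True)
        p = sub["p_value"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank_pos in range(m - 1, -1, -1):  # BH step-up from the largest p
            i = order[rank_pos]
            running = min(running, p[i] * m / (rank_pos + 1))
            adj[i] = running
        np.testing.assert_allclose(sub["adjusted_p"].to_numpy(), adj, atol=1e-12)

    def test_small_cluster_skipped(self, rng):
        X = rng.poisson(5.0, (20, 10))
        clus = cc.Clustering(np.r_[np.zeros(18, int), [1, 1]], 0.3, 0.0)
        table = cc.find_markers(counts_from(X), clus)
        assert set(table["cluster"]) == {0}

    def test_adjusted_p_at_least_p(self, rng):
        cm, clus = self.make_two_cluster_data(rng)
        table = cc.find_markers(cm, clus)
        assert (table["adjusted_p"] >= table["p_value"] - 1e-15).all()


class TestClassifyPattern:
    def test_separated_blobs_are_discrete(self, rng):
        emb = blob_embedding(rng, [np.zeros(10), np.r_[20.0, np.zeros(9)]], 150)
        clus = cc.cluster_graph(emb, resolution=0.3, seed=0)
        call = cc.classify_pattern(emb, clus)
        assert call.pattern == "discrete"
        assert call.separation_p < 0.01

    def test_single_blob_is_continuous(self, rng):
        emb = blob_embedding(rng, [np.zeros(10)], 200)
        clus = cc.cluster_graph(emb, resolution=0.3, seed=0)
        call = cc.classify_pattern(emb, clus)
        assert call.pattern == "continuous"

    def test_one_cluster_is_continuous_by_definition(self, rng):
        emb = blob_embedding(rng, [np.zeros(10), np.r_[20.0, np.zeros(9)]], 100)
        clus = cc.Clustering(np.zeros(200, dtype=int), 0.3, 0.0)
        assert cc.classify_pattern(emb, clus).pattern == "continuous"

    def test_separation_monotonicity(self, rng):
        """Once discrete, increasing blob separation never flips the call."""
        seen_discrete = False
        for sep in (2.0, 5.0, 10.0, 20.0):
            emb = blob_embedding(rng, [np.zeros(10), np.r_[sep, np.zeros(9)]], 150)
            clus = cc.cluster_graph(emb, resolution=0.3, seed=0)
            call = cc.classify_pattern(emb, clus)
            if seen_discrete:
                assert call.pattern == "discrete"
            seen_discrete = seen_discrete or call.pattern == "discrete"
        assert seen_discrete


class TestAssignCellLines:
    def test_pooled_lines_recovered(self, rna_small):
        cm, truth = rna_small
        emb = cc.embed(cm, n_components=20)
        clus = cc.cluster_graph(emb, resolution=0.3, seed=0)
        assert clus.n_clusters == 3
        ref = truth.reference_profiles
        table = cc.assign_cell_lines(cm, clus, ref)
        assert table["assigned"].all()
        # every truth line appears exactly once among assignments
        assert sorted(table["line"]) == sorted(ref.index)
        # assignments agree with the dominant truth line of each cluster
        for _, row in table.iterrows():
            mask = clus.labels == row["cluster"]
            major = cm.cell_meta["cell_line"][mask].mode()[0]
            assert row["line"] == major

    def test_disjoint_markers_unassigned(self, rng):
        X = rng.poisson(5.0, (60, 30))
        X[:30, :5] += 50  # markers g0..g4
        cm = counts_from(X)
        clus = cc.Clustering(np.repeat([0, 1], 30), 0.3, 0.0)
        ref = pd.DataFrame(
            [[10.0] * 10], index=["lineX"],
            columns=[f"g{j}" for j in range(20, 30)],
        )
        table = cc.assign_cell_lines(cm, clus, ref, top_n_ref=10)
        row0 = table[table["cluster"] == 0].iloc[0]
        assert not row0["assigned"] and row0["line"] is None

    def test_no_shared_genes_errors(self, rng):
        cm = counts_from(rng.poisson(5.0, (40, 10)))
        clus = cc.Clustering(np.repeat([0, 1], 20), 0.3, 0.0)
        ref = pd.DataFrame([[1.0]], index=["lineX"], columns=["other_gene"])
        with pytest.raises(ValueError):
            cc.assign_cell_lines(cm, clus, ref)
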