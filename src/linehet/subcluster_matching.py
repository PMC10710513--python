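"""Cross-condition subcluster matching and ATAC -> RNA label transfer.

Matching uses the 80% rule: two condition subclusters are matched when more
than 80% of the cells of each lie in one common cluster of the jointly
embedded (concatenated, jointly HVG-selected, per-condition-scaled) data.
A cluster "divided from one to more" by the treatment — a latent subgroup
responding differently — surfaces either as a one-to-many match (one
condition cluster sharing its integrated cluster with several counterpart
clusters) or as a condition cluster spreading over two or more integrated
clusters at >= 20% each; both are flagged split.

Label transfer computes a per-ATAC-cell gene activity (fragment midpoints
over the gene body extended 2 kb upstream), embeds activity and expression
jointly, and assigns each ATAC cell the majority RNA cluster among its k
nearest RNA neighbours iff that majority fraction (the prediction score)
exceeds 0.9.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cluster_core import Clustering, cluster_graph, Embedding, log_normalize
from .io_formats import CountMatrix, FragmentSet, GeneModels

log = logging.getLogger(__name__)

__all__ = [
    "MatchTable",
    "TransferResult",
    "match_conditions",
    "gene_activity",
    "transfer_atac_to_rna",
    "transfer_from_activity",
    "hypoxia_de",
]


@dataclass
class MatchTable:
    rows: pd.DataFrame  # cluster_A, cluster_B, integrated_cluster, fracs, status
    clustering_a: Clustering = None
    clustering_b: Clustering = None
    integrated: Clustering = None

    def matched_pairs(self) -> list:
        sub = self.rows[self.rows["status"] == "matched"]
        return list(zip(sub["cluster_A"], sub["cluster_B"]))

    def split_clusters(self, condition: str = "A") -> list:
        """Clusters of one condition flagged split.

        A cluster is split when it pairs with >= 2 counterpart clusters
        (one-to-many match) or occupies >= 2 integrated clusters itself.
        """
        col = f"cluster_{condition}"
        other = "cluster_B" if condition == "A" else "cluster_A"
        sub = self.rows[self.rows["status"] == "split"]
        out = []
        for c, rows_c in sub.dropna(subset=[col]).groupby(col):
            if len(rows_c) >= 2 or rows_c[other].isna().all():
                out.append(int(c))
        return sorted(out)


@dataclass
class TransferResult:
    table: pd.DataFrame  # per ATAC cell: assigned cluster, score, unassigned

    @property
    def assigned_fraction(self) -> float:
        return float((~self.table["unassigned"]).mean())


def _joint_embedding(
    mats: list, n_hvg: int = 2000, n_components: int = 30
) -> np.ndarray:
    """Concatenated embedding: joint HVG on pooled data, per-batch scaling, PCA."""
    from sklearn.decomposition import PCA

    logn = [log_normalize(m) for m in mats]
    pooled = np.vstack(logn)
    if pooled.shape[1] > n_hvg:
        order = np.sort(np.argsort(pooled.var(axis=0))[::-1][:n_hvg])
    else:
        order = np.arange(pooled.shape[1])
    scaled = []
    for X in logn:
        sub = X[:, order]
        mu, sd = sub.mean(axis=0), sub.std(axis=0)
        sd[sd == 0] = 1.0
        scaled.append(np.clip((sub - mu) / sd, -10, 10))
    stacked = np.vstack(scaled)
    n_comp = min(n_components, stacked.shape[1] - 1, stacked.shape[0] - 1)
    pca = PCA(n_components=n_comp, svd_solver="arpack", random_state=0)
    return pca.fit_transform(stacked)


def match_conditions(
    counts_a: CountMatrix,
    counts_b: CountMatrix,
    resolution: float = 0.3,
    integrated_resolution: float = 0.1,
    seed: int = 0,
    match_threshold: float = 0.8,
    split_threshold: float = 0.2,
) -> MatchTable:
    """Match subclusters between two conditions via integrated clustering.

    Cluster a of A matches cluster b of B iff more than ``match_threshold``
    of the cells of each lie in one common integrated cluster; a condition
    cluster occupying >= 2 integrated clusters at >= ``split_threshold`` each
    is flagged split; everything else is unmatched.
    """
    shared = [g for g in counts_a.gene_ids if g in set(counts_b.gene_ids)]
    if not shared:
        raise ValueError("condition matrices share no genes")
    idx_a = {g: i for i, g in enumerate(counts_a.gene_ids)}
    idx_b = {g: i for i, g in enumerate(counts_b.gene_ids)}
    a = counts_a.subset_genes([idx_a[g] for g in shared])
    b = counts_b.subset_genes([idx_b[g] for g in shared])

    from .cluster_core import embed

    clus_a = cluster_graph(embed(a), resolution=resolution, seed=seed)
    clus_b = cluster_graph(embed(b), resolution=resolution, seed=seed)

    coords = _joint_embedding([a.counts, b.counts])
    joint_emb = Embedding(coords, "rna", coords.shape[1], coords.var(axis=0))
    integrated = cluster_graph(joint_emb, resolution=integrated_resolution, seed=seed)
    n_a = a.n_cells
    int_a, int_b = integrated.labels[:n_a], integrated.labels[n_a:]

    def occupancy(labels, integrated_labels):
        out = {}
        for c in range(int(labels.max()) + 1):
            mask = labels == c
            out[c] = (
                pd.Series(integrated_labels[mask]).value_counts(normalize=True)
            )
        return out

    occ_a = occupancy(clus_a.labels, int_a)
    occ_b = occupancy(clus_b.labels, int_b)

    pairs = []
    for ca, oa in occ_a.items():
        for cb, ob in occ_b.items():
            common = set(oa[oa > match_threshold].index) & set(
                ob[ob > match_threshold].index
            )
            if common:
                g = common.pop()
                pairs.append((ca, cb, g, float(oa[g]), float(ob[g])))
    # a condition cluster pairing with >= 2 counterparts was divided from one
    # to more by the treatment: flag the whole group split, not matched
    count_a = pd.Series([p[0] for p in pairs]).value_counts() if pairs else {}
    count_b = pd.Series([p[1] for p in pairs]).value_counts() if pairs else {}
    rows, matched_a, matched_b = [], set(), set()
    for ca, cb, g, fa, fb in pairs:
        status = "matched"
        if count_a.get(ca, 0) >= 2 or count_b.get(cb, 0) >= 2:
            status = "split"
        rows.append(
            {"cluster_A": ca, "cluster_B": cb, "integrated_cluster": g,
             "frac_A_in_integrated": fa, "frac_B_in_integrated": fb,
             "status": status}
        )
        matched_a.add(ca)
        matched_b.add(cb)

    def leftovers(occ, matched, side):
        for c, o in occ.items():
            if c in matched:
                continue
            status = "split" if (o >= split_threshold).sum() >= 2 else "unmatched"
            row = {"cluster_A": None, "cluster_B": None,
                   "integrated_cluster": int(o.idxmax()),
                   "frac_A_in_integrated": np.nan,
                   "frac_B_in_integrated": np.nan, "status": status}
            row[f"cluster_{side}"] = c
            row[f"frac_{side}_in_integrated"] = float(o.max())
            rows.append(row)

    leftovers(occ_a, matched_a, "A")
    leftovers(occ_b, matched_b, "B")
    table = pd.DataFrame(
        rows,
        columns=["cluster_A", "cluster_B", "integrated_cluster",
                 "frac_A_in_integrated", "frac_B_in_integrated", "status"],
    )
    return MatchTable(table, clus_a, clus_b, integrated)


# ---------------------------------------------------------------------------
# label transfer


def gene_activity(
    fragments: FragmentSet, gene_models: GeneModels, upstream: int = 2000
) -> CountMatrix:
    """Per-cell accessibility over gene body + upstream flank.

    Counts fragment midpoints inside each gene's interval extended
    ``upstream`` bp upstream of the TSS (strand-aware); a simple
    interval-overlap gene activity score.
    """
    genes = gene_models.genes
    barcodes = np.sort(fragments.records["barcode"].unique())
    bc_idx = {b: i for i, b in enumerate(barcodes)}
    mat = np.zeros((len(barcodes), len(genes)), dtype=np.int64)
    rec = fragments.records
    mids_all = ((rec["start"] + rec["end"]) // 2).to_numpy()
    cells_all = rec["barcode"].map(bc_idx).to_numpy()
    chrom_arr = rec["chrom"].to_numpy()
    for chrom, sub in genes.groupby("chrom"):
        sel = np.flatnonzero(chrom_arr == chrom)
        if sel.size == 0:
            continue
        order = np.argsort(mids_all[sel], kind="stable")
        mids = mids_all[sel][order]
        cells = cells_all[sel][order]
        ext_start = np.where(
            sub["strand"] == "+", sub["start"] - upstream, sub["start"]
        )
        ext_end = np.where(
            sub["strand"] == "+", sub["end"], sub["end"] + upstream
        )
        for gi, (s, e) in zip(sub.index, zip(ext_start, ext_end)):
            lo, hi = np.searchsorted(mids, [s, e])
            col = genes.index.get_loc(gi)
            np.add.at(mat, (cells[lo:hi], col), 1)
    return CountMatrix(
        sp.csr_matrix(mat), barcodes,
        genes["gene_id"].to_numpy(dtype=object),
    )


def transfer_from_activity(
    activity: CountMatrix,
    counts_rna: CountMatrix,
    rna_clusters: Clustering,
    k: int = 25,
    score_min: float = 0.9,
    n_hvg: int = 2000,
    n_components: int = 30,
) -> TransferResult:
    """k-NN label transfer from RNA clusters onto activity profiles.

    Both matrices are embedded jointly over shared HVGs; each query cell's
    prediction score is the fraction of its ``k`` nearest RNA neighbours in
    the majority RNA cluster, assigned iff score > ``score_min``.
    """
    from sklearn.neighbors import NearestNeighbors

    if k >= counts_rna.n_cells:
        raise ValueError("k must be smaller than the number of RNA cells")
    shared = [g for g in counts_rna.gene_ids if g in set(activity.gene_ids)]
    if not shared:
        raise ValueError("no shared gene universe after gene-activity computation")
    idx_r = {g: i for i, g in enumerate(counts_rna.gene_ids)}
    idx_q = {g: i for i, g in enumerate(activity.gene_ids)}
    rna = counts_rna.subset_genes([idx_r[g] for g in shared])
    query = activity.subset_genes([idx_q[g] for g in shared])

    coords = _joint_embedding(
        [rna.counts, query.counts], n_hvg=n_hvg, n_components=n_components
    )
    ref, qry = coords[: rna.n_cells], coords[rna.n_cells :]
    nn = NearestNeighbors(n_neighbors=k).fit(ref)
    _, nbr = nn.kneighbors(qry)
    labels = rna_clusters.labels[nbr]  # query x k
    rows = []
    for i, barcode in enumerate(activity.cell_ids):
        counts = np.bincount(labels[i])
        major = int(np.argmax(counts))
        score = counts[major] / k
        assigned = score > score_min
        rows.append(
            {"barcode": barcode,
             "assigned_cluster": major if assigned else None,
             "prediction_score": float(score), "unassigned": not assigned}
        )
    return TransferResult(pd.DataFrame(rows).set_index("barcode"))


def transfer_atac_to_rna(
    fragments: FragmentSet,
    gene_models: GeneModels,
    counts_rna: CountMatrix,
    rna_clusters: Clustering,
    k: int = 25,
    score_min: float = 0.9,
) -> TransferResult:
    """ATAC -> RNA label transfer with the 0.9 prediction-score gate."""
    activity = gene_activity(fragments, gene_models)
    return transfer_from_activity(
        activity, counts_rna, rna_clusters, k=k, score_min=score_min
    )


# ---------------------------------------------------------------------------
# differential expression between conditions


def hypoxia_de(
    counts_a: CountMatrix,
    counts_b: CountMatrix,
    matches: list,
    labels_a=None,
    labels_b=None,
    min_lfc: float = 2.0,
    max_adj_p: float = 0.01,
) -> pd.DataFrame:
    """Rank-sum DE between conditions within each matched subcluster pair.

    ``matches`` lists (cluster_A, cluster_B) pairs; labels default to the
    ``cluster`` column of each matrix's cell_meta.  Significant genes need
    adjusted p < ``max_adj_p`` AND |log2FC| > ``min_lfc`` (fold computed
    treated/B over control/A on mean normalized expression, pseudocount 1).
    Pairs with fewer than 3 cells on either side are skipped.
    """
    la = np.asarray(labels_a if labels_a is not None else counts_a.cell_meta["cluster"])
    lb = np.asarray(labels_b if labels_b is not None else counts_b.cell_meta["cluster"])
    if list(counts_a.gene_ids) != list(counts_b.gene_ids):
        raise ValueError("condition matrices must share a gene universe")
    norm_a = log_normalize(counts_a.counts, log=False)
    norm_b = log_normalize(counts_b.counts, log=False)
    frames = []
    for ca, cb in matches:
        x = norm_a[la == ca]
        y = norm_b[lb == cb]
        if x.shape[0] < 3 or y.shape[0] < 3:
            log.warning("pair (%s, %s) has <3 cells per side; skipped", ca, cb)
            continue
        with np.errstate(invalid="ignore"):
            _, p = stats.mannwhitneyu(
                np.log1p(x), np.log1p(y), axis=0,
                alternative="two-sided", method="asymptotic",
            )
        p = np.nan_to_num(p, nan=1.0)
        adj = multipletests(p, method="fdr_bh")[1]
        lfc = np.log2(y.mean(axis=0) + 1.0) - np.log2(x.mean(axis=0) + 1.0)
        frames.append(
            pd.DataFrame(
                {"cluster_A": ca, "cluster_B": cb, "gene": counts_a.gene_ids,
                 "log2_fold_change": lfc, "p_value": p,
                 "adjusted_p": np.maximum(adj, p),
                 "is_significant": (adj < max_adj_p) & (np.abs(lfc) > min_lfc)}
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["cluster_A", "cluster_B", "gene", "log2_fold_change",
                     "p_value", "adjusted_p", "is_significant"]
        )
    return pd.concat(frames, ignore_index=True)
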