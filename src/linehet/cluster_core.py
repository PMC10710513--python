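"""Embedding, graph clustering, marker detection and cell-line assignment.

The RNA path follows the standard single-cell recipe (library-size
log-normalization, variance-stabilized HVG selection, scaling, PCA); the
ATAC path uses TF-IDF + truncated SVD (latent semantic indexing) on a
cell x bin matrix, dropping the first component when it tracks sequencing
depth.  Clustering is Leiden modularity optimization on a KNN graph built
from Euclidean distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.neighbors import kneighbors_graph
from statsmodels.stats.multitest import multipletests

from .io_formats import CountMatrix, FragmentSet

log = logging.getLogger(__name__)

__all__ = [
    "Embedding",
    "Clustering",
    "PatternCall",
    "embed",
    "cluster_graph",
    "find_markers",
    "classify_pattern",
    "assign_cell_lines",
    "log_normalize",
]


@dataclass
class Embedding:
    coords: np.ndarray  # cells x components, columns by decreasing variance
    modality: str
    n_components: int
    component_variance: np.ndarray
    cell_ids: np.ndarray = None

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]


@dataclass
class Clustering:
    labels: np.ndarray  # contiguous ids from 0
    resolution: float
    modularity: float

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


@dataclass
class PatternCall:
    pattern: str  # "discrete" | "continuous"
    n_clusters: int
    separation_p: float


def log_normalize(counts, target: float = 1e4, log: bool = True) -> np.ndarray:
    """Library-size normalization to ``target`` counts per cell, optionally log1p."""
    X = counts.toarray() if sp.issparse(counts) else np.asarray(counts, dtype=float)
    lib = X.sum(axis=1, keepdims=True)
    lib[lib == 0] = 1.0
    X = X / lib * target
    return np.log1p(X) if log else X


def embed(
    data,
    modality: str = "rna",
    n_hvg: int = 2000,
    n_components: int = 30,
    bin_size: int = 100_000,
) -> Embedding:
    """Dimensionality reduction for either modality.

    RNA (:class:`CountMatrix`): normalize, log1p, HVG, scale, PCA.
    ATAC (:class:`FragmentSet`): binarized cell x bin TF-IDF then truncated
    SVD; the leading component is dropped if |r| > 0.9 with log depth.
    """
    if modality == "rna":
        if not isinstance(data, CountMatrix):
            raise TypeError("rna modality expects a CountMatrix")
        if data.n_cells <= n_components:
            raise ValueError("fewer cells than requested components")
        import scanpy as sc

        adata = data.to_anndata()
        sc.pp.normalize_total(adata, target_sum=1e4)
        sc.pp.log1p(adata)
        if sp.issparse(adata.X):
            adata.X = np.asarray(adata.X.todense())
        if data.n_genes > n_hvg:
            sc.pp.highly_variable_genes(adata, n_top_genes=n_hvg, flavor="seurat")
            adata = adata[:, adata.var["highly_variable"]].copy()
        sc.pp.scale(adata, max_value=10)
        n_comp = min(n_components, adata.n_vars - 1, adata.n_obs - 1)
        sc.tl.pca(adata, n_comps=n_comp, svd_solver="arpack", random_state=0)
        coords = np.asarray(adata.obsm["X_pca"], dtype=float)
        var = np.asarray(adata.uns["pca"]["variance"], dtype=float)
        return Embedding(coords, "rna", coords.shape[1], var, data.cell_ids)

    if modality == "atac":
        if not isinstance(data, FragmentSet):
            raise TypeError("atac modality expects a FragmentSet")
        mat, _, barcodes = data.to_bin_matrix(bin_size)
        if mat.shape[0] <= n_components:
            raise ValueError("fewer cells than requested components")
        depth = mat.sum(axis=1).astype(float)
        binary = (mat > 0).astype(float)
        tf = binary / np.maximum(binary.sum(axis=1, keepdims=True), 1.0)
        n_open = np.maximum(binary.sum(axis=0), 1.0)
        idf = mat.shape[0] / n_open
        lsi = np.log1p(tf * idf * 1e4)
        from sklearn.decomposition import TruncatedSVD

        n_comp = min(n_components, lsi.shape[1] - 1, lsi.shape[0] - 1)
        svd = TruncatedSVD(n_components=n_comp, random_state=0)
        coords = svd.fit_transform(lsi)
        var = coords.var(axis=0)
        r = np.corrcoef(coords[:, 0], np.log1p(depth))[0, 1]
        if abs(r) > 0.9:
            log.info("dropping LSI component 1 (depth correlation %.3f)", r)
            coords, var = coords[:, 1:], var[1:]
        order = np.argsort(var)[::-1]
        return Embedding(
            coords[:, order], "atac", coords.shape[1], var[order],
            np.asarray(barcodes, dtype=object),
        )

    raise ValueError(f"unknown modality {modality!r}")


def cluster_graph(
    embedding: Embedding,
    resolution: float = 0.3,
    k_neighbors: int = 20,
    seed: int = 0,
) -> Clustering:
    """Leiden community detection on a Euclidean KNN graph.

    Labels are relabeled by decreasing cluster size (ties by first member)
    and are deterministic given the seed.
    """
    n = embedding.n_cells
    if n == 0:
        raise ValueError("empty embedding")
    if k_neighbors >= n:
        raise ValueError("k_neighbors must be smaller than the number of cells")
    import igraph
    import leidenalg

    adj = kneighbors_graph(embedding.coords, k_neighbors, mode="connectivity")
    adj = adj + adj.T  # mutual union, weights ignored
    adj.data[:] = 1.0
    sources, targets = adj.nonzero()
    mask = sources < targets
    graph = igraph.Graph(
        n=n, edges=list(zip(sources[mask], targets[mask])), directed=False
    )
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    raw = np.asarray(part.membership)
    # stable relabeling: decreasing size, ties broken by first appearance
    order = sorted(
        np.unique(raw),
        key=lambda c: (-(raw == c).sum(), int(np.flatnonzero(raw == c)[0])),
    )
    remap = {c: i for i, c in enumerate(order)}
    labels = np.array([remap[c] for c in raw])
    return Clustering(labels, resolution, graph.modularity(raw))


def find_markers(
    counts: CountMatrix,
    clustering: Clustering,
    min_lfc: float = 0.5,
    max_adj_p: float = 0.01,
) -> pd.DataFrame:
    """One-vs-rest rank-sum marker test per cluster.

    The test runs on log-normalized values; log2FC uses a pseudocount of 1 on
    mean normalized expression; Benjamini-Hochberg is applied across genes
    within each cluster.  Returns one row per (cluster, gene) tested with an
    ``is_marker`` flag (adjusted_p < max_adj_p AND log2FC > min_lfc, strict).
    """
    if clustering.n_clusters < 2:
        raise ValueError("marker detection needs at least 2 clusters")
    norm = log_normalize(counts.counts, log=False)
    logn = np.log1p(norm)
    labels = clustering.labels
    frames = []
    for c in range(clustering.n_clusters):
        mask = labels == c
        if mask.sum() < 3:
            log.warning("cluster %d has <3 cells; skipped", c)
            continue
        x, y = logn[mask], logn[~mask]
        with np.errstate(invalid="ignore"):
            _, p = stats.mannwhitneyu(
                x, y, axis=0, alternative="two-sided", method="asymptotic"
            )
        p = np.nan_to_num(p, nan=1.0)
        adj = multipletests(p, method="fdr_bh")[1]
        lfc = np.log2(norm[mask].mean(axis=0) + 1.0) - np.log2(
            norm[~mask].mean(axis=0) + 1.0
        )
        frames.append(
            pd.DataFrame(
                {
                    "cluster": c,
                    "gene": counts.gene_ids,
                    "log2_fold_change": lfc,
                    "p_value": p,
                    "adjusted_p": np.maximum(adj, p),
                    "is_marker": (adj < max_adj_p) & (lfc > min_lfc),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def classify_pattern(
    embedding: Embedding, clustering: Clustering, max_pairs: int = 20_000
) -> PatternCall:
    """Call the heterogeneity pattern: discrete vs continuous.

    Discrete iff >= 2 clusters and sampled within-cluster pairwise distances
    are significantly smaller than between-cluster ones (one-sided rank-sum,
    p < 0.01, median(within) < median(between)); otherwise continuous.
    """
    n = embedding.n_cells
    labels = clustering.labels
    if clustering.n_clusters < 2:
        return PatternCall("continuous", clustering.n_clusters, float("nan"))
    rng = np.random.default_rng(0)
    n_draw = min(8 * max_pairs, max(n * (n - 1) // 2, 1))
    i = rng.integers(0, n, n_draw)
    j = rng.integers(0, n, n_draw)
    ok = i < j
    i, j = i[ok], j[ok]
    d = np.linalg.norm(embedding.coords[i] - embedding.coords[j], axis=1)
    same = labels[i] == labels[j]
    within, between = d[same][:max_pairs], d[~same][:max_pairs]
    if within.size == 0 or between.size == 0:
        return PatternCall("continuous", clustering.n_clusters, float("nan"))
    p = stats.mannwhitneyu(within, between, alternative="less").pvalue
    discrete = p < 0.01 and np.median(within) < np.median(between)
    return PatternCall(
        "discrete" if discrete else "continuous", clustering.n_clusters, float(p)
    )


def assign_cell_lines(
    counts: CountMatrix,
    clustering: Clustering,
    reference_profiles: pd.DataFrame,
    top_n_ref: int = 200,
    min_score: float = 0.1,
) -> pd.DataFrame:
    """Assign pooled-run clusters to cell lines by marker overlap.

    For each cluster, the overlap score against a line is
    |cluster markers ∩ top ``top_n_ref`` reference genes| / |cluster markers|;
    the argmax line is assigned when its score reaches ``min_score``, with
    confidence the margin over the runner-up.
    """
    shared = [g for g in counts.gene_ids if g in set(reference_profiles.columns)]
    if not shared:
        raise ValueError("no shared genes between query and reference")
    ref = reference_profiles[shared]
    top = {
        line: set(ref.loc[line].nlargest(top_n_ref).index)
        for line in ref.index
    }
    markers = find_markers(counts, clustering)
    rows = []
    for c, sub in markers[markers["is_marker"]].groupby("cluster"):
        genes = set(sub["gene"])
        scores = {
            line: len(genes & top[line]) / len(genes) if genes else 0.0
            for line in ref.index
        }
        ranked = sorted(scores.items(), key=lambda kv: -kv[1])
        best, second = ranked[0], ranked[1] if len(ranked) > 1 else (None, 0.0)
        rows.append(
            {
                "cluster": c,
                "line": best[0] if best[1] >= min_score else None,
                "score": best[1],
                "confidence": best[1] - second[1],
                "assigned": best[1] >= min_score,
            }
        )
    return pd.DataFrame(rows, columns=["cluster", "line", "score", "confidence", "assigned"])
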