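"""Recurrent NMF expression programs across cell lines.

Per line, non-negative matrix factorization is run at several factor counts
on log-normalized, per-gene scaled data with negative values zeroed; each
factor's 50 top-loading genes form a program.  A program is *robust* when a
program obtained at a different k shares at least 35 of its 50 genes.
Robust programs are clustered across lines by Jaccard similarity of their
gene sets (average-linkage hierarchy); clusters spanning more than 3 lines
are the recurrent programs, and their signature genes are those appearing in
more than 25% of member programs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .cluster_core import log_normalize
from .cnv_subclones import hypergeometric_enrichment
from .io_formats import CountMatrix

log = logging.getLogger(__name__)

__all__ = [
    "NmfProgram",
    "ProgramCluster",
    "extract_programs",
    "cluster_programs",
    "signature_genes",
    "score_gene_set",
    "program_cooccurrence",
    "jaccard",
]


@dataclass
class NmfProgram:
    line_id: str
    k: int
    factor_index: int
    top_genes: np.ndarray  # 50 gene ids, decreasing loading
    loadings: pd.Series  # weight per top gene

    def gene_set(self) -> frozenset:
        return frozenset(self.top_genes)


@dataclass
class ProgramCluster:
    cluster_id: int
    member_programs: list
    member_lines: list = field(init=False)
    signature_genes: np.ndarray = field(init=False)
    annotation_label: str = ""

    def __post_init__(self) -> None:
        self.member_lines = sorted({p.line_id for p in self.member_programs})
        self.signature_genes = signature_genes(self)


def jaccard(a, b) -> float:
    a, b = set(a), set(b)
    union = len(a | b)
    return len(a & b) / union if union else 1.0


def _nmf_input(counts: CountMatrix, n_hvg: int) -> tuple:
    """Log-normalize, per-gene z-score, zero negatives; optional HVG subset."""
    logn = log_normalize(counts.counts)
    if counts.n_genes > n_hvg:
        order = np.argsort(logn.var(axis=0))[::-1][:n_hvg]
        order = np.sort(order)
    else:
        order = np.arange(counts.n_genes)
    X = logn[:, order]
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    X = np.maximum((X - mu) / sd, 0.0)
    return X, counts.gene_ids[order]


def extract_programs(
    counts_per_line: dict,
    k_range=range(6, 10),
    n_top_genes: int = 50,
    robust_overlap: int = 35,
    min_cells: int = 100,
    n_hvg: int = 2000,
    seed: int = 0,
    max_iter: int = 400,
) -> list:
    """Robust NMF programs per line, deduplicated.

    ``counts_per_line`` maps line id to its QC-filtered CountMatrix.  Lines
    with fewer than ``min_cells`` cells are skipped with a warning.  Output
    depends only on (data, k_range, seed).
    """
    from sklearn.decomposition import NMF

    programs: list = []
    for line_id in sorted(counts_per_line):
        counts = counts_per_line[line_id]
        if counts.n_cells < min_cells:
            log.warning("line %s has <%d cells; skipped", line_id, min_cells)
            continue
        X, genes = _nmf_input(counts, n_hvg)
        per_k: dict = {}
        for k in k_range:
            model = NMF(
                n_components=k, init="nndsvd", random_state=seed,
                max_iter=max_iter, tol=1e-4,
            )
            model.fit(X)
            H = model.components_  # k x genes
            per_k[k] = []
            for f in range(k):
                order = np.argsort(H[f])[::-1][:n_top_genes]
                per_k[k].append(
                    NmfProgram(
                        line_id, k, f, genes[order],
                        pd.Series(H[f][order], index=genes[order]),
                    )
                )
        robust = []
        for k, progs in per_k.items():
            for p in progs:
                s = p.gene_set()
                hit = any(
                    len(s & q.gene_set()) >= robust_overlap
                    for k2, qs in per_k.items() if k2 != k
                    for q in qs
                )
                if hit:
                    robust.append(p)
        # deduplicate within the line, keeping the smallest-k representative
        robust.sort(key=lambda p: (p.k, p.factor_index))
        kept: list = []
        for p in robust:
            if all(
                len(p.gene_set() & q.gene_set()) < robust_overlap for q in kept
            ):
                kept.append(p)
        programs.extend(kept)
    return programs


def cluster_programs(
    programs: list, min_lines: int = 4, cut_distance: float = 0.9
) -> list:
    """Recurrent program clusters from Jaccard similarity of gene sets.

    Average-linkage hierarchical clustering on 1 - Jaccard, tree cut at
    ``cut_distance``; clusters spanning at least ``min_lines`` distinct lines
    (the ">3 cell lines" recurrence rule) are returned.
    """
    if len(programs) < 2:
        return []
    n = len(programs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - jaccard(programs[i].top_genes, programs[j].top_genes)
            dist[i, j] = dist[j, i] = d
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    assignment = hierarchy.fcluster(link, t=cut_distance, criterion="distance")
    clusters = []
    for cid in np.unique(assignment):
        members = [programs[i] for i in np.flatnonzero(assignment == cid)]
        cluster = ProgramCluster(int(cid), members)
        if len(cluster.member_lines) >= min_lines:
            clusters.append(cluster)
    return clusters


def signature_genes(cluster: ProgramCluster) -> np.ndarray:
    """Genes present in strictly more than 25% of a cluster's programs."""
    members = cluster.member_programs
    count = pd.Series(
        np.concatenate([p.top_genes for p in members])
    ).value_counts()
    sig = count[count > 0.25 * len(members)].index
    return np.asarray(sorted(sig), dtype=object)


def score_gene_set(
    counts: CountMatrix,
    gene_set,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell module score: target mean minus expression-matched control.

    Genes are binned into ``n_bins`` equal-size bins by average log-normalized
    expression; each target gene contributes ``n_ctrl`` control genes drawn
    from its bin (the whole bin when it holds fewer than ``n_ctrl`` genes).
    """
    gene_index = {g: i for i, g in enumerate(counts.gene_ids)}
    target = [gene_index[g] for g in gene_set if g in gene_index]
    if not target:
        raise ValueError("gene_set shares no genes with the matrix")
    logn = log_normalize(counts.counts)
    avg = logn.mean(axis=0)
    order = np.argsort(avg, kind="stable")
    bin_of = np.empty(len(avg), dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bin_of[chunk] = b
    bins = {b: np.flatnonzero(bin_of == b) for b in range(n_bins)}
    rng = np.random.default_rng(seed)
    ctrl: list = []
    for g in target:
        pool = bins[bin_of[g]]
        if pool.size <= n_ctrl:
            ctrl.append(pool)
        else:
            ctrl.append(rng.choice(pool, size=n_ctrl, replace=False))
    ctrl = np.concatenate(ctrl)
    return logn[:, target].mean(axis=1) - logn[:, ctrl].mean(axis=1)


def program_cooccurrence(clusters: list, universe=None) -> pd.DataFrame:
    """Hypergeometric co-occurrence of recurrent programs across lines.

    For each cluster pair, the upper-tail probability of the observed overlap
    of member lines given the line universe; BH-adjusted across pairs.
    """
    if len(clusters) < 2:
        raise ValueError("need at least 2 recurrent clusters")
    if universe is None:
        universe = sorted({l for c in clusters for l in c.member_lines})
    n_u = len(universe)
    rows = []
    for a, b in itertools.combinations(clusters, 2):
        la, lb = set(a.member_lines), set(b.member_lines)
        overlap = len(la & lb)
        p = hypergeometric_enrichment(overlap, len(la), len(lb), n_u)
        rows.append(
            {"cluster_a": a.cluster_id, "cluster_b": b.cluster_id,
             "overlap": overlap, "p_value": p}
        )
    out = pd.DataFrame(rows)
    out["adjusted_p"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
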