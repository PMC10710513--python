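"""Expression-inferred CNV profiles, subclones and their association with
transcriptomic subclusters.

The CNV profile is a window-average re-implementation: log2 expression
residuals against reference normal cells, averaged over a moving window of
400 genes ordered by genomic position.  Subclones are called from a
multimodal chromosome-arm dosage signal (2-component Gaussian mixture vs 1,
BIC margin) followed by a 2-way hierarchical cut.  Lines are typed A
(subclones nested in transcriptomic subclusters), B (subclones scattered
across them) or C (no subclones).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .cluster_core import Clustering, log_normalize
from .io_formats import CountMatrix

log = logging.getLogger(__name__)

__all__ = [
    "CnvProfile",
    "SubcloneCall",
    "infer_cnv_profile",
    "detect_subclones",
    "classify_association",
    "hypergeometric_enrichment",
]


@dataclass
class CnvProfile:
    values: np.ndarray  # tumor cells x windows, log2 ratio to reference
    cell_ids: np.ndarray
    windows: pd.DataFrame  # chrom, center_gene, position, n_genes
    window_genes: list  # ordered gene-id array per window
    reference_cell_ids: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]


@dataclass
class SubcloneCall:
    labels: pd.Series  # per-cell subclone id (0-based)
    evidence: list = field(default_factory=list)  # (arm, bic_margin, mean_sep)
    association_type: str = None

    @property
    def n_subclones(self) -> int:
        return int(self.labels.nunique())


def infer_cnv_profile(
    counts: CountMatrix,
    reference_cells,
    gene_models=None,
    window: int = 400,
    clip: float = 3.0,
    min_mean_expr: float = 0.1,
    norm_target: float = 1e6,
) -> CnvProfile:
    """Window-averaged log2 expression ratio against reference cells.

    Genes are ordered by genomic position (from ``gene_models`` or the
    matrix's own gene_meta), low-expression genes (mean raw count below
    ``min_mean_expr``) are excluded, each gene's log2 normalized expression
    is centered on the reference-cell mean, and a moving average over a
    centered ``window``-gene window (truncated at chromosome ends) is taken
    per cell.  Values are clipped to ±``clip``.  Chromosomes with fewer than
    10 positioned genes are excluded with a warning.
    """
    reference_cells = np.asarray(list(reference_cells), dtype=object)
    if reference_cells.size == 0:
        raise ValueError("reference_cells must be nonempty")
    pos = (
        gene_models.genes.set_index("gene_id")[["chrom", "start"]]
        if gene_models is not None
        else counts.gene_meta[["chrom", "start"]]
    )
    pos = pos.reindex(counts.gene_ids).dropna()

    mean_raw = np.asarray(counts.counts.mean(axis=0)).ravel()
    expressed = set(counts.gene_ids[mean_raw >= min_mean_expr])
    pos = pos[pos.index.isin(expressed)]

    # counts-per-million keeps typical values far above the +1 pseudocount,
    # so window averages read as log2 dosage ratios
    logx = np.log2(log_normalize(counts.counts, target=norm_target, log=False) + 1.0)
    gene_col = {g: i for i, g in enumerate(counts.gene_ids)}
    is_ref = np.isin(counts.cell_ids, reference_cells)
    if not is_ref.any():
        raise ValueError("no reference cells found in the matrix")
    ref_mean = logx[is_ref].mean(axis=0)
    resid = logx - ref_mean
    # per-cell median centering: a gained block inflates the cell's library
    # size and deflates every normalized value; re-anchoring each cell on its
    # median residual restores the log2 dosage scale
    used_cols = np.array([gene_col[g] for g in pos.index])
    resid -= np.median(resid[:, used_cols], axis=1, keepdims=True)
    # the cell-median of skewed residuals is biased; re-anchor the per-gene
    # zero on the (identically centered) reference cells
    resid -= resid[is_ref].mean(axis=0)

    tumor = ~is_ref
    blocks, win_rows, win_genes = [], [], []
    for chrom, sub in pos.groupby("chrom", sort=True):
        sub = sub.sort_values("start", kind="stable")
        if len(sub) < 10:
            log.warning("chromosome %s has <10 positioned genes; excluded", chrom)
            continue
        cols = np.array([gene_col[g] for g in sub.index])
        X = resid[np.ix_(tumor, cols)]
        n_g = len(cols)
        half = window // 2
        csum = np.concatenate(
            [np.zeros((X.shape[0], 1)), np.cumsum(X, axis=1)], axis=1
        )
        lo = np.maximum(np.arange(n_g) - half, 0)
        hi = np.minimum(np.arange(n_g) + half + 1, n_g)
        win = (csum[:, hi] - csum[:, lo]) / (hi - lo)
        blocks.append(win)
        starts = sub["start"].to_numpy()
        for j in range(n_g):
            win_rows.append(
                {"chrom": chrom, "center_gene": sub.index[j],
                 "position": int(starts[j]), "n_genes": int(hi[j] - lo[j])}
            )
            win_genes.append(sub.index.to_numpy()[lo[j]:hi[j]])
    if not blocks:
        raise ValueError("no chromosome had enough positioned genes")
    values = np.clip(np.concatenate(blocks, axis=1), -clip, clip)
    return CnvProfile(
        values,
        counts.cell_ids[tumor],
        pd.DataFrame(win_rows),
        win_genes,
        reference_cells,
    )


def detect_subclones(
    profile: CnvProfile,
    cytobands: pd.DataFrame = None,
    bic_margin: float = 10.0,
    mean_separation: float = 0.2,
) -> SubcloneCall:
    """Subclone labels from multimodal chromosome-arm CNV signal.

    Per arm, the mean CNV value per cell is tested for bimodality: a
    2-component Gaussian mixture must beat 1 component by a BIC margin and
    separate its means by more than ``mean_separation``.  If any arm is
    flagged, an average-linkage hierarchy over the flagged-arm signal matrix
    is cut into 2 subclones; otherwise a single subclone is called.  Without
    a cytoband table, whole chromosomes serve as arms.
    """
    from sklearn.mixture import GaussianMixture

    win = profile.windows
    if cytobands is None:
        log.info("no cytoband table; using whole chromosomes as arms")
        arm_of = win["chrom"].to_numpy()
    else:
        cen = {
            c: sub.loc[sub["band"].str.startswith("q"), "start"].min()
            for c, sub in cytobands.groupby("chrom")
        }
        arm_of = np.array(
            [
                f"{c}{'q' if p >= cen.get(c, np.inf) else 'p'}"
                for c, p in zip(win["chrom"], win["position"])
            ]
        )
    evidence, flagged = [], []
    for arm in pd.unique(arm_of):
        signal = profile.values[:, arm_of == arm].mean(axis=1)
        x = signal.reshape(-1, 1)
        if np.allclose(signal.var(), 0):
            continue
        g1 = GaussianMixture(1, random_state=0, n_init=1).fit(x)
        g2 = GaussianMixture(2, random_state=0, n_init=5).fit(x)
        margin = g1.bic(x) - g2.bic(x)
        sep = float(abs(np.diff(g2.means_.ravel())[0]))
        if margin > bic_margin and sep > mean_separation:
            evidence.append((arm, float(margin), sep))
            flagged.append(signal)
    if not flagged:
        labels = np.zeros(len(profile.cell_ids), dtype=int)
    else:
        X = np.column_stack(flagged)
        link = hierarchy.linkage(X, method="average")
        cut = hierarchy.fcluster(link, t=2, criterion="maxclust") - 1
        # label 0 = larger subclone for stability
        if (cut == 1).sum() > (cut == 0).sum():
            cut = 1 - cut
        labels = cut
    return SubcloneCall(
        pd.Series(labels, index=pd.Index(profile.cell_ids)), evidence
    )


def classify_association(
    subclones: SubcloneCall, clustering: Clustering, cell_ids=None, purity: float = 0.9
) -> str:
    """Type the subclone/subcluster association: A, B or C.

    C: a single subclone.  A: every subclone has at least ``purity`` of its
    cells inside one transcriptomic subcluster.  B: otherwise.
    """
    labels = subclones.labels
    if cell_ids is not None:
        cluster = pd.Series(clustering.labels, index=pd.Index(cell_ids))
    else:
        if len(clustering.labels) != len(labels):
            raise ValueError("subclone and cluster label sets misaligned")
        cluster = pd.Series(clustering.labels, index=labels.index)
    missing = labels.index.difference(cluster.index)
    if len(missing):
        raise ValueError("subclone and cluster label sets misaligned")
    if subclones.n_subclones == 1:
        subclones.association_type = "C"
        return "C"
    nested = all(
        cluster.loc[labels.index[labels == s]].value_counts(normalize=True).iloc[0]
        >= purity
        for s in labels.unique()
    )
    subclones.association_type = "A" if nested else "B"
    return subclones.association_type


def hypergeometric_enrichment(
    hits_in_set: int, set_size: int, hits_total: int, universe: int
) -> float:
    """Upper-tail hypergeometric probability P(X >= hits_in_set).

    ``set_size`` items are drawn without replacement from a ``universe``
    containing ``hits_total`` marked items; X is the number of marked items
    drawn.
    """
    if not (
        0 <= hits_in_set <= min(set_size, hits_total) <= universe
        and set_size <= universe
    ):
        raise ValueError("inconsistent hypergeometric margins")
    return float(stats.hypergeom.sf(hits_in_set - 1, universe, hits_total, set_size))
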