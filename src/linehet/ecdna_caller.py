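"""ecDNA detection from scATAC-seq coverage.

ecDNA amplicons are acentric, highly amplified and broadly accessible, so
they surface in scATAC data as genomic bins whose per-cell coverage stands
far above the diploid background while lacking the promoter-concentrated
(TSS-peaked) fragment profile of ordinary chromatin.  The caller:

1. tiles the genome into fixed bins and computes per-cell *normalized
   coverage* (bin count / chromosome fragment count x 10,000);
2. estimates each cell's *reference coverage* — the first (lowest) mode of
   its nonzero bin-coverage distribution, i.e. the two-copy level — and
   derives *relative coverage* as their ratio;
3. keeps bins with relative coverage above a threshold in enough cells and
   merges consecutive bins into candidate fragments;
4. removes candidates with a promoter-like TSS enrichment score
   (±50 bp / ±2000 bp fragment-count ratio);
5. merges nearby, coverage-correlated fragments into ecDNA regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .cnv_subclones import hypergeometric_enrichment
from .io_formats import CountMatrix, FragmentSet, GeneModels

log = logging.getLogger(__name__)

__all__ = [
    "EcdnaParams",
    "BinCoverageMatrix",
    "CandidateFragment",
    "EcdnaRegion",
    "bin_coverage",
    "reference_coverage",
    "candidate_fragments",
    "tss_filter",
    "merge_correlated",
    "region_statistics",
    "call_ecdna",
]


@dataclass
class EcdnaParams:
    bin_size: int = 100_000
    rel_cov_min: float = 6.0
    rel_cov_inclusive: bool = False  # strict ">" by default
    min_cells: int = 15
    tss_max: float = 0.25
    tss_inner: int = 50
    tss_outer: int = 2000
    pcc_min: float = 0.3
    merge_fraction: float = 0.7
    vicinity: int = 1_000_000
    cluster_divisor: int = 3
    min_nonzero_bins: int = 50  # per-cell floor for reference estimation
    kde_prominence: float = 0.05  # fraction of global density maximum

    def __post_init__(self) -> None:
        if self.tss_inner >= self.tss_outer:
            raise ValueError("tss_inner must be smaller than tss_outer")
        for name in (
            "bin_size", "rel_cov_min", "min_cells", "tss_max", "pcc_min",
            "merge_fraction", "vicinity", "cluster_divisor",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class BinCoverageMatrix:
    bins: pd.DataFrame  # chrom, start, end (non-overlapping tiling)
    normalized: np.ndarray  # cells x bins
    cell_ids: np.ndarray
    reference: np.ndarray = None  # per-cell reference coverage (NaN = failed)
    relative: np.ndarray = None  # normalized / reference

    @property
    def n_cells(self) -> int:
        return self.normalized.shape[0]

    def valid_cells(self) -> np.ndarray:
        if self.reference is None:
            raise ValueError("reference coverage not yet computed")
        return ~np.isnan(self.reference)

    def high_mask(self, params: EcdnaParams) -> np.ndarray:
        """Boolean cells x bins: relative coverage beyond the ecDNA threshold."""
        with np.errstate(invalid="ignore"):
            if params.rel_cov_inclusive:
                return self.relative >= params.rel_cov_min
            return self.relative > params.rel_cov_min


@dataclass
class CandidateFragment:
    chrom: str
    start: int
    end: int
    bin_indices: np.ndarray
    tss_score: float = None


@dataclass
class EcdnaRegion:
    chrom: str
    start: int
    end: int
    member_bins: np.ndarray
    supporting_cells: pd.Series  # barcode -> max relative coverage in region
    tss_score: float
    merged_from: list = field(default_factory=list)  # (chrom, start, end)
    contains_oncogene: bool = None

    @property
    def interval(self) -> tuple:
        return (self.chrom, self.start, self.end)


# ---------------------------------------------------------------------------


def bin_coverage(fragments: FragmentSet, params: EcdnaParams = None) -> BinCoverageMatrix:
    """Per-cell normalized coverage over a fixed genome tiling.

    Each fragment is assigned to exactly one bin by its midpoint; normalized
    coverage is bin count / the cell's fragment count on that chromosome
    x 10,000, so per cell and chromosome the bins sum to exactly 10,000
    (zero where the cell has no fragments on the chromosome).
    """
    params = params or EcdnaParams()
    raw, bins, barcodes = fragments.to_bin_matrix(params.bin_size)
    normalized = np.zeros(raw.shape, dtype=float)
    chroms = bins["chrom"].to_numpy()
    for c in pd.unique(chroms):
        cols = chroms == c
        totals = raw[:, cols].sum(axis=1, keepdims=True).astype(float)
        nz = totals.ravel() > 0
        normalized[np.ix_(nz, cols)] = (
            raw[np.ix_(nz, cols)] / totals[nz] * 10_000.0
        )
    return BinCoverageMatrix(bins, normalized, np.asarray(barcodes, dtype=object))


def reference_coverage(values: np.ndarray, params: EcdnaParams = None) -> float:
    """First-mode (two-copy) coverage of one cell's nonzero bin coverages.

    A Gaussian KDE (Silverman bandwidth) is evaluated over the nonzero
    coverages; the reference is the location of the lowest-coverage local
    maximum whose density reaches ``kde_prominence`` of the global maximum.
    Returns NaN when the cell has too few nonzero bins.
    """
    params = params or EcdnaParams()
    v = np.asarray(values, dtype=float)
    v = v[v > 0]
    if v.size < params.min_nonzero_bins:
        return float("nan")
    if np.allclose(v, v[0]):
        return float(v[0])
    kde = stats.gaussian_kde(v, bw_method="silverman")
    grid = np.linspace(0.0, v.max() * 1.05, 512)
    dens = kde(grid)
    padded = np.concatenate([[0.0], dens, [0.0]])
    peaks, _ = signal.find_peaks(padded, height=params.kde_prominence * dens.max())
    if peaks.size == 0:
        return float(grid[np.argmax(dens)])
    return float(grid[peaks[0] - 1])


def compute_relative(matrix: BinCoverageMatrix, params: EcdnaParams = None) -> BinCoverageMatrix:
    """Fill per-cell reference and relative coverage in place."""
    params = params or EcdnaParams()
    ref = np.array(
        [reference_coverage(row, params) for row in matrix.normalized]
    )
    n_fail = int(np.isnan(ref).sum())
    if n_fail:
        log.info("%d cells excluded from calling (reference peak not estimable)", n_fail)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = matrix.normalized / ref[:, None]
    matrix.reference = ref
    matrix.relative = rel
    return matrix


def candidate_fragments(matrix: BinCoverageMatrix, params: EcdnaParams = None) -> list:
    """High-coverage bins recurring across cells, merged when consecutive.

    A bin is *high* in a cell when its relative coverage exceeds
    ``rel_cov_min``; bins high in more than ``min_cells`` cells are retained
    and runs of genomically consecutive retained bins become candidate
    fragments.
    """
    params = params or EcdnaParams()
    if matrix.relative is None:
        compute_relative(matrix, params)
    high = matrix.high_mask(params)
    n_high = np.nansum(high[matrix.valid_cells()], axis=0)
    retained = np.flatnonzero(n_high > params.min_cells)
    out: list = []
    bins = matrix.bins
    run: list = []
    for b in retained:
        if run and (
            b != run[-1] + 1 or bins["chrom"].iat[b] != bins["chrom"].iat[run[-1]]
        ):
            out.append(run)
            run = []
        run.append(int(b))
    if run:
        out.append(run)
    return [
        CandidateFragment(
            bins["chrom"].iat[r[0]],
            int(bins["start"].iat[r[0]]),
            int(bins["end"].iat[r[-1]]),
            np.asarray(r),
        )
        for r in out
    ]


def _tss_score_for_interval(
    chrom: str,
    start: int,
    end: int,
    support_barcodes: set,
    fragment_set: FragmentSet,
    gene_models: GeneModels,
    params: EcdnaParams,
) -> float:
    """TSS enrichment of pooled supporting-cell fragments inside an interval.

    Counts fragment midpoints inside ±tss_inner / ±tss_outer windows of the
    TSSs located within the interval; returns inner/outer, and 0 when the
    interval holds no TSS fragments at all (maximally non-promoter-like).
    """
    rec = fragment_set.records
    mids = (rec["start"].to_numpy() + rec["end"].to_numpy()) // 2
    sel = (
        (rec["chrom"].to_numpy() == chrom)
        & (mids >= start)
        & (mids < end)
        & rec["barcode"].isin(support_barcodes).to_numpy()
    )
    m = np.sort(mids[sel])
    tss_all = gene_models.tss_by_chrom().get(chrom, np.empty(0, dtype=np.int64))
    tss = tss_all[(tss_all >= start) & (tss_all < end)]
    if m.size == 0 or tss.size == 0:
        return 0.0

    def count_within(half):
        lo = np.searchsorted(m, tss - half, side="left")
        hi = np.searchsorted(m, tss + half, side="right")
        covered = np.zeros(m.size + 1, dtype=np.int64)
        np.add.at(covered, lo, 1)
        np.add.at(covered, hi, -1)
        return int((np.cumsum(covered)[:-1] > 0).sum())

    outer = count_within(params.tss_outer)
    if outer == 0:
        return 0.0
    return count_within(params.tss_inner) / outer


def _supporting(matrix: BinCoverageMatrix, bins: np.ndarray, params: EcdnaParams):
    high = matrix.high_mask(params)
    mask = np.nansum(high[:, bins], axis=1) > 0
    mask &= matrix.valid_cells()
    return mask


def tss_filter(
    candidates: list,
    fragment_set: FragmentSet,
    gene_models: GeneModels,
    matrix: BinCoverageMatrix,
    params: EcdnaParams = None,
) -> list:
    """Annotate candidates with a TSS enrichment score and keep the broad ones.

    Pools fragments of each candidate's supporting cells inside its interval;
    candidates with score < ``tss_max`` survive (promoter-concentrated,
    CNV/random-like regions are removed).
    """
    params = params or EcdnaParams()
    kept = []
    for cand in candidates:
        support = set(matrix.cell_ids[_supporting(matrix, cand.bin_indices, params)])
        cand.tss_score = _tss_score_for_interval(
            cand.chrom, cand.start, cand.end, support,
            fragment_set, gene_models, params,
        )
        if cand.tss_score < params.tss_max:
            kept.append(cand)
    return kept


def merge_correlated(
    candidates: list,
    matrix: BinCoverageMatrix,
    params: EcdnaParams = None,
    fragment_set: FragmentSet = None,
    gene_models: GeneModels = None,
) -> list:
    """Merge nearby, coverage-correlated candidate fragments into regions.

    Pearson correlations are computed between candidates' per-cell mean
    relative coverage; an average-linkage hierarchy on 1 - PCC is cut into
    ceil(n / cluster_divisor) clusters.  A cluster is merged into one region
    when more than ``merge_fraction`` of its fragment pairs have
    PCC > ``pcc_min`` and all members lie mutually within ``vicinity`` on the
    same chromosome; other fragments pass through as singleton regions.
    Merged regions get a recomputed TSS score when the fragment data are
    supplied.
    """
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import squareform

    params = params or EcdnaParams()
    valid = matrix.valid_cells()

    def make_region(chrom, start, end, bin_idx, score, merged_from):
        mask = _supporting(matrix, bin_idx, params)
        with np.errstate(invalid="ignore"):
            cov = np.nanmax(matrix.relative[np.ix_(mask, bin_idx)], axis=1)
        return EcdnaRegion(
            chrom, start, end, bin_idx,
            pd.Series(cov, index=pd.Index(matrix.cell_ids[mask])),
            score, merged_from,
        )

    if not candidates:
        return []
    if len(candidates) == 1:
        c = candidates[0]
        return [make_region(c.chrom, c.start, c.end, c.bin_indices, c.tss_score, [])]

    prof = np.vstack(
        [
            np.nanmean(matrix.relative[np.ix_(valid, c.bin_indices)], axis=1)
            for c in candidates
        ]
    )
    with np.errstate(invalid="ignore"):
        pcc = np.corrcoef(prof)
    pcc = np.nan_to_num(pcc, nan=0.0)
    np.fill_diagonal(pcc, 1.0)
    dist = np.clip(1.0 - pcc, 0.0, 2.0)
    n = len(candidates)
    n_clusters = int(np.ceil(n / params.cluster_divisor))
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    assignment = hierarchy.fcluster(link, t=n_clusters, criterion="maxclust")

    regions: list = []
    for cid in np.unique(assignment):
        idx = np.flatnonzero(assignment == cid)
        members = [candidates[i] for i in idx]
        mergeable = False
        if len(members) > 1:
            pairs = [(a, b) for i, a in enumerate(idx) for b in idx[i + 1 :]]
            good = sum(pcc[a, b] > params.pcc_min for a, b in pairs)
            same_chrom = len({m.chrom for m in members}) == 1
            near = same_chrom and all(
                max(members[i].start, members[j].start)
                - min(members[i].end, members[j].end)
                < params.vicinity
                for i in range(len(members))
                for j in range(i + 1, len(members))
            )
            mergeable = good > params.merge_fraction * len(pairs) and near
        if mergeable:
            chrom = members[0].chrom
            start = min(m.start for m in members)
            end = max(m.end for m in members)
            bin_idx = np.sort(np.concatenate([m.bin_indices for m in members]))
            if fragment_set is not None and gene_models is not None:
                support = set(matrix.cell_ids[_supporting(matrix, bin_idx, params)])
                score = _tss_score_for_interval(
                    chrom, start, end, support, fragment_set, gene_models, params
                )
            else:
                score = float(np.mean([m.tss_score for m in members]))
            if score < params.tss_max:
                regions.append(
                    make_region(
                        chrom, start, end, bin_idx, score,
                        [(m.chrom, m.start, m.end) for m in members],
                    )
                )
        else:
            for m in members:
                regions.append(
                    make_region(m.chrom, m.start, m.end, m.bin_indices, m.tss_score, [])
                )
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def call_ecdna(
    fragments: FragmentSet,
    gene_models: GeneModels,
    params: EcdnaParams = None,
):
    """End-to-end ecDNA calling; returns (regions, coverage matrix)."""
    params = params or EcdnaParams()
    matrix = bin_coverage(fragments, params)
    compute_relative(matrix, params)
    cands = candidate_fragments(matrix, params)
    cands = tss_filter(cands, fragments, gene_models, matrix, params)
    regions = merge_correlated(cands, matrix, params, fragments, gene_models)
    return regions, matrix


# ---------------------------------------------------------------------------
# downstream statistics


def region_statistics(
    regions: list,
    matrix: BinCoverageMatrix,
    gene_models: GeneModels = None,
    oncogene_list=None,
    counts_rna: CountMatrix = None,
    params: EcdnaParams = None,
) -> pd.DataFrame:
    """Per-region report: cell support, oncogene enrichment, RNA coupling.

    Supporting-cell fraction uses cells with an estimable reference peak as
    the denominator.  Oncogene enrichment is a one-tailed hypergeometric test
    of oncogenes among region-resident genes against the gene universe.  With
    an RNA matrix sharing barcodes, the Spearman correlation between per-cell
    region coverage and summed resident-gene expression is reported; with
    unmatched cells, the positive-cell fraction is compared with the
    high-expressing-cell fraction instead.
    """
    params = params or EcdnaParams()
    n_valid = int(matrix.valid_cells().sum())
    onco = set(oncogene_list) if oncogene_list is not None else None
    rows = []
    for i, region in enumerate(regions):
        row = {
            "region": f"{region.chrom}:{region.start}-{region.end}",
            "n_supporting_cells": len(region.supporting_cells),
            "supporting_fraction": len(region.supporting_cells) / max(n_valid, 1),
            "tss_score": region.tss_score,
        }
        resident = None
        if gene_models is not None:
            g = gene_models.genes
            inside = (
                (g["chrom"] == region.chrom)
                & (g["start"] < region.end)
                & (g["end"] > region.start)
            )
            resident = list(g.loc[inside, "gene_id"])
            row["n_genes"] = len(resident)
            if onco is not None:
                if resident:
                    universe = len(g)
                    hits_total = len(onco & set(g["gene_id"]))
                    hits = len(onco & set(resident))
                    row["oncogene_p"] = hypergeometric_enrichment(
                        hits, len(resident), hits_total, universe
                    )
                    region.contains_oncogene = hits > 0
                else:
                    log.warning("region %s holds no genes; enrichment skipped", row["region"])
        if counts_rna is not None and resident:
            gene_idx = {g_: j for j, g_ in enumerate(counts_rna.gene_ids)}
            cols = [gene_idx[g_] for g_ in resident if g_ in gene_idx]
            if cols:
                from .cluster_core import log_normalize

                expr = log_normalize(counts_rna.counts, log=False)[:, cols].sum(axis=1)
                shared = np.isin(counts_rna.cell_ids, matrix.cell_ids)
                if shared.any():
                    pos = {b: j for j, b in enumerate(matrix.cell_ids)}
                    sel = np.flatnonzero(shared)
                    cov = np.nanmean(
                        matrix.relative[
                            np.ix_(
                                [pos[counts_rna.cell_ids[j]] for j in sel],
                                region.member_bins,
                            )
                        ],
                        axis=1,
                    )
                    e = expr[sel]
                    ok = ~np.isnan(cov)
                    if np.ptp(cov[ok]) > 0 and np.ptp(e[ok]) > 0:
                        rho, p = stats.spearmanr(cov[ok], e[ok])
                        row["expression_spearman"] = float(rho)
                        row["expression_p"] = float(p)
                else:
                    thr = expr.mean() + 2 * expr.std()
                    row["high_expression_fraction"] = float((expr > thr).mean())
        rows.append(row)
    return pd.DataFrame(rows)
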