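"""Synthetic single-cell multi-omic data with known ground truth.

The RNA generator emits UMI count matrices with cell-line structure
(line-specific marker blocks over a shared Gamma-distributed baseline),
CNV subclones (dosage multipliers over contiguous gene blocks) and
heterogeneously active gene programs, under a Gamma-Poisson (negative
binomial) noise law.  The ATAC generator emits fragment files with a diploid
Poisson background, TSS-concentrated accessibility, chromosomal CNVs and
high-copy, broadly accessible ecDNA amplicons carried by random cell subsets
(stochastic segregation).  Every generator is a pure function of
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CountMatrix, FragmentSet, GeneModels
import scipy.sparse as sp

__all__ = [
    "RnaSimConfig",
    "ProgramSpec",
    "AtacSimConfig",
    "EcdnaSpec",
    "CnvSpec",
    "ResponseSpec",
    "TruthTables",
    "simulate_rna",
    "simulate_atac",
    "simulate_condition_pair",
]


@dataclass
class ProgramSpec:
    """A heterogeneously active expression module."""

    n_genes: int = 50
    active_fraction: float = 0.3
    log2_fold: float = 2.0
    lines: tuple = (0,)
    name: str = "program"
    gene_range: tuple = None  # optional (lo, hi) index window to draw genes from


@dataclass
class RnaSimConfig:
    n_cell_lines: int = 3
    cells_per_line: int = 500
    n_genes: int = 2000
    baseline_shape: float = 0.25  # per-gene Gamma shape for baseline means
    baseline_scale: float = 8.0
    dispersion: float = 2.0  # NB inverse-dispersion (gamma shape)
    line_markers: tuple = (100, 8.0)  # (genes per line, fold)
    # line -> list of (cell fraction, [((g0, g1), dosage multiplier), ...])
    subclone_spec: dict = field(default_factory=dict)
    program_spec: list = field(default_factory=list)
    n_chroms: int = 2
    seed: int = 0

    def validate(self) -> None:
        for line, subs in self.subclone_spec.items():
            total = sum(f for f, _ in subs)
            if not all(0 < f <= 1 for f, _ in subs) or total > 1:
                raise ValueError(f"subclone fractions of line {line} invalid")
            for _, blocks in subs:
                for (g0, g1), mult in blocks:
                    if not (0 <= g0 < g1 <= self.n_genes):
                        raise ValueError("CNV block outside gene range")
                    if mult <= 0:
                        raise ValueError("dosage multiplier must be > 0")
        for p in self.program_spec:
            if p.n_genes > self.n_genes:
                raise ValueError("program gene set exceeds n_genes")


@dataclass
class EcdnaSpec:
    chrom: str = "chr1"
    start: int = 0
    end: int = 100_000
    multiplier: float = 8.0  # copy multiplier, >= 6 for a bona fide amplicon
    fraction: float = 0.4  # positive-cell fraction (stochastic segregation)
    uniform: bool = True  # broadly accessible (ecDNA-like) vs TSS-concentrated


@dataclass
class CnvSpec:
    chrom: str = "chr1"
    start: int = 0
    end: int = 100_000
    multiplier: float = 2.5
    fraction: float = 0.5


@dataclass
class AtacSimConfig:
    chrom_sizes: dict = field(default_factory=lambda: {"chr1": 30_000_000, "chr2": 30_000_000})
    cells: int = 500
    background_rate: float = 3.0  # expected fragments / 100-kb bin / cell
    tss_every: int = 25_000  # TSS spacing when tss_positions is None
    tss_positions: dict = None  # chrom -> array of TSS bp
    tss_concentration: float = 0.5  # fraction of background fragments at TSS
    ecdna_spec: list = field(default_factory=list)
    cnv_spec: list = field(default_factory=list)
    dropout_intervals: list = field(default_factory=list)  # (chrom, start, end)
    bin_size: int = 100_000
    fragment_length: int = 150
    seed: int = 0

    def validate(self) -> None:
        for s in list(self.ecdna_spec) + list(self.cnv_spec):
            if s.chrom not in self.chrom_sizes or not (
                0 <= s.start < s.end <= self.chrom_sizes[s.chrom]
            ):
                raise ValueError(f"interval outside chrom_sizes: {s}")
            if s.multiplier < 1:
                raise ValueError("copy multipliers must be >= 1")
        for e in self.ecdna_spec:
            for c in self.cnv_spec:
                if e.chrom == c.chrom and e.start < c.end and c.start < e.end:
                    raise ValueError("overlapping ecDNA and CNV intervals")


@dataclass
class ResponseSpec:
    """Condition response: a global shift plus a latent-subgroup module."""

    n_global_genes: int = 0
    global_log2_fold: float = 1.5
    latent_line: int = 0
    latent_fraction: float = 0.0  # hidden responder fraction within that line
    n_latent_genes: int = 0
    latent_log2_fold: float = 2.5


@dataclass
class TruthTables:
    """Ground truth emitted alongside each simulated dataset."""

    cells: pd.DataFrame = None
    line_markers: dict = None
    programs: dict = None
    cnv_blocks: pd.DataFrame = None
    reference_profiles: pd.DataFrame = None  # line x gene expected bulk means
    ecdna_cells: dict = None  # region name -> positive barcode array
    ecdna_regions: pd.DataFrame = None
    cnv_cells: dict = None
    response_genes: dict = None


# ---------------------------------------------------------------------------
# RNA


def _rna_means(config: RnaSimConfig, rng: np.random.Generator):
    """Per-cell x per-gene Gamma-Poisson mean matrix plus truth annotations."""
    n_lines, n_cells = config.n_cell_lines, config.cells_per_line
    n_genes = config.n_genes
    baseline = rng.gamma(config.baseline_shape, config.baseline_scale, n_genes)
    baseline = np.maximum(baseline, 1e-3)

    n_mark, mark_fold = config.line_markers
    perm = rng.permutation(n_genes)
    markers = {
        line: np.sort(perm[line * n_mark : (line + 1) * n_mark])
        for line in range(n_lines)
    }
    free = np.sort(perm[n_lines * n_mark :])  # genes free for programs

    programs = {}
    for p in config.program_spec:
        pool = free
        if p.gene_range is not None:
            lo, hi = p.gene_range
            pool = free[(free >= lo) & (free < hi)]
        genes = np.sort(rng.choice(pool, size=p.n_genes, replace=False))
        programs[p.name] = genes

    total = n_lines * n_cells
    line_of = np.repeat(np.arange(n_lines), n_cells)
    cell_ids = np.array(
        [f"L{line_of[i]}_{i:05d}" for i in range(total)], dtype=object
    )
    means = np.tile(baseline, (total, 1))
    for line, g in markers.items():
        means[np.ix_(line_of == line, g)] *= mark_fold

    subclone = np.zeros(total, dtype=int)
    cnv_rows = []
    for line, subs in config.subclone_spec.items():
        cells = np.flatnonzero(line_of == line)
        start = 0
        for s_idx, (frac, blocks) in enumerate(subs, start=1):
            n_s = int(round(frac * cells.size))
            members = cells[start : start + n_s]
            start += n_s
            subclone[members] = s_idx
            for (g0, g1), mult in blocks:
                means[np.ix_(members, np.arange(g0, g1))] *= mult
                cnv_rows.append(
                    {"line": line, "subclone": s_idx, "gene_lo": g0,
                     "gene_hi": g1, "multiplier": mult}
                )

    cell_truth = pd.DataFrame(
        {"line": line_of, "subclone": subclone}, index=pd.Index(cell_ids)
    )
    for p in config.program_spec:
        active = np.zeros(total, dtype=bool)
        in_lines = np.isin(line_of, list(p.lines))
        active[in_lines] = rng.random(in_lines.sum()) < p.active_fraction
        means[np.ix_(active, programs[p.name])] *= 2.0 ** p.log2_fold
        cell_truth[f"active_{p.name}"] = active

    ref = pd.DataFrame(
        np.vstack([means[line_of == line].mean(axis=0) for line in range(n_lines)]),
        index=[f"line{line}" for line in range(n_lines)],
    )
    truth = TruthTables(
        cells=cell_truth,
        line_markers=markers,
        programs=programs,
        cnv_blocks=pd.DataFrame(
            cnv_rows, columns=["line", "subclone", "gene_lo", "gene_hi", "multiplier"]
        ),
        reference_profiles=ref,
    )
    return means, cell_ids, line_of, truth


def _sample_counts(means: np.ndarray, dispersion: float, rng: np.random.Generator):
    lam = rng.gamma(dispersion, means / dispersion)
    return rng.poisson(lam)


def _gene_meta(n_genes: int, n_chroms: int) -> pd.DataFrame:
    per = int(np.ceil(n_genes / n_chroms))
    chrom = [f"chr{i // per + 1}" for i in range(n_genes)]
    pos = [(i % per) * 10_000 for i in range(n_genes)]
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": pos,
            "end": [p + 1_000 for p in pos],
            "strand": "+",
        },
        index=pd.Index([f"gene{i:04d}" for i in range(n_genes)]),
    )


def simulate_rna(config: RnaSimConfig):
    """Draw a :class:`CountMatrix` and its :class:`TruthTables`.

    Counts are Gamma-Poisson with mean = baseline x line-marker fold x CNV
    dosage x program activity; reproducible bitwise from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    means, cell_ids, line_of, truth = _rna_means(config, rng)
    counts = _sample_counts(means, config.dispersion, rng)
    gene_meta = _gene_meta(config.n_genes, config.n_chroms)
    cell_meta = truth.cells.copy()
    cell_meta["cell_line"] = [f"line{line}" for line in line_of]
    cm = CountMatrix(
        sp.csr_matrix(counts),
        cell_ids,
        gene_meta.index.to_numpy(dtype=object),
        cell_meta,
        gene_meta,
    )
    truth.reference_profiles.columns = cm.gene_ids
    for key in ("line_markers", "programs"):
        mapping = getattr(truth, key)
        setattr(
            truth, key,
            {k: cm.gene_ids[np.asarray(v)] for k, v in mapping.items()},
        )
    return cm, truth


# ---------------------------------------------------------------------------
# ATAC


def _tile(chrom_sizes: dict, bin_size: int) -> pd.DataFrame:
    rows = []
    for c in sorted(chrom_sizes):
        size = chrom_sizes[c]
        for i in range(int(np.ceil(size / bin_size))):
            rows.append((c, i * bin_size, min((i + 1) * bin_size, size)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def simulate_atac(config: AtacSimConfig):
    """Draw a fragment file with implanted CNVs and ecDNA amplicons.

    Per cell, fragment counts per bin are Poisson(background_rate x regional
    multiplier).  Background fragments land in ±50 bp TSS windows with
    probability ``tss_concentration``; fragments in ecDNA bins of positive
    cells are placed uniformly (broad accessibility).  Returns
    ``(FragmentSet, GeneModels, TruthTables)``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    bins = _tile(config.chrom_sizes, config.bin_size)
    n_bins, n_cells = len(bins), config.cells
    barcodes = np.array([f"BC{i:05d}" for i in range(n_cells)], dtype=object)

    # TSS layout and gene models
    tss = config.tss_positions
    if tss is None:
        tss = {
            c: np.arange(10_000, size - 10_000, config.tss_every)
            for c, size in config.chrom_sizes.items()
        }
    gene_rows = []
    for c in sorted(tss):
        for k, t in enumerate(np.sort(np.asarray(tss[c]))):
            gene_rows.append((f"g_{c}_{k}", c, int(t), int(t) + 500, "+"))
    models = GeneModels(
        pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    )

    bstart = bins["start"].to_numpy()
    bend = bins["end"].to_numpy()
    bchrom = bins["chrom"].to_numpy()

    def overlapping(chrom, start, end):
        return np.flatnonzero((bchrom == chrom) & (bstart < end) & (bend > start))

    lam = np.full((n_cells, n_bins), float(config.background_rate))
    uniform_mask = np.zeros((n_cells, n_bins), dtype=bool)
    ecdna_cells, region_rows = {}, []
    for i, e in enumerate(config.ecdna_spec):
        name = f"ecdna_{i}"
        pos = rng.random(n_cells) < e.fraction
        b = overlapping(e.chrom, e.start, e.end)
        lam[np.ix_(pos, b)] *= e.multiplier
        if e.uniform:
            uniform_mask[np.ix_(pos, b)] = True
        ecdna_cells[name] = barcodes[pos]
        region_rows.append(
            {"name": name, "chrom": e.chrom, "start": e.start, "end": e.end,
             "multiplier": e.multiplier, "n_positive": int(pos.sum())}
        )
    cnv_cells = {}
    for i, c in enumerate(config.cnv_spec):
        pos = rng.random(n_cells) < c.fraction
        b = overlapping(c.chrom, c.start, c.end)
        lam[np.ix_(pos, b)] *= c.multiplier
        cnv_cells[f"cnv_{i}"] = barcodes[pos]

    counts = rng.poisson(lam)
    flat = counts.ravel()
    nz = np.flatnonzero(flat)
    reps = flat[nz]
    cell_idx = np.repeat(nz // n_bins, reps)
    bin_idx = np.repeat(nz % n_bins, reps)
    n_frag = cell_idx.size

    # ragged TSS-per-bin lookup (CSR layout over bins)
    tss_flat, tss_off = [], np.zeros(n_bins + 1, dtype=np.int64)
    for j in range(n_bins):
        arr = tss.get(bchrom[j], np.empty(0, dtype=np.int64))
        arr = np.asarray(arr)
        inside = arr[(arr >= bstart[j]) & (arr < bend[j])]
        tss_flat.append(inside)
        tss_off[j + 1] = tss_off[j] + inside.size
    tss_flat = (
        np.concatenate(tss_flat) if tss_flat else np.empty(0, dtype=np.int64)
    )
    n_tss_bin = np.diff(tss_off)

    u_place = rng.random(n_frag)
    u_pick = rng.random(n_frag)
    at_tss = (
        (u_place < config.tss_concentration)
        & ~uniform_mask[cell_idx, bin_idx]
        & (n_tss_bin[bin_idx] > 0)
    )
    mids = np.empty(n_frag, dtype=np.int64)
    # uniform placement within the bin
    span = bend[bin_idx] - bstart[bin_idx]
    mids[:] = bstart[bin_idx] + (u_pick * span).astype(np.int64)
    # TSS-window placement (+-50 bp around a uniformly chosen TSS of the bin)
    sel = np.flatnonzero(at_tss)
    if sel.size:
        k = (u_pick[sel] * n_tss_bin[bin_idx[sel]]).astype(np.int64)
        chosen = tss_flat[tss_off[bin_idx[sel]] + k]
        mids[sel] = chosen + rng.integers(-50, 51, size=sel.size)

    half = config.fragment_length // 2
    chrom_arr = bchrom[bin_idx]
    sizes = np.array([config.chrom_sizes[c] for c in chrom_arr])
    start = np.clip(mids - half, 0, sizes - config.fragment_length)
    end = start + config.fragment_length

    keep = np.ones(n_frag, dtype=bool)
    for (c, s, e) in config.dropout_intervals:
        keep &= ~((chrom_arr == c) & (mids >= s) & (mids < e))

    records = pd.DataFrame(
        {
            "chrom": chrom_arr[keep],
            "start": start[keep],
            "end": end[keep],
            "barcode": barcodes[cell_idx[keep]],
            "dup_count": 1,
        }
    )
    frags = FragmentSet(records, dict(config.chrom_sizes))
    truth = TruthTables(
        cells=pd.DataFrame({"barcode": barcodes}).set_index("barcode"),
        ecdna_cells=ecdna_cells,
        ecdna_regions=pd.DataFrame(
            region_rows,
            columns=["name", "chrom", "start", "end", "multiplier", "n_positive"],
        ),
        cnv_cells=cnv_cells,
    )
    return frags, models, truth


# ---------------------------------------------------------------------------
# condition pairs


def simulate_condition_pair(base: RnaSimConfig, response: ResponseSpec, seed: int = None):
    """Control and treated matrices over the same cell population.

    The treated matrix applies a global response shift to all cells plus an
    extra module shift to a hidden fraction of one line's cells; the truth
    table marks the latent subgroup.
    """
    base.validate()
    if response.latent_fraction and not (0 < response.latent_fraction < 1):
        raise ValueError("latent fraction must lie in (0, 1)")
    rng = np.random.default_rng(base.seed if seed is None else seed)
    means, cell_ids, line_of, truth = _rna_means(base, rng)
    gene_meta = _gene_meta(base.n_genes, base.n_chroms)
    gene_ids = gene_meta.index.to_numpy(dtype=object)

    n_genes = base.n_genes
    pool = rng.permutation(n_genes)
    g_global = np.sort(pool[: response.n_global_genes])
    g_latent = np.sort(
        pool[response.n_global_genes : response.n_global_genes + response.n_latent_genes]
    )
    latent = np.zeros(len(cell_ids), dtype=bool)
    if response.latent_fraction and response.n_latent_genes:
        members = np.flatnonzero(line_of == response.latent_line)
        latent[members] = rng.random(members.size) < response.latent_fraction

    treated_means = means.copy()
    if g_global.size:
        treated_means[:, g_global] *= 2.0 ** response.global_log2_fold
    if g_latent.size:
        treated_means[np.ix_(latent, g_latent)] *= 2.0 ** response.latent_log2_fold

    counts_ctrl = _sample_counts(means, base.dispersion, rng)
    counts_trt = _sample_counts(treated_means, base.dispersion, rng)

    meta = truth.cells.copy()
    meta["cell_line"] = [f"line{line}" for line in line_of]
    meta["latent_responder"] = latent

    def pack(counts, condition):
        m = meta.copy()
        m["condition"] = condition
        return CountMatrix(sp.csr_matrix(counts), cell_ids, gene_ids, m, gene_meta)

    truth.cells = meta
    truth.response_genes = {
        "global": gene_ids[g_global],
        "latent": gene_ids[g_latent],
    }
    truth.reference_profiles.columns = gene_ids
    return pack(counts_ctrl, "control"), pack(counts_trt, "treated"), truth
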