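"""Readers/writers for the on-disk formats the pipeline touches, plus QC.

Two root containers feed every downstream stage: :class:`CountMatrix` for the
scRNA-seq modality (sparse cell x gene UMI counts, Matrix Market on disk) and
:class:`FragmentSet` for the scATAC-seq modality (barcoded genomic intervals,
tab-delimited fragments files).  All genomic coordinates are 0-based
half-open internally; GTF input (1-based closed) is converted on read.
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

log = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "CountMatrix",
    "FragmentSet",
    "GeneModels",
    "QcParams",
    "read_counts",
    "write_counts",
    "read_fragments",
    "write_fragments",
    "read_gene_models",
    "apply_qc",
    "pool_count_matrices",
    "midpoints_in_tss_windows",
]


class FormatError(ValueError):
    """A file violated the contract of its declared format."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class CountMatrix:
    """Sparse cell x gene UMI count matrix with aligned metadata.

    ``counts`` is CSR with cells as rows.  ``cell_meta`` / ``gene_meta`` are
    indexed by the corresponding id arrays; ``gene_meta`` carries
    chrom/start/end/strand columns when genomic positions are known.
    """

    counts: sp.csr_matrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    cell_meta: pd.DataFrame = None
    gene_meta: pd.DataFrame = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        n, g = self.counts.shape
        if len(self.cell_ids) != n or len(self.gene_ids) != g:
            raise FormatError(
                f"id/matrix mismatch: {n}x{g} counts, "
                f"{len(self.cell_ids)} cells, {len(self.gene_ids)} genes"
            )
        if len(set(self.cell_ids)) != n:
            raise FormatError("duplicate cell identifiers")
        if len(set(self.gene_ids)) != g:
            raise FormatError("duplicate gene identifiers")
        if self.counts.nnz and (
            not np.isfinite(self.counts.data).all() or (self.counts.data < 0).any()
        ):
            raise FormatError("counts must be finite and non-negative")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cell_ids))
        else:
            self.cell_meta = self.cell_meta.loc[list(self.cell_ids)]
        if self.gene_meta is None:
            self.gene_meta = pd.DataFrame(index=pd.Index(self.gene_ids))
        else:
            self.gene_meta = self.gene_meta.loc[list(self.gene_ids)]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, mask) -> "CountMatrix":
        """Row subset by boolean mask or integer index, preserving order."""
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            self.counts[idx],
            self.cell_ids[idx],
            self.gene_ids,
            self.cell_meta.iloc[idx],
            self.gene_meta,
        )

    def subset_genes(self, mask) -> "CountMatrix":
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            self.counts[:, idx],
            self.cell_ids,
            self.gene_ids[idx],
            self.cell_meta,
            self.gene_meta.iloc[idx],
        )

    def to_anndata(self):
        import anndata

        return anndata.AnnData(
            X=self.counts.astype(np.float32),
            obs=self.cell_meta.copy(),
            var=self.gene_meta.copy(),
        )


@dataclass
class FragmentSet:
    """Barcoded accessible-chromatin fragments (0-based half-open).

    ``records`` has columns chrom/start/end/barcode/dup_count sorted by
    (chrom, start); ``chrom_sizes`` maps chromosome name to length in bp.
    """

    records: pd.DataFrame
    chrom_sizes: dict

    def __post_init__(self) -> None:
        cols = ["chrom", "start", "end", "barcode", "dup_count"]
        self.records = self.records[cols].reset_index(drop=True)
        self.records = self.records.sort_values(
            ["chrom", "start"], kind="stable"
        ).reset_index(drop=True)

    @property
    def n_fragments(self) -> int:
        return len(self.records)

    def barcodes(self) -> np.ndarray:
        """Distinct barcodes in first-appearance order of the sorted records."""
        return self.records["barcode"].unique()

    def fragment_counts(self) -> pd.Series:
        """Unique-fragment count per barcode (each record counts once)."""
        return self.records.groupby("barcode", sort=False).size()

    def subset_barcodes(self, keep) -> "FragmentSet":
        keep = set(keep)
        sub = self.records[self.records["barcode"].isin(keep)]
        return FragmentSet(sub.copy(), dict(self.chrom_sizes))

    def midpoints(self) -> pd.Series:
        return (self.records["start"] + self.records["end"]) // 2

    def to_bin_matrix(self, bin_size: int = 100_000):
        """Cell x bin raw fragment counts, fragments assigned by midpoint.

        Returns ``(counts, bins, barcodes)`` where ``bins`` is a DataFrame of
        (chrom, start, end) tiling every chromosome without overlap.
        """
        chroms = sorted(self.chrom_sizes)
        rows, offset = [], {}
        for c in chroms:
            size = self.chrom_sizes[c]
            nb = int(np.ceil(size / bin_size))
            offset[c] = len(rows)
            for i in range(nb):
                rows.append((c, i * bin_size, min((i + 1) * bin_size, size)))
        bins = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        barcodes = np.sort(self.records["barcode"].unique())
        bc_index = {b: i for i, b in enumerate(barcodes)}
        mat = np.zeros((len(barcodes), len(bins)), dtype=np.int64)
        rec = self.records
        known = rec["chrom"].isin(offset)
        rec = rec[known]
        mids = ((rec["start"] + rec["end"]) // 2).to_numpy()
        bin_idx = (
            rec["chrom"].map(offset).to_numpy() + (mids // bin_size)
        ).astype(np.int64)
        cell_idx = rec["barcode"].map(bc_index).to_numpy()
        np.add.at(mat, (cell_idx, bin_idx), 1)
        return mat, bins, barcodes


@dataclass
class GeneModels:
    """Gene intervals with a strand-aware single-bp TSS per gene."""

    genes: pd.DataFrame  # gene_id, chrom, start, end, strand

    def __post_init__(self) -> None:
        g = self.genes.reset_index(drop=True)
        if (~g["strand"].isin(["+", "-"])).any():
            raise FormatError("gene strand must be '+' or '-' (TSS undeterminable)")
        dup = g["gene_id"].duplicated()
        if dup.any():
            log.warning("collapsing %d duplicate gene_ids to first occurrence", dup.sum())
            g = g[~dup].reset_index(drop=True)
        g["tss"] = np.where(g["strand"] == "+", g["start"], g["end"] - 1)
        self.genes = g

    @property
    def tss(self) -> pd.Series:
        return self.genes["tss"]

    def tss_by_chrom(self) -> dict:
        """chrom -> sorted array of TSS positions."""
        return {
            c: np.sort(sub["tss"].to_numpy())
            for c, sub in self.genes.groupby("chrom")
        }


@dataclass
class QcParams:
    min_umi: int = 1000
    min_genes: int = 500
    min_fragments: int = 1000
    min_tss_proportion: float = 4.0

    def __post_init__(self) -> None:
        for name in ("min_umi", "min_genes", "min_fragments", "min_tss_proportion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


# ---------------------------------------------------------------------------
# readers / writers


def _read_table(path, **kw):
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        return pd.read_csv(fh, sep="\t", header=None, comment="#", **kw)


def read_counts(mtx_path, barcodes_path, features_path, cells_as_rows=None) -> CountMatrix:
    """Read a Matrix Market count matrix with its barcode/feature sidecars.

    Cells are returned as rows regardless of on-disk orientation; the
    orientation is inferred from the dimensions.  For a square matrix the
    caller must disambiguate with ``cells_as_rows``.
    """
    mat = scipy.io.mmread(mtx_path)
    barcodes = _read_table(barcodes_path)[0].astype(str).to_numpy()
    features = _read_table(features_path)[0].astype(str).to_numpy()
    data = mat.tocoo().data
    if data.size and not np.allclose(data, np.round(data)):
        raise FormatError("count matrix contains non-integer entries")
    n_bc, n_ft = len(barcodes), len(features)
    if mat.shape == (n_bc, n_ft) and mat.shape == (n_ft, n_bc):
        if cells_as_rows is None:
            raise FormatError(
                "square matrix with equal barcode/feature counts: "
                "pass cells_as_rows explicitly"
            )
        if not cells_as_rows:
            mat = mat.T
    elif mat.shape == (n_bc, n_ft):
        pass
    elif mat.shape == (n_ft, n_bc):
        mat = mat.T
    else:
        raise FormatError(
            f"matrix shape {mat.shape} matches neither {n_bc} barcodes x "
            f"{n_ft} features nor its transpose"
        )
    counts = sp.csr_matrix(mat).astype(np.int64)
    return CountMatrix(counts, barcodes, features)


def write_counts(cm: CountMatrix, out_dir) -> None:
    """Write matrix.mtx / barcodes.tsv / features.tsv (cells as rows)."""
    os.makedirs(out_dir, exist_ok=True)
    scipy.io.mmwrite(
        os.path.join(out_dir, "matrix.mtx"), cm.counts.tocoo(), field="integer"
    )
    pd.Series(cm.cell_ids).to_csv(
        os.path.join(out_dir, "barcodes.tsv"), sep="\t", header=False, index=False
    )
    pd.Series(cm.gene_ids).to_csv(
        os.path.join(out_dir, "features.tsv"), sep="\t", header=False, index=False
    )


def read_fragments(path, chrom_sizes: dict) -> FragmentSet:
    """Read a 4/5-column fragments file, rejecting malformed records.

    Records with start >= end or an unknown chromosome are dropped with a
    logged warning; a missing 5th column defaults the duplicate count to 1.
    """
    df = _read_table(path, dtype={0: str, 3: str})
    if df.shape[1] == 4:
        df[4] = 1
    elif df.shape[1] != 5:
        raise FormatError(f"fragments file must have 4 or 5 columns, got {df.shape[1]}")
    df.columns = ["chrom", "start", "end", "barcode", "dup_count"]
    df["dup_count"] = df["dup_count"].fillna(1)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["dup_count"] = df["dup_count"].astype(np.int64)
    sizes = df["chrom"].map(chrom_sizes)
    ok = (
        (df["start"] >= 0)
        & (df["start"] < df["end"])
        & sizes.notna()
        & (df["end"] <= sizes.fillna(-1))
        & (df["barcode"].str.len() > 0)
    )
    n_bad = int((~ok).sum())
    if n_bad:
        log.warning("rejected %d malformed fragment records", n_bad)
    return FragmentSet(df[ok].copy(), dict(chrom_sizes))


def write_fragments(fs: FragmentSet, path) -> None:
    fs.records.to_csv(path, sep="\t", header=False, index=False)


def read_gene_models(path) -> GeneModels:
    """Read gene models from BED6 or GTF (detected by extension/columns).

    GTF coordinates (1-based closed) are converted to 0-based half-open.
    """
    base = str(path).removesuffix(".gz")
    df = _read_table(path, dtype={0: str})
    if base.endswith((".gtf", ".gff")) or df.shape[1] >= 9:
        df = df[df[2] == "gene"]
        attrs = df[8].str.extract(r'gene_id[ =]"?([^";]+)"?')[0]
        genes = pd.DataFrame(
            {
                "gene_id": attrs.to_numpy(),
                "chrom": df[0].to_numpy(),
                "start": df[3].astype(np.int64).to_numpy() - 1,
                "end": df[4].astype(np.int64).to_numpy(),
                "strand": df[6].to_numpy(),
            }
        )
    elif df.shape[1] >= 6:
        genes = pd.DataFrame(
            {
                "gene_id": df[3].astype(str).to_numpy(),
                "chrom": df[0].to_numpy(),
                "start": df[1].astype(np.int64).to_numpy(),
                "end": df[2].astype(np.int64).to_numpy(),
                "strand": df[5].to_numpy(),
            }
        )
    else:
        raise FormatError("gene models must be BED6 or GTF")
    return GeneModels(genes)


def pool_count_matrices(mats: list) -> CountMatrix:
    """Concatenate pooled-run matrices over a shared gene universe.

    Barcodes colliding across files are disambiguated by suffixing the file
    index (pooled-run design).
    """
    if not mats:
        raise ValueError("no matrices to pool")
    genes = list(mats[0].gene_ids)
    for m in mats[1:]:
        if list(m.gene_ids) != genes:
            raise FormatError("pooled matrices must share an identical gene universe")
    seen: dict = {}
    ids, blocks, metas = [], [], []
    for i, m in enumerate(mats):
        for b in m.cell_ids:
            ids.append(f"{b}-{i}" if b in seen else b)
            seen[b] = True
        blocks.append(m.counts)
        metas.append(m.cell_meta.reset_index(drop=True))
    meta = pd.concat(metas, axis=0).reset_index(drop=True)
    meta.index = pd.Index(ids)
    return CountMatrix(
        sp.vstack(blocks).tocsr(), np.asarray(ids, dtype=object),
        mats[0].gene_ids, meta, mats[0].gene_meta,
    )


# ---------------------------------------------------------------------------
# QC


def midpoints_in_tss_windows(fragments: pd.DataFrame, tss_by_chrom: dict, half_width: int) -> np.ndarray:
    """Boolean per record: fragment midpoint within ±half_width of any TSS."""
    out = np.zeros(len(fragments), dtype=bool)
    mids = ((fragments["start"] + fragments["end"]) // 2).to_numpy()
    chroms = fragments["chrom"].to_numpy()
    for c, tss in tss_by_chrom.items():
        sel = np.flatnonzero(chroms == c)
        if sel.size == 0 or tss.size == 0:
            continue
        m = mids[sel]
        idx = np.searchsorted(tss, m)
        right = np.where(idx < tss.size, tss[np.minimum(idx, tss.size - 1)] - m, np.iinfo(np.int64).max)
        left = np.where(idx > 0, m - tss[np.maximum(idx - 1, 0)], np.iinfo(np.int64).max)
        out[sel] = np.minimum(left, right) <= half_width
    return out


def tss_proportion(fs: FragmentSet, gene_models: GeneModels, half_width: int = 2000) -> pd.Series:
    """Per-barcode percentage of fragments falling in ±half_width TSS windows."""
    hit = midpoints_in_tss_windows(fs.records, gene_models.tss_by_chrom(), half_width)
    df = pd.DataFrame({"barcode": fs.records["barcode"], "hit": hit})
    grouped = df.groupby("barcode", sort=False)
    return 100.0 * grouped["hit"].mean()


def apply_qc(data, gene_models: GeneModels = None, params: QcParams = None):
    """Modality-specific cell filtering.

    RNA: keep cells with UMI > min_umi AND detected genes > min_genes (strict).
    ATAC: keep barcodes with unique fragments >= min_fragments AND TSS
    proportion >= min_tss_proportion; requires ``gene_models``.
    Surviving cells keep their input order.  Kept/dropped counts are logged.
    """
    params = params or QcParams()
    if isinstance(data, CountMatrix):
        umi = np.asarray(data.counts.sum(axis=1)).ravel()
        detected = np.asarray((data.counts > 0).sum(axis=1)).ravel()
        keep = (umi > params.min_umi) & (detected > params.min_genes)
        out = data.subset_cells(keep)
        n_keep = int(keep.sum())
    elif isinstance(data, FragmentSet):
        if gene_models is None:
            raise ValueError("ATAC QC requires gene_models for the TSS proportion")
        counts = data.fragment_counts()
        prop = tss_proportion(data, gene_models)
        good = counts.index[
            (counts >= params.min_fragments)
            & (prop.reindex(counts.index).fillna(0.0) >= params.min_tss_proportion)
        ]
        out = data.subset_barcodes(good)
        n_keep = len(good)
    else:
        raise TypeError(f"apply_qc does not handle {type(data)!r}")
    total = data.n_cells if isinstance(data, CountMatrix) else len(data.fragment_counts())
    if n_keep == 0:
        log.warning("QC removed every cell (%d dropped)", total)
    else:
        log.info("QC kept %d / %d cells", n_keep, total)
    return out
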