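"""Benchmark scenarios on synthetic data with known ground truth.

Each scenario fixes the study conditions (sample sizes, effect sizes, noise
levels) for one pipeline stage and measures how well the stage recovers the
implanted truth.  They are the package's own end-to-end validation harness:
the test suite asserts on their outputs and ``scripts/acceptance.py``
reports them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import cluster_core, cnv_subclones, diversity, ecdna_caller, nmf_programs
from . import subcluster_matching, synthetic_data as sd
from .cluster_core import Embedding

__all__ = [
    "ecdna_benchmark",
    "nmf_recovery_benchmark",
    "cnv_typing_benchmark",
    "matching_benchmark",
    "diversity_benchmark",
]


# ---------------------------------------------------------------------------
# ecDNA caller end-to-end


def ecdna_benchmark_config(seed: int = 0) -> sd.AtacSimConfig:
    """500 cells over a 60-Mb toy genome: three bona fide amplicons, one
    chromosomal CNV (dosage 2.5 — below the relative-coverage rule) and one
    high-copy but TSS-concentrated control that the TSS rule must reject."""
    return sd.AtacSimConfig(
        chrom_sizes={"chr1": 30_000_000, "chr2": 30_000_000},
        cells=500,
        background_rate=3.0,
        tss_concentration=0.5,
        ecdna_spec=[
            sd.EcdnaSpec("chr1", 5_000_000, 5_500_000, 10.0, 0.40, True),
            sd.EcdnaSpec("chr1", 20_000_000, 20_300_000, 8.0, 0.35, True),
            sd.EcdnaSpec("chr2", 10_000_000, 10_400_000, 12.0, 0.30, True),
            # promoter-concentrated amplified control (not ecDNA-like)
            sd.EcdnaSpec("chr1", 25_000_000, 25_200_000, 8.0, 0.40, False),
        ],
        cnv_spec=[sd.CnvSpec("chr2", 20_000_000, 22_000_000, 2.5, 0.5)],
        seed=seed,
    )


def _overlaps(region, chrom, start, end) -> bool:
    return region.chrom == chrom and region.start < end and region.end > start


def ecdna_benchmark(seed: int = 0) -> dict:
    """Run the full caller on the benchmark genome and score recovery."""
    config = ecdna_benchmark_config(seed)
    frags, models, truth = sd.simulate_atac(config)
    params = ecdna_caller.EcdnaParams()
    regions, matrix = ecdna_caller.call_ecdna(frags, models, params)

    true_amplicons = [
        e for e in config.ecdna_spec if e.uniform
    ]
    recovered = sum(
        any(_overlaps(r, e.chrom, e.start, e.end) for r in regions)
        for e in true_amplicons
    )
    control = next(e for e in config.ecdna_spec if not e.uniform)
    n_false_cnv = sum(
        any(_overlaps(r, c.chrom, c.start, c.end) for c in config.cnv_spec)
        for r in regions
    )
    n_false_control = sum(
        _overlaps(r, control.chrom, control.start, control.end) for r in regions
    )
    n_background = sum(
        not any(
            _overlaps(r, e.chrom, e.start, e.end) for e in config.ecdna_spec
        )
        and not any(_overlaps(r, c.chrom, c.start, c.end) for c in config.cnv_spec)
        for r in regions
    )
    return {
        "config": config,
        "fragments": frags,
        "gene_models": models,
        "truth": truth,
        "params": params,
        "matrix": matrix,
        "regions": regions,
        "n_true_amplicons": len(true_amplicons),
        "n_recovered": int(recovered),
        "n_false_cnv": int(n_false_cnv),
        "n_false_control": int(n_false_control),
        "n_false_background": int(n_background),
    }


# ---------------------------------------------------------------------------
# NMF program recovery


def nmf_recovery_config(seed: int = 0) -> sd.RnaSimConfig:
    """Six lines x 800 cells; one 50-gene module heterogeneously active in
    four of them, a second module in an overlapping set of four lines."""
    return sd.RnaSimConfig(
        n_cell_lines=6,
        cells_per_line=800,
        n_genes=1000,
        baseline_shape=0.5,
        baseline_scale=6.0,
        line_markers=(0, 1.0),
        program_spec=[
            sd.ProgramSpec(50, 0.3, 2.0, (0, 1, 2, 3), "module_a"),
            sd.ProgramSpec(50, 0.3, 2.0, (2, 3, 4, 5), "module_b"),
        ],
        seed=seed,
    )


def nmf_recovery_benchmark(seed: int = 0, k_range=range(6, 10)) -> dict:
    config = nmf_recovery_config(seed)
    cm, truth = sd.simulate_rna(config)
    per_line = {
        line: cm.subset_cells(np.asarray(cm.cell_meta["cell_line"] == line))
        for line in sorted(set(cm.cell_meta["cell_line"]))
    }
    programs = nmf_programs.extract_programs(per_line, k_range=k_range, seed=seed)
    clusters = nmf_programs.cluster_programs(programs, min_lines=4)
    results = {}
    for name, genes in truth.programs.items():
        best, best_cluster = 0.0, None
        for c in clusters:
            j = nmf_programs.jaccard(c.signature_genes, genes)
            if j > best:
                best, best_cluster = j, c
        results[name] = {
            "jaccard": best,
            "n_lines": len(best_cluster.member_lines) if best_cluster else 0,
        }
    return {
        "config": config,
        "counts": cm,
        "truth": truth,
        "programs": programs,
        "clusters": clusters,
        "recovery": results,
    }


# ---------------------------------------------------------------------------
# CNV subclones and A/B/C typing


def cnv_typing_config(kind: str, seed: int = 0) -> sd.RnaSimConfig:
    """Tumor line (line 0) plus a diploid reference line (line 1).

    ``kind``: 'A' — a 500-gene dosage-2 block carried by 40% of tumor cells
    is the only heterogeneity; 'B' — the same block plus an independent
    strong program, so subclones scatter across program-driven subclusters;
    'C' — no CNV at all.
    """
    # depth mirrors real UMI data (~30k counts over 2000 genes); at this
    # expression level log2(x+1) tracks log dosage nearly linearly
    base = dict(
        n_cell_lines=2,
        cells_per_line=600,
        n_genes=2000,
        baseline_shape=5.0,
        baseline_scale=3.0,
        line_markers=(0, 1.0),
        n_chroms=2,
        seed=seed,
    )
    block = [(0.4, [((1000, 1500), 2.0)])]  # chr2 genes 0..500
    if kind == "A":
        return sd.RnaSimConfig(subclone_spec={0: block}, **base)
    if kind == "B":
        return sd.RnaSimConfig(
            subclone_spec={0: block},
            # program confined to chr1 so the chr2 CNV arm signal stays clean
            program_spec=[sd.ProgramSpec(300, 0.5, 2.0, (0,), "confounder", (0, 1000))],
            **base,
        )
    if kind == "C":
        return sd.RnaSimConfig(**base)
    raise ValueError(kind)


def cnv_typing_benchmark(kind: str, seed: int = 0) -> dict:
    config = cnv_typing_config(kind, seed)
    cm, truth = sd.simulate_rna(config)
    tumor_mask = np.asarray(cm.cell_meta["line"] == 0)
    reference_cells = cm.cell_ids[~tumor_mask]
    profile = cnv_subclones.infer_cnv_profile(cm, reference_cells)
    call = cnv_subclones.detect_subclones(profile)

    tumor = cm.subset_cells(tumor_mask)
    emb = cluster_core.embed(tumor)
    clus = cluster_core.cluster_graph(emb, resolution=0.3, seed=seed)
    assoc = cnv_subclones.classify_association(
        call, clus, cell_ids=tumor.cell_ids
    )

    out = {
        "config": config,
        "counts": cm,
        "truth": truth,
        "profile": profile,
        "subclones": call,
        "clustering": clus,
        "association_type": assoc,
    }
    # subclone recovery accuracy against truth (majority-aligned)
    true_sub = truth.cells.loc[list(call.labels.index), "subclone"].to_numpy()
    pred = call.labels.to_numpy()
    acc = max((pred == true_sub).mean(), (1 - pred == true_sub).mean())
    out["subclone_accuracy"] = float(acc)
    if assoc == "A" and clus.n_clusters >= 2:
        markers = cluster_core.find_markers(tumor, clus)
        degs = set(markers.loc[markers["is_marker"], "gene"])
        lo, hi = 1000, 1500
        cnv_genes = set(cm.gene_ids[lo:hi])
        out["deg_in_cnv_p"] = cnv_subclones.hypergeometric_enrichment(
            len(degs & cnv_genes), len(degs), len(cnv_genes), cm.n_genes
        )
    return out


# ---------------------------------------------------------------------------
# cross-condition matching


def matching_base_config(seed: int = 0) -> sd.RnaSimConfig:
    """Two marker-separated lines standing in for two stable subclusters."""
    return sd.RnaSimConfig(
        n_cell_lines=2,
        cells_per_line=400,
        n_genes=1500,
        baseline_shape=0.5,
        baseline_scale=6.0,
        line_markers=(120, 6.0),
        seed=seed,
    )


def matching_benchmark(seed: int = 0) -> dict:
    """Identity pair (perfect one-to-one match) and a latent-subgroup pair
    (one condition cluster must split under treatment)."""
    base = matching_base_config(seed)
    cm, _ = sd.simulate_rna(base)
    identity = subcluster_matching.match_conditions(cm, cm, seed=seed)

    # the latent module is moderate by design: strong enough for the treated
    # data to support one extra subcluster, weak enough that the integrated
    # clustering keeps the parent population together (one-to-many match)
    response = sd.ResponseSpec(
        n_global_genes=100,
        global_log2_fold=1.5,
        latent_line=0,
        latent_fraction=0.5,
        n_latent_genes=150,
        latent_log2_fold=1.4,
    )
    ctrl, trt, truth = sd.simulate_condition_pair(base, response)
    latent = subcluster_matching.match_conditions(ctrl, trt, seed=seed)
    return {
        "identity": identity,
        "latent": latent,
        "truth": truth,
        "control": ctrl,
        "treated": trt,
    }


# ---------------------------------------------------------------------------
# diversity closed forms


def diversity_benchmark(seed: int = 0, n_cells: int = 1000) -> dict:
    """Closed-form checks and two-blob monotonicity of the diversity score."""
    rng = np.random.default_rng(seed)
    out = {}

    identical = np.zeros((50, 5))
    emb = Embedding(identical, "rna", 5, np.zeros(5))
    out["identical_score"] = float(
        diversity.diversity_score(emb, ["l"] * 50, n_components=5).per_line["score"][0]
    )

    d = 2.5
    two_point = np.zeros((40, 5))
    two_point[: 20, 0] = -d
    two_point[20:, 0] = d
    emb = Embedding(two_point, "rna", 5, np.ones(5))
    out["two_point_d"] = d
    out["two_point_score"] = float(
        diversity.diversity_score(emb, ["l"] * 40, n_components=5).per_line["score"][0]
    )

    scores = []
    for sep in (0.0, 1.0, 2.0, 4.0):
        coords = rng.standard_normal((n_cells, 2))
        coords[: n_cells // 2, 0] -= sep / 2
        coords[n_cells // 2 :, 0] += sep / 2
        emb = Embedding(coords, "rna", 2, np.ones(2))
        res = diversity.diversity_score(emb, ["l"] * n_cells, n_components=2)
        scores.append(float(res.per_line["score"][0]))
    out["blob_separations"] = [0.0, 1.0, 2.0, 4.0]
    out["blob_scores"] = scores
    out["monotone"] = bool(np.all(np.diff(scores) > 0))
    return out
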