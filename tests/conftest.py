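"""Shared fixtures: each expensive benchmark scenario runs once per session."""

import numpy as np
import pytest

from linehet import scenarios, synthetic_data as sd


@pytest.fixture(scope="session")
def rna_small():
    """Three marker-separated lines, small enough for fast unit tests."""
    config = sd.RnaSimConfig(
        n_cell_lines=3,
        cells_per_line=150,
        n_genes=600,
        line_markers=(60, 8.0),
        seed=11,
    )
    return sd.simulate_rna(config)


@pytest.fixture(scope="session")
def ecdna_bench():
    return scenarios.ecdna_benchmark(seed=1)


@pytest.fixture(scope="session")
def nmf_bench():
    return scenarios.nmf_recovery_benchmark(seed=1)


@pytest.fixture(scope="session")
def cnv_bench():
    return {kind: scenarios.cnv_typing_benchmark(kind, seed=1) for kind in "ABC"}


@pytest.fixture(scope="session")
def matching_bench():
    return scenarios.matching_benchmark(seed=1)


@pytest.fixture(scope="session")
def atac_dropout():
    """One amplicon with a zeroed middle bin (coverage dropout)."""
    from linehet import ecdna_caller as ec

    cfg = sd.AtacSimConfig(
        chrom_sizes={"chr1": 30_000_000, "chr2": 30_000_000},
        cells=500,
        ecdna_spec=[sd.EcdnaSpec("chr1", 5_000_000, 5_500_000, 10.0, 0.4, True)],
        dropout_intervals=[("chr1", 5_200_000, 5_300_000)],
        seed=2,
    )
    frags, models, truth = sd.simulate_atac(cfg)
    params = ec.EcdnaParams()
    matrix = ec.bin_coverage(frags, params)
    ec.compute_relative(matrix, params)
    return {
        "config": cfg, "fragments": frags, "gene_models": models,
        "truth": truth, "params": params, "matrix": matrix,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
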