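"""Shared fixtures: tiny hand-built inputs and cached simulated cohorts."""

import numpy as np
import pandas as pd
import pytest

import methylscreen as ms


@pytest.fixture(scope="session")
def default_cohort():
    """Default-geometry cohort (500 genes -> 2,000 blocks, 28 tumors)."""
    cfg = ms.SimulationConfig(seed=4)
    probes = ms.simulate_manifest(cfg)
    blocks = ms.assemble_blocks(probes)
    beta, samples, truth = ms.simulate_beta_cohort(cfg, probes)
    bb = ms.block_beta(beta, blocks)
    return {
        "config": cfg,
        "probes": probes,
        "blocks": blocks,
        "beta": beta,
        "samples": samples,
        "truth": truth,
        "block_beta": bb,
    }


@pytest.fixture(scope="session")
def screen_cohort():
    """Large cohort (2,000 genes) with 50 planted silenced genes plus the
    matching expression arrays, for the integrated screen."""
    cfg = ms.SimulationConfig(seed=8, n_genes=2000)
    probes = ms.simulate_manifest(cfg)
    blocks = ms.assemble_blocks(probes)
    beta, samples, truth = ms.simulate_beta_cohort(cfg, probes)
    bb = ms.block_beta(beta, blocks)
    expr, probe_to_gene, expr_samples = ms.simulate_expression(cfg, truth)
    gene_expr = ms.aggregate_genes(ms.normalize_75th(expr), probe_to_gene)
    return {
        "config": cfg,
        "blocks": blocks,
        "samples": samples,
        "truth": truth,
        "block_beta": bb,
        "gene_expr": gene_expr,
        "expr_samples": expr_samples,
    }


@pytest.fixture
def tiny_block_beta():
    """Hand-built block beta matrix: 3 normals + tumors with known calls."""
    normals = ["N1", "N2", "N3"]
    tumors = [f"T{i}" for i in range(1, 11)]
    data = {}
    # blockA: unmethylated in normals, methylated in 7 tumors
    data["A|TSS200|Island|CGI_A"] = [0.05, 0.08, 0.10] + [0.6] * 7 + [0.1] * 3
    # blockB: unmethylated everywhere
    data["B|TSS200|Island|CGI_B"] = [0.05, 0.05, 0.05] + [0.1] * 10
    # blockC: methylated in a normal -> never aberrant
    data["C|TSS200|Island|CGI_C"] = [0.5, 0.05, 0.05] + [0.7] * 10
    # blockD: open sea, low in normals (CGI restriction check)
    data["D|Body|OpenSea|NA"] = [0.01, 0.01, 0.01] + [0.9] * 10
    df = pd.DataFrame(data, index=normals + tumors).T
    df.index.name = "block_id"
    return df, normals, tumors


def tumors_normals(samples: pd.DataFrame):
    tissue = samples[samples["material"] == "tissue"]
    return (
        sorted(tissue.index[tissue["group"] == "primary"]),
        sorted(tissue.index[tissue["group"] == "normal"]),
    )
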