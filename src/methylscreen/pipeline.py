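"""End-to-end workflow: files in, result tables out.

Wires the library modules into the full analysis: block assembly and
block-level beta, aberrant-methylation calls against normals, most-variable-
block clustering, methylated-CGI fractions, the integrated silencing screen
per cell line (when expression arrays are given), PMR (when a qMSP table is
given), and clonal-evolution calls for patients with a matched
primary/metastasis pair.  Outputs are deterministic for a given config and
seed; no stage mutates its inputs, and each output table suffices to rerun
downstream stages in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .aberrant import (
    AberrantCallConfig,
    call_aberrant_blocks,
    cluster_samples,
    methylated_fraction,
    normally_unmethylated_cgi_blocks,
    select_variable_blocks,
)
from .core import (
    assemble_blocks,
    block_beta,
    load_beta_matrix,
    load_manifest,
    load_sample_sheet,
)
from .evolution import classify_evolution, pair_sets
from .expression import (
    aggregate_genes,
    expressed_in_baseline,
    induction_screen,
    load_expression,
    normalize_75th,
)
from .qmsp import load_qmsp_table, pmr_table
from .screen import ScreenCriteria, eligible_gene_universe, run_screen

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


@dataclass
class RunConfig:
    """Inputs, thresholds, and output location for one pipeline run."""

    manifest: str
    beta: str
    samples: str
    out_dir: str
    expression: str | None = None
    expression_samples: str | None = None
    probe_to_gene: str | None = None
    qmsp: str | None = None
    seed: int = 0
    n_variable_blocks: int = 500
    cluster_k: int = 2
    element_cap: int = 20_000
    linkage_method: str = "complete"
    shared_fraction_min: float = 0.75
    baseline_threshold: float = 0.5
    induction_log2_threshold: float = 1.0
    aberrant: AberrantCallConfig = field(default_factory=AberrantCallConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        ab = raw.pop("aberrant", None)
        cfg = cls(**raw)
        if ab:
            cfg.aberrant = AberrantCallConfig(**ab)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)


def run_pipeline(config: RunConfig) -> Path:
    """Run every applicable stage; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("manifest", "beta", "samples"):
        p = getattr(config, name)
        if not Path(p).exists():
            raise FileNotFoundError(f"missing input {name!r}: {p}")

    probes = load_manifest(config.manifest)
    beta = load_beta_matrix(config.beta)
    samples = load_sample_sheet(config.samples)

    blocks = assemble_blocks(probes)
    bb = block_beta(beta, blocks)
    _write(bb, out / "block_beta.tsv")

    tissue = samples[samples["material"] == "tissue"]
    normals = sorted(tissue.index[tissue["group"] == "normal"])
    tumors = sorted(tissue.index[tissue["group"] == "primary"])
    if not normals or not tumors:
        raise ValueError("sample sheet must contain tissue normals and primary tumors")

    reference = normally_unmethylated_cgi_blocks(bb, blocks, normals, config.aberrant)
    pd.Series(reference, name="block_id").to_frame().to_csv(
        out / "reference_blocks.tsv", sep="\t", index=False
    )

    gene_of_block = {b.block_id: (b.gene or "") for b in blocks}
    aberrant = call_aberrant_blocks(bb, tumors, normals, config.aberrant)
    aberrant.insert(0, "gene", [gene_of_block[b] for b in aberrant.index])
    _write(aberrant, out / "aberrant_blocks.tsv")

    n_var = min(config.n_variable_blocks, len(bb.loc[:, tumors].dropna()))
    variable = select_variable_blocks(bb, tumors, n=n_var)
    result = cluster_samples(
        bb,
        variable,
        samples=tumors,
        element_cap=config.element_cap,
        seed=config.seed,
        method=config.linkage_method,
    )
    labels = result.labels(config.cluster_k)
    labels.to_frame().to_csv(out / "clusters.tsv", sep="\t")
    _write(result.merge_table(), out / "linkage.tsv", index=False)

    fractions = pd.Series(
        {s: methylated_fraction(bb, s, reference, "tissue") for s in tumors},
        name="methylated_cgi_fraction",
    )
    fractions.index.name = "sample_id"
    _write(fractions.to_frame(), out / "methylated_fraction.tsv")

    expressed: set[str] | None = None
    if config.expression:
        expr = load_expression(config.expression)
        expr_samples = pd.read_csv(
            config.expression_samples, sep="\t", dtype=str, keep_default_na=False
        ).set_index("sample_id")
        probe_to_gene = pd.read_csv(config.probe_to_gene, index_col=0).iloc[:, 0]
        gene_expr = aggregate_genes(normalize_75th(expr), probe_to_gene)
        msc = sorted(expr_samples.index[expr_samples["group"] == "msc"])
        ob = sorted(expr_samples.index[expr_samples["group"] == "osteoblast"])
        expressed = expressed_in_baseline(
            gene_expr, msc, ob, threshold=config.baseline_threshold
        )
        criteria = ScreenCriteria(
            aberrant_config=config.aberrant,
            baseline_threshold=config.baseline_threshold,
            induction_log2_threshold=config.induction_log2_threshold,
        )
        universe = eligible_gene_universe(
            blocks, bb, tumors, normals, expressed, set(gene_expr.index), criteria
        )
        mocks = expr_samples[expr_samples["group"] == "mock"]
        for mock_id, row in mocks.iterrows():
            cl = row["cell_line"]
            treated_ids = expr_samples.index[
                (expr_samples["group"] == "treated") & (expr_samples["cell_line"] == cl)
            ]
            if treated_ids.empty or f"{cl}_mock" not in bb.columns:
                logger.warning("skipping cell line %s: missing treated arm or beta", cl)
                continue
            induction = induction_screen(
                gene_expr,
                mock_id,
                list(treated_ids),
                log2_threshold=config.induction_log2_threshold,
            )
            screen = run_screen(universe, bb[f"{cl}_mock"], induction, criteria)
            _write(screen, out / f"screen_{cl}.tsv")

    if config.qmsp:
        pmr = pmr_table(load_qmsp_table(config.qmsp))
        _write(pmr, out / "pmr.tsv", index=False)

    # clonal evolution for patients with a matched primary/metastasis pair
    evo_universe = [
        b for b in reference if b.split("|")[1] == "TSS200"
    ]
    if expressed is not None:
        evo_universe = [
            b for b in evo_universe if gene_of_block[b] in expressed
        ]
    calls = {}
    mets = tissue[tissue["group"] == "metastasis"]
    for met_id, row in mets.iterrows():
        patient = row["patient_id"]
        prim = tissue.index[
            (tissue["group"] == "primary") & (tissue["patient_id"] == patient)
        ]
        if prim.empty:
            continue
        pair = pair_sets(
            bb, prim[0], met_id, evo_universe, config.aberrant, patient_id=patient
        )
        call = classify_evolution(pair, config.shared_fraction_min)
        calls[patient] = dataclasses.asdict(call)
    if calls:
        with open(out / "evolution.json", "w") as fh:
            json.dump(calls, fh, indent=1, sort_keys=True)

    config_dict = config.to_dict()
    manifest = {
        "package": "methylscreen",
        "version": __version__,
        "config": config_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out
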