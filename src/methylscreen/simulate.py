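"""Synthetic beadarray cohorts with planted ground truth.

Emulates the statistical structure of the real inputs so every analysis
stage can be validated against known truth without any download:

* a probe manifest in which each gene carries a promoter (TSS200) CpG-island
  block, a first-exon island block, an upstream shore block, and a gene-body
  open-sea block;
* a 450K-style beta matrix with the bimodal beta-value distribution of
  beadarrays (per-state Beta distributions with means ~0.05 / 0.5 / 0.85),
  planted aberrantly methylated promoter blocks in tumors, a high-methylation
  (CIMP-like) tumor subgroup sharing extra methylated islands, and
  near-binary cell-line profiles;
* MSC/osteoblast baseline and mock / 5-aza-dC expression arrays with planted
  silenced-and-reactivated genes (log-normal multiplicative noise);
* qMSP molecule counts (Poisson) and primary-metastasis aberrant-set pairs
  generated under an explicit clonal or parallel model.

Every output is a deterministic function of (config, master seed); each
product draws from its own named RNG stream so adding one simulation never
perturbs another.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenomicBlock, ProbeRecord, assemble_blocks
from .evolution import MethylationProfilePair
from .qmsp import QmspMeasurement

STATE_CODES = {"unmeth": 0, "partial": 1, "meth": 2}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; the seed fully determines every output.

    The defaults reproduce the cohort geometry of the emulated study:
    28 primary tumors (10 of them high-methylators) against 3 normals,
    promoter hypermethylation called at beta >= 0.4 with normals < 0.2,
    4-fold re-activation of silenced genes under 5-aza-dC, and 10%
    multiplicative expression noise.
    """

    seed: int = 0
    # cohort geometry
    n_genes: int = 500
    n_normals: int = 3
    n_tumors: int = 28
    n_high_methylators: int = 10
    n_cell_lines: int = 2
    n_msc: int = 7
    n_osteoblasts: int = 3
    # beta-value distributions (Beta shape pairs per methylation state)
    beta_unmeth_params: tuple[float, float] = (2.0, 38.0)  # mean ~0.05
    beta_partial_params: tuple[float, float] = (5.0, 5.0)  # mean 0.5
    beta_meth_params: tuple[float, float] = (17.0, 3.0)  # mean 0.85
    cell_line_unmeth_params: tuple[float, float] = (2.0, 58.0)  # mean ~0.033
    cell_line_meth_params: tuple[float, float] = (60.0, 6.0)  # mean ~0.91
    noise_free: bool = False  # point masses instead of Beta draws
    # planted methylation structure
    normal_methylated_cgi_fraction: float = 0.10
    aberrant_block_fraction: float = 0.02
    aberrant_tumor_range: tuple[int, int] = (10, 28)
    high_methylator_extra_fraction: float = 0.20
    # expression structure
    expressed_gene_fraction: float = 0.30
    n_silenced_genes: int = 50
    induction_true_fold: float = 4.0
    expression_noise_cv: float = 0.10
    baseline_expressed_level: float = 2.0
    silenced_level: float = 0.05
    platform_coverage: float = 0.95
    demethylation_range: tuple[float, float] = (0.18, 0.51)
    # matched primary-metastasis samples in the beta cohort (every third
    # pair follows the parallel model, the others the clonal model)
    n_met_pairs: int = 3
    # qMSP
    qmsp_poisson_scale: float = 1000.0
    # primary-metastasis pairs
    pair_mode: str = "clonal"
    pair_universe_size: int = 100
    clonal_primary_size: int = 40
    clonal_extra_events: int = 10
    parallel_ancestor_size: int = 15
    parallel_private_size: int = 15
    call_flip_prob: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "normal_methylated_cgi_fraction",
            "aberrant_block_fraction",
            "high_methylator_extra_fraction",
            "expressed_gene_fraction",
            "platform_coverage",
            "call_flip_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.pair_mode not in ("clonal", "parallel"):
            raise ValueError(f"pair_mode must be clonal or parallel, got {self.pair_mode!r}")
        if self.n_high_methylators > self.n_tumors:
            raise ValueError("n_high_methylators cannot exceed n_tumors")
        if self.n_met_pairs > self.n_tumors:
            raise ValueError("n_met_pairs cannot exceed n_tumors")


@dataclass
class GroundTruth:
    """Planted truth emitted alongside each simulated cohort."""

    normally_unmethylated_cgi_blocks: list[str] = field(default_factory=list)
    normal_methylated_cgi_blocks: list[str] = field(default_factory=list)
    aberrant_blocks: dict[str, list[str]] = field(default_factory=dict)
    high_extra_blocks: list[str] = field(default_factory=list)
    high_methylator_samples: list[str] = field(default_factory=list)
    cluster_labels: dict[str, str] = field(default_factory=dict)
    expressed_genes: list[str] = field(default_factory=list)
    silenced_genes: list[str] = field(default_factory=list)
    gene_tss200_block: dict[str, str] = field(default_factory=dict)
    demethylation_delta: dict[str, float] = field(default_factory=dict)
    cell_lines: list[str] = field(default_factory=list)
    platform_genes: list[str] = field(default_factory=list)
    pair_patterns: dict[str, str] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def stream_rng(seed: int, name: str) -> np.random.Generator:
    """One named, independent RNG stream derived from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


# ---------------------------------------------------------------------------
# Manifest


def simulate_manifest(config: SimulationConfig) -> list[ProbeRecord]:
    """A probe manifest with four genomic blocks per gene.

    Per gene: TSS200/Island (2-5 probes), FirstExon/Island (1-2, same CGI),
    TSS1500/Shore (1-2), Body/OpenSea (1-3).  With the default 500 genes
    this yields 2,000 genomic blocks.
    """
    rng = stream_rng(config.seed, "manifest")
    probes: list[ProbeRecord] = []
    counter = 0
    for i in range(config.n_genes):
        gene = f"GENE{i:05d}"
        chrom = f"chr{(i % 22) + 1}"
        cgi = f"CGI{i:05d}"
        base = (i + 1) * 100_000
        layout = [
            ("TSS200", "Island", cgi, int(rng.integers(2, 6)), 0),
            ("FirstExon", "Island", cgi, int(rng.integers(1, 3)), 500),
            ("TSS1500", "Shore", cgi, int(rng.integers(1, 3)), -1500),
            ("Body", "OpenSea", None, int(rng.integers(1, 4)), 5000),
        ]
        for tss_rel, cgi_rel, cgi_id, k, offset in layout:
            for j in range(k):
                probes.append(
                    ProbeRecord(
                        probe_id=f"cg{counter:08d}",
                        chromosome=chrom,
                        position=base + offset + j * 50 + int(rng.integers(0, 30)),
                        gene=(gene,),
                        tss_relation=tss_rel,
                        cgi_relation=cgi_rel,
                        cgi_id=cgi_id,
                    )
                )
                counter += 1
    return probes


# ---------------------------------------------------------------------------
# Beta cohort


def _draw_beta(rng, params, size, noise_free, point):
    if noise_free:
        return np.full(size, point)
    return rng.beta(params[0], params[1], size=size)


def simulate_beta_cohort(
    config: SimulationConfig, probes: list[ProbeRecord]
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Probe-level beta matrix, sample sheet, and planted truth.

    Samples: normals N01.., primary tumors T01.. (a random subset of which
    are high-methylators sharing a planted set of extra methylated islands),
    and per cell line a mock and a 5-aza-dC-treated profile.  Tumor promoter
    blocks of planted silenced genes (plus extra random island blocks, up to
    ``aberrant_block_fraction`` of all blocks) are methylated in 10-28
    tumors each; treated cell-line profiles lose a per-gene uniform
    0.18-0.51 beta at silenced promoters.
    """
    rng = stream_rng(config.seed, "beta")
    blocks = assemble_blocks(probes)
    block_by_id = {b.block_id: b for b in blocks}
    island_ids = sorted(b.block_id for b in blocks if b.cgi_relation == "Island")
    genes = sorted({b.gene for b in blocks if b.gene is not None})
    tss200_block = {
        b.gene: b.block_id
        for b in blocks
        if b.tss_relation == "TSS200" and b.cgi_relation == "Island"
    }

    # planted methylation structure
    n_norm_meth = round(config.normal_methylated_cgi_fraction * len(island_ids))
    normal_meth = set(rng.choice(island_ids, size=n_norm_meth, replace=False))
    normally_unmeth = sorted(set(island_ids) - normal_meth)

    expressed = sorted(
        rng.choice(
            genes,
            size=round(config.expressed_gene_fraction * len(genes)),
            replace=False,
        )
    )
    silenceable = [g for g in expressed if tss200_block[g] not in normal_meth]
    n_sil = min(config.n_silenced_genes, len(silenceable))
    silenced = sorted(rng.choice(silenceable, size=n_sil, replace=False))
    silenced_blocks = {tss200_block[g] for g in silenced}

    n_aberrant = max(round(config.aberrant_block_fraction * len(blocks)), n_sil)
    pool = sorted(set(normally_unmeth) - silenced_blocks)
    extra_needed = n_aberrant - len(silenced_blocks)
    extra_aberrant = set(rng.choice(pool, size=extra_needed, replace=False))
    aberrant_ids = sorted(silenced_blocks | extra_aberrant)

    normals = [f"N{i + 1:02d}" for i in range(config.n_normals)]
    tumors = [f"T{i + 1:02d}" for i in range(config.n_tumors)]
    cell_lines = [f"CL{i + 1}" for i in range(config.n_cell_lines)]
    high = sorted(rng.choice(tumors, size=config.n_high_methylators, replace=False))

    lo, hi = config.aberrant_tumor_range
    aberrant_tumors = {
        bid: sorted(rng.choice(tumors, size=int(rng.integers(lo, hi + 1)), replace=False))
        for bid in aberrant_ids
    }
    extra_pool = sorted(set(normally_unmeth) - set(aberrant_ids))
    extra_mask = rng.random(len(extra_pool)) < config.high_methylator_extra_fraction
    high_extra = [b for b, m in zip(extra_pool, extra_mask) if m]

    # per-(block, sample) state codes for tissue samples
    tissue_samples = normals + tumors
    block_ids = [b.block_id for b in blocks]
    codes = pd.DataFrame(
        STATE_CODES["unmeth"], index=block_ids, columns=tissue_samples, dtype=int
    )
    body_ids = [b.block_id for b in blocks if b.cgi_relation == "OpenSea"]
    codes.loc[body_ids, :] = STATE_CODES["partial"]
    codes.loc[sorted(normal_meth), :] = STATE_CODES["meth"]
    for bid, ts in aberrant_tumors.items():
        codes.loc[bid, ts] = STATE_CODES["meth"]
    if high_extra:
        codes.loc[high_extra, high] = STATE_CODES["meth"]

    # matched metastasis samples: copy the paired primary's states, then
    # follow the clonal model (add private events) or, for every third pair,
    # the parallel model (keep half the primary's promoter events, add the
    # same number of private ones) over the evaluable promoter pool
    normally_unmeth_set = set(normally_unmeth)
    promoter_pool = sorted(
        b for b in tss200_block.values() if b in normally_unmeth_set
    )
    met_samples = []
    pair_patterns: dict[str, str] = {}
    for i in range(config.n_met_pairs):
        prim = tumors[i]
        met_id = f"{prim}M"
        patient = f"P{i + 1:02d}"
        met_codes = codes[prim].copy()
        prim_meth = [b for b in promoter_pool if codes.loc[b, prim] == STATE_CODES["meth"]]
        unmeth_pool = [b for b in promoter_pool if b not in set(prim_meth)]
        mode = "parallel" if (i + 1) % 3 == 0 else "clonal"
        if mode == "clonal":
            n_extra = max(2, len(prim_meth) // 4)
            extra = rng.choice(unmeth_pool, size=min(n_extra, len(unmeth_pool)), replace=False)
            met_codes.loc[extra] = STATE_CODES["meth"]
        else:
            dropped = rng.choice(prim_meth, size=len(prim_meth) // 2, replace=False)
            met_codes.loc[dropped] = STATE_CODES["unmeth"]
            private = rng.choice(
                unmeth_pool, size=min(len(dropped), len(unmeth_pool)), replace=False
            )
            met_codes.loc[private] = STATE_CODES["meth"]
        codes[met_id] = met_codes
        met_samples.append(met_id)
        pair_patterns[patient] = mode
    tissue_samples = tissue_samples + met_samples

    # cell-line states (near-binary): mock profile per cell line
    cl_codes = pd.DataFrame(
        STATE_CODES["unmeth"], index=block_ids, columns=cell_lines, dtype=int
    )
    cl_codes.loc[sorted(normal_meth), :] = STATE_CODES["meth"]
    cl_codes.loc[sorted(silenced_blocks), :] = STATE_CODES["meth"]
    body_meth = rng.random((len(body_ids), len(cell_lines))) < 0.5
    cl_codes.loc[body_ids, :] = np.where(
        body_meth, STATE_CODES["meth"], STATE_CODES["unmeth"]
    )

    # expand block states to probes and draw beta values
    probe_ids = [p.probe_id for p in probes]
    probe_block = {}
    for b in blocks:
        for pid in b.probe_ids:
            probe_block.setdefault(pid, b.block_id)  # one gene per probe here
    pcodes = codes.loc[[probe_block[p] for p in probe_ids]].to_numpy()
    pcodes_cl = cl_codes.loc[[probe_block[p] for p in probe_ids]].to_numpy()

    def draw_tissue(code_matrix):
        out = np.empty(code_matrix.shape)
        for name, params, point in (
            ("unmeth", config.beta_unmeth_params, 0.05),
            ("partial", config.beta_partial_params, 0.5),
            ("meth", config.beta_meth_params, 0.85),
        ):
            mask = code_matrix == STATE_CODES[name]
            out[mask] = _draw_beta(rng, params, int(mask.sum()), config.noise_free, point)
        return out

    def draw_cell_line(code_matrix):
        out = np.empty(code_matrix.shape)
        for name, params, point in (
            ("unmeth", config.cell_line_unmeth_params, 0.05),
            ("partial", config.beta_partial_params, 0.5),
            ("meth", config.cell_line_meth_params, 0.90),
        ):
            mask = code_matrix == STATE_CODES[name]
            out[mask] = _draw_beta(rng, params, int(mask.sum()), config.noise_free, point)
        return out

    beta_tissue = draw_tissue(pcodes)
    beta_mock = draw_cell_line(pcodes_cl)

    # 5-aza-dC-treated cell-line profiles: silenced promoters lose a planted
    # per-gene delta; other probes keep the mock draw.
    d_lo, d_hi = config.demethylation_range
    deltas = {
        g: float(rng.uniform(d_lo, d_hi)) if not config.noise_free else float(
            np.round(np.interp(i, [0, max(len(silenced) - 1, 1)], [d_lo, d_hi]), 4)
        )
        for i, g in enumerate(silenced)
    }
    beta_aza = beta_mock.copy()
    probe_delta = np.zeros(len(probe_ids))
    for g in silenced:
        bid = tss200_block[g]
        for pid in block_by_id[bid].probe_ids:
            probe_delta[probe_ids.index(pid)] = deltas[g]
    beta_aza = np.clip(beta_aza - probe_delta[:, None], 0.01, 1.0)

    columns = tissue_samples + [f"{cl}_mock" for cl in cell_lines] + [
        f"{cl}_aza" for cl in cell_lines
    ]
    values = np.hstack([beta_tissue, beta_mock, beta_aza])
    beta = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"), columns=columns)

    sample_rows = (
        [(s, "tissue", "normal", "") for s in normals]
        + [(s, "tissue", "primary", f"P{i + 1:02d}") for i, s in enumerate(tumors)]
        + [(s, "tissue", "metastasis", f"P{i + 1:02d}") for i, s in enumerate(met_samples)]
        + [(f"{cl}_mock", "cell_line", "mock", cl) for cl in cell_lines]
        + [(f"{cl}_aza", "cell_line", "treated", cl) for cl in cell_lines]
    )
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "material", "group", "patient_id"]
    ).set_index("sample_id")

    truth = GroundTruth(
        normally_unmethylated_cgi_blocks=normally_unmeth,
        normal_methylated_cgi_blocks=sorted(normal_meth),
        aberrant_blocks={b: ts for b, ts in sorted(aberrant_tumors.items())},
        high_extra_blocks=sorted(high_extra),
        high_methylator_samples=high,
        cluster_labels={t: ("high" if t in high else "low") for t in tumors},
        expressed_genes=expressed,
        silenced_genes=silenced,
        gene_tss200_block=tss200_block,
        demethylation_delta=deltas,
        cell_lines=cell_lines,
        pair_patterns=pair_patterns,
    )
    return beta, samples, truth


# ---------------------------------------------------------------------------
# Expression


def simulate_expression(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Raw probe-level expression arrays for baseline and cell lines.

    Returns (expr, probe_to_gene, samples).  Each probe carries a fixed
    log-normal affinity (shared across samples, as hybridization efficiency
    is), which gives every array the continuous signal distribution that
    percentile normalization assumes; affinities cancel in treated/mock
    ratios.  A per-sample raw scale factor makes 75th-percentile
    normalization do real work.  Silenced genes are near the floor in mock
    cells and raised ``induction_true_fold``-fold in treated cells.
    """
    rng = stream_rng(config.seed, "expression")
    genes = sorted(truth.gene_tss200_block)
    expressed = set(truth.expressed_genes)
    silenced = set(truth.silenced_genes)

    n_platform = round(config.platform_coverage * len(genes))
    platform = set(rng.choice(genes, size=n_platform, replace=False)) | silenced
    platform = sorted(platform)
    truth.platform_genes = platform

    probe_rows = []
    for g in platform:
        for j in range(int(rng.integers(1, 4))):
            probe_rows.append((f"EXP{len(probe_rows):06d}", g))
    probe_ids = [p for p, _ in probe_rows]
    probe_to_gene = pd.Series({p: g for p, g in probe_rows}, name="gene")
    gene_of_probe = probe_to_gene.loc[probe_ids].to_numpy()

    msc = [f"MSC{i + 1:02d}" for i in range(config.n_msc)]
    ob = [f"OB{i + 1:02d}" for i in range(config.n_osteoblasts)]
    mock = [f"{cl}_mock" for cl in truth.cell_lines]
    treated = [f"{cl}_aza" for cl in truth.cell_lines]
    columns = msc + ob + mock + treated

    # each cell line expresses its own program on top of the baseline set
    # (minus the silenced genes), so every array keeps a substantial
    # expressed population anchoring the 75th percentile
    non_baseline = sorted(set(platform) - expressed)
    cell_program: dict[str, set[str]] = {}
    for cl in truth.cell_lines:
        specific = set(
            rng.choice(
                non_baseline,
                size=round(config.expressed_gene_fraction * len(non_baseline)),
                replace=False,
            )
        )
        cell_program[cl] = (expressed | specific) - silenced

    hi, lo = config.baseline_expressed_level, config.silenced_level
    in_expressed = np.isin(gene_of_probe, list(expressed))
    in_silenced = np.isin(gene_of_probe, list(silenced))
    target = np.empty((len(probe_ids), len(columns)))
    for j, col in enumerate(columns):
        if col in msc or col in ob:
            level = np.where(in_expressed, hi, lo)
        else:
            cl = col.removesuffix("_mock").removesuffix("_aza")
            on = np.isin(gene_of_probe, list(cell_program[cl]))
            level = np.where(on, hi, lo)
            if col in treated:  # silenced genes induced by the planted fold
                level = np.where(in_silenced, lo * config.induction_true_fold, level)
        target[:, j] = level

    # probe-specific hybridization affinity, constant across samples
    affinity = rng.lognormal(mean=0.0, sigma=0.25, size=len(probe_ids))
    target = target * affinity[:, None]

    cv = config.expression_noise_cv
    if not config.noise_free and cv > 0:
        sigma = np.sqrt(np.log1p(cv**2))
        noise = rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=target.shape)
        target = target * noise
    scale = rng.uniform(50.0, 200.0, size=len(columns))
    expr = pd.DataFrame(
        target * scale, index=pd.Index(probe_ids, name="probe_id"), columns=columns
    )

    sample_rows = (
        [(s, "msc", "") for s in msc]
        + [(s, "osteoblast", "") for s in ob]
        + [(s, "mock", s.removesuffix("_mock")) for s in mock]
        + [(s, "treated", s.removesuffix("_aza")) for s in treated]
    )
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "group", "cell_line"]
    ).set_index("sample_id")
    return expr, probe_to_gene, samples


# ---------------------------------------------------------------------------
# qMSP


def simulate_qmsp(
    config: SimulationConfig,
    true_pmr: float,
    target_id: str = "CGI00000",
    rng: np.random.Generator | None = None,
) -> tuple[QmspMeasurement, QmspMeasurement]:
    """One sample + fully methylated reference with counts Poisson around
    expectations consistent with ``true_pmr`` (exact in noise-free mode)."""
    if true_pmr < 0:
        raise ValueError("true_pmr must be >= 0")
    if rng is None:
        rng = stream_rng(config.seed, "qmsp")
    scale = config.qmsp_poisson_scale
    exp_sample_meth = scale * true_pmr / 100.0
    if config.noise_free:
        samp_meth, samp_alu, ref_meth, ref_alu = exp_sample_meth, scale, scale, scale
    else:
        samp_meth = float(rng.poisson(exp_sample_meth))
        samp_alu = float(max(rng.poisson(scale), 1))
        ref_meth = float(max(rng.poisson(scale), 1))
        ref_alu = float(max(rng.poisson(scale), 1))
    sample = QmspMeasurement("sample", target_id, samp_meth, samp_alu)
    reference = QmspMeasurement("sssi_reference", target_id, ref_meth, ref_alu)
    return sample, reference


# ---------------------------------------------------------------------------
# Cohort writer


def write_cohort(config: SimulationConfig, out_dir) -> dict:
    """Generate and write a full cohort in the dialects the pipeline reads.

    Emits manifest.csv, beta.tsv, samples.tsv, expression.tsv,
    expression_samples.tsv, probe_to_gene.csv and ground_truth.json under
    ``out_dir``; returns the file paths.
    """
    from pathlib import Path

    from .core import write_manifest

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    probes = simulate_manifest(config)
    beta, samples, truth = simulate_beta_cohort(config, probes)
    expr, probe_to_gene, expr_samples = simulate_expression(config, truth)

    paths = {
        "manifest": out / "manifest.csv",
        "beta": out / "beta.tsv",
        "samples": out / "samples.tsv",
        "expression": out / "expression.tsv",
        "expression_samples": out / "expression_samples.tsv",
        "probe_to_gene": out / "probe_to_gene.csv",
        "ground_truth": out / "ground_truth.json",
    }
    write_manifest(probes, paths["manifest"])
    beta.to_csv(paths["beta"], sep="\t", float_format="%.6g")
    samples.to_csv(paths["samples"], sep="\t")
    expr.to_csv(paths["expression"], sep="\t", float_format="%.6g")
    expr_samples.to_csv(paths["expression_samples"], sep="\t")
    probe_to_gene.rename("gene").to_csv(paths["probe_to_gene"])
    truth.to_json(paths["ground_truth"])
    return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# Primary-metastasis pairs


def simulate_pair(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[MethylationProfilePair, dict]:
    """A primary/metastasis aberrant-set pair under a clonal or parallel model.

    Clonal: the metastasis inherits the primary's aberrant set and adds
    private events.  Parallel: primary and metastasis each combine a common
    ancestor set with independent private events.  ``call_flip_prob``
    applies independent per-block membership flips to both observed sets,
    modelling methylation-call noise.
    """
    if rng is None:
        rng = stream_rng(config.seed, f"pair:{config.pair_mode}")
    universe = [f"B{i:04d}" for i in range(config.pair_universe_size)]
    if config.pair_mode == "clonal":
        primary = set(rng.choice(universe, size=config.clonal_primary_size, replace=False))
        rest = sorted(set(universe) - primary)
        extra = set(rng.choice(rest, size=config.clonal_extra_events, replace=False))
        met = primary | extra
    else:
        ancestor = set(
            rng.choice(universe, size=config.parallel_ancestor_size, replace=False)
        )
        rest = sorted(set(universe) - ancestor)
        priv = rng.choice(rest, size=2 * config.parallel_private_size, replace=False)
        primary = ancestor | set(priv[: config.parallel_private_size])
        met = ancestor | set(priv[config.parallel_private_size :])

    def flip(s: set) -> frozenset:
        if config.call_flip_prob <= 0:
            return frozenset(s)
        flips = rng.random(len(universe)) < config.call_flip_prob
        return frozenset(
            b for b, f in zip(universe, flips) if (b in s) != f
        )

    pair = MethylationProfilePair(
        patient_id=f"sim_{config.pair_mode}",
        primary_aberrant=flip(primary),
        met_aberrant=flip(met),
        universe=frozenset(universe),
    )
    truth = {
        "mode": config.pair_mode,
        "primary_true": sorted(primary),
        "met_true": sorted(met),
    }
    return pair, truth
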