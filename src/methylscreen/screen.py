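"""Integrated chemical-genomic screen for methylation-silenced genes.

A gene is a candidate methylation-silenced gene when
(i) its promoter (TSS200) CpG-island block is unmethylated in normal tissue
and methylated in a minimum number of tumors, (ii) it is expressed in the
mesenchymal stem cell / osteoblast baseline (so silencing in tumors is
meaningful), (iii) its expression change is evaluable on the array platform,
and — in the treated cell line — its expression is re-activated by the
demethylating agent 5-aza-2'-deoxycytidine.  Optionally the screened cell
line must itself carry the methylation (beta >= 0.8, the cell-line
methylated state), so that the induction can be attributed to demethylation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .aberrant import AberrantCallConfig, call_aberrant_blocks
from .core import METH_LOWER


@dataclass(frozen=True)
class ScreenCriteria:
    """Thresholds for the integrated methylation-silencing screen."""

    aberrant_config: AberrantCallConfig = field(default_factory=AberrantCallConfig)
    baseline_threshold: float = 0.5
    induction_log2_threshold: float = 1.0
    restrict_to_tss200_cgi: bool = True
    require_cell_line_methylated: bool = True
    cell_line_meth_threshold: float = METH_LOWER["cell_line"]


@dataclass(frozen=True)
class CandidateGene:
    gene: str
    block_id: str
    n_methylated_tumors: int
    baseline_expressed: bool
    cell_line_methylated: bool
    log2_induction: float
    passes: bool


def eligible_gene_universe(
    blocks,
    block_beta: pd.DataFrame,
    tumors: list[str],
    normals: list[str],
    expressed_genes: set[str],
    platform_genes: set[str],
    criteria: ScreenCriteria = ScreenCriteria(),
) -> pd.DataFrame:
    """Genes eligible for the screen, with their representative block.

    Eligible genes have a TSS200 CpG-island block that is unmethylated in
    every normal and methylated in at least ``min_tumor_count`` tumors, are
    expressed in the MSC/osteoblast baseline, and are present on the
    expression platform (otherwise induction cannot be evaluated).  When a
    gene has several qualifying blocks the one methylated in the most
    tumors represents it.  Returns a DataFrame indexed by gene with columns
    ``block_id`` and ``n_methylated_tumors``.
    """
    if not expressed_genes:
        raise ValueError("empty baseline expressed-gene set")
    candidates = {}
    for b in blocks:
        if b.gene is None:
            continue
        if criteria.restrict_to_tss200_cgi and not (
            b.tss_relation == "TSS200" and b.cgi_relation == "Island"
        ):
            continue
        candidates.setdefault(b.gene, []).append(b.block_id)

    cand_blocks = sorted({bid for bids in candidates.values() for bid in bids})
    cand_blocks = [b for b in cand_blocks if b in block_beta.index]
    aberrant = call_aberrant_blocks(
        block_beta,
        tumors,
        normals,
        criteria.aberrant_config,
        candidate_blocks=cand_blocks,
    )

    rows = []
    for gene in sorted(candidates):
        if gene not in expressed_genes or gene not in platform_genes:
            continue
        hits = [bid for bid in candidates[gene] if bid in aberrant.index]
        if not hits:
            continue
        counts = aberrant.loc[hits, "n_methylated_tumors"]
        best = counts.sort_index().sort_values(ascending=False, kind="stable").index[0]
        rows.append((gene, best, int(aberrant.loc[best, "n_methylated_tumors"])))
    out = pd.DataFrame(rows, columns=["gene", "block_id", "n_methylated_tumors"])
    return out.set_index("gene")


def run_screen(
    universe: pd.DataFrame,
    cell_line_block_beta: pd.Series,
    induction: pd.DataFrame,
    criteria: ScreenCriteria = ScreenCriteria(),
) -> pd.DataFrame:
    """Apply the re-activation criteria to the eligible gene universe.

    ``universe`` is the output of :func:`eligible_gene_universe`;
    ``cell_line_block_beta`` the block beta values of the screened cell
    line; ``induction`` the output of
    :func:`methylscreen.expression.induction_screen` for that cell line.
    Returns one row per universe gene with per-criterion evidence and a
    ``passes`` flag, candidates first, sorted by descending log2 induction
    then gene symbol.
    """
    if universe.empty:
        return pd.DataFrame(
            columns=[
                "block_id",
                "n_methylated_tumors",
                "cell_line_beta",
                "cell_line_methylated",
                "log2_induction",
                "induced",
                "passes",
            ]
        )
    missing = universe["block_id"][~universe["block_id"].isin(cell_line_block_beta.index)]
    if not missing.empty:
        raise KeyError(
            f"cell-line beta missing for blocks of genes {missing.index.tolist()[:5]}"
        )
    out = universe.copy()
    out["cell_line_beta"] = cell_line_block_beta.loc[universe["block_id"]].to_numpy()
    out["cell_line_methylated"] = out["cell_line_beta"] >= criteria.cell_line_meth_threshold
    evaluable = out.index.intersection(induction.index)
    out = out.loc[evaluable]
    out["log2_induction"] = induction.loc[out.index, "log2_ratio"]
    out["induced"] = out["log2_induction"] >= criteria.induction_log2_threshold
    out["passes"] = out["induced"]
    if criteria.require_cell_line_methylated:
        out["passes"] &= out["cell_line_methylated"]
    out = out.sort_index().sort_values(
        ["passes", "log2_induction"], ascending=[False, False], kind="stable"
    )
    return out


def candidate_genes(screen_result: pd.DataFrame) -> list[CandidateGene]:
    """The passing rows of :func:`run_screen` as typed records."""
    return [
        CandidateGene(
            gene=gene,
            block_id=row["block_id"],
            n_methylated_tumors=int(row["n_methylated_tumors"]),
            baseline_expressed=True,  # universe membership implies it
            cell_line_methylated=bool(row["cell_line_methylated"]),
            log2_induction=float(row["log2_induction"]),
            passes=True,
        )
        for gene, row in screen_result[screen_result["passes"]].iterrows()
    ]


def demethylation_delta(
    block_beta_before: pd.Series,
    block_beta_after: pd.Series,
    gene_blocks: pd.Series | dict,
) -> pd.Series:
    """Per-gene promoter demethylation, in percentage points of beta.

    ``before``/``after`` are block beta values of a matched pair (mock vs
    5-aza-dC-treated cells, or untreated vs treated xenograft);
    ``gene_blocks`` maps each gene to its promoter TSS200 CpG-island block.
    Positive values mean methylation was lost under treatment.
    """
    mapping = pd.Series(gene_blocks)
    missing = [
        b
        for b in mapping
        if b not in block_beta_before.index or b not in block_beta_after.index
    ]
    if missing:
        raise KeyError(f"unmatched blocks in before/after pair: {missing[:5]}")
    delta = (
        block_beta_before.loc[mapping.to_numpy()].to_numpy()
        - block_beta_after.loc[mapping.to_numpy()].to_numpy()
    ) * 100.0
    return pd.Series(delta, index=mapping.index, name="demethylation_pp").sort_index()
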