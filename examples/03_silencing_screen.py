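"""Integrated chemical-genomic screen for methylation-silenced genes.

A gene passes when its TSS200 CpG island is unmethylated in normals and
methylated in tumors, it is expressed in the MSC/osteoblast baseline,
its promoter is methylated in the screened cell line (beta >= 0.8), and
5-aza-dC treatment re-activates it at least two-fold.  The cohort plants
50 silenced-and-reactivated genes among 2,000.
"""

import methylscreen as ms

cfg = ms.SimulationConfig(seed=8, n_genes=2000)
probes = ms.simulate_manifest(cfg)
blocks = ms.assemble_blocks(probes)
beta, samples, truth = ms.simulate_beta_cohort(cfg, probes)
bb = ms.block_beta(beta, blocks)
expr, probe_to_gene, expr_samples = ms.simulate_expression(cfg, truth)

gene_expr = ms.aggregate_genes(ms.normalize_75th(expr), probe_to_gene)
msc = sorted(expr_samples.index[expr_samples["group"] == "msc"])
ob = sorted(expr_samples.index[expr_samples["group"] == "osteoblast"])
expressed = ms.expressed_in_baseline(gene_expr, msc, ob)

tissue = samples[samples["material"] == "tissue"]
tumors = sorted(tissue.index[tissue["group"] == "primary"])
normals = sorted(tissue.index[tissue["group"] == "normal"])
universe = ms.eligible_gene_universe(
    blocks, bb, tumors, normals, expressed, set(gene_expr.index)
)
print(f"eligible gene universe (methylated promoter + baseline-expressed + on array): "
      f"{len(universe)} of {cfg.n_genes} genes")

induction = ms.induction_screen(gene_expr, "CL1_mock", "CL1_aza")
result = ms.run_screen(universe, bb["CL1_mock"], induction)
candidates = result[result["passes"]]
planted = set(truth.silenced_genes)
hit = len(set(candidates.index) & planted)
print(f"re-activated candidates in CL1: {len(candidates)} "
      f"({hit}/{len(planted)} planted silenced genes recovered)")
top = candidates.iloc[0]
print(f"strongest candidate {candidates.index[0]}: cell-line promoter beta "
      f"{top['cell_line_beta']:.2f}, log2 induction {top['log2_induction']:.2f}")

gene_blocks = {g: truth.gene_tss200_block[g] for g in truth.silenced_genes}
deltas = ms.demethylation_delta(bb["CL1_mock"], bb["CL1_aza"], gene_blocks)
print(f"promoter demethylation under 5-aza-dC: {deltas.min():.0f}-{deltas.max():.0f} "
      "percentage points of beta across the silenced genes")
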