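"""Assemble CpG probes into genomic blocks and call methylation states.

Simulates a small probe manifest, averages probe beta values per block, and
discretises block values with the tissue / cell-line threshold schemes.
"""

import methylscreen as ms

cfg = ms.SimulationConfig(seed=1, n_genes=25)
probes = ms.simulate_manifest(cfg)
blocks = ms.assemble_blocks(probes)
beta, samples, truth = ms.simulate_beta_cohort(cfg, probes)
bb = ms.block_beta(beta, blocks)

print(f"{len(probes)} probes -> {len(blocks)} genomic blocks "
      f"(key: gene x TSS category x CGI relation x CGI id)")

block = truth.gene_tss200_block["GENE00000"]
for sample, material in [("T01", "tissue"), ("CL1_mock", "cell_line")]:
    value = bb.loc[block, sample]
    state = ms.call_state(value, material)
    print(f"{block}  {sample}: beta = {value:.3f} -> {state} ({material} thresholds)")

# A block beta of 0.45 is 'methylated' in a tissue (>= 0.4) but only
# 'partial' in a near-clonal cancer cell line (methylated needs >= 0.8).
print("beta 0.45:", ms.call_state(0.45, "tissue"), "(tissue) vs",
      ms.call_state(0.45, "cell_line"), "(cell line)")
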