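"""Find aberrantly methylated CpG-island blocks and the CIMP-like subgroup.

Generates a tumor/normal cohort with 50 planted aberrant promoter blocks
and a 10-tumor high-methylation subgroup, then recovers both: blocks
unmethylated in every normal (beta < 0.2) and methylated (beta >= 0.4) in
at least 6 of 28 tumors are called aberrant, and hierarchical clustering
over normally unmethylated islands separates high- from low-methylators.
"""

from sklearn.metrics import adjusted_rand_score

import methylscreen as ms

cfg = ms.SimulationConfig(seed=4)
probes = ms.simulate_manifest(cfg)
blocks = ms.assemble_blocks(probes)
beta, samples, truth = ms.simulate_beta_cohort(cfg, probes)
bb = ms.block_beta(beta, blocks)

tissue = samples[samples["material"] == "tissue"]
normals = sorted(tissue.index[tissue["group"] == "normal"])
tumors = sorted(tissue.index[tissue["group"] == "primary"])

reference = ms.normally_unmethylated_cgi_blocks(bb, blocks, normals)
aberrant = ms.call_aberrant_blocks(bb, tumors, normals)
recovered = set(truth.aberrant_blocks) <= set(aberrant.index)
print(f"normally unmethylated CGI blocks: {len(reference)}")
print(f"aberrantly methylated blocks called: {len(aberrant)} "
      f"(every planted block recovered: {recovered})")
top_count = int(aberrant["n_methylated_tumors"].iloc[0])
print("top call:", aberrant.index[0],
      f"methylated in {top_count} of {len(tumors)} tumors")

labels = ms.cluster_samples(bb, reference, samples=tumors, seed=4).labels(2)
truth_labels = [truth.cluster_labels[t] for t in labels.index]
ari = adjusted_rand_score(truth_labels, labels.to_numpy())
print(f"cluster cut at k=2 vs planted high/low subgroup: adjusted Rand index = {ari:.2f}")

high = truth.high_methylator_samples[0]
frac = ms.methylated_fraction(bb, high, reference, "tissue")
print(f"methylated-CGI fraction of high-methylator {high}: {frac:.2f} "
      "(share of normally unmethylated islands that are methylated in this tumor)")
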