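"""Compute the transcriptional risk score and compare it between subtypes.

The eGene risk-direction table is built from planted differential genes
(+1 when higher expression carries risk, -1 when lower expression does);
per-gene z-scores are polarized, summed and re-standardized.  A higher TRS
in PBmu mirrors the elevated genetic risk signal reported for the
mucosal-like subtype.
"""

import pbmustrat as pb

cfg = pb.SimulationConfig(n_cd_peripheral=40, n_genes=3000, n_de_genes=300,
                          de_log2fc=1.5, seed=2)
cohort = pb.generate_cohort(cfg)
normed, _ = pb.median_of_ratios_normalize(cohort.counts)
log2m = pb.log2_transform(normed)
meta = cohort.metadata
peri = meta[(meta.compartment == "peripheral") & (meta.disease == "CD")]
labels = peri["subtype_label"]
mat = log2m.subset_samples(peri.index)

table = pb.simulate.generate_eqtl_risk_table(cohort, n_egenes=142,
                                             frac_risk_up=0.9, seed=2)
vec = pb.trs.compute_trs(mat, table)
test, stat, p = pb.trs.compare_trs(vec, labels)

print(f"eGenes used: {vec.n_egenes_used} (missing: {len(vec.missing_egenes)})")
print(f"mean TRS  PBmu: {vec.scores[labels == 'PBmu'].mean():+.2f}   "
      f"PBT: {vec.scores[labels == 'PBT'].mean():+.2f}")
print(f"{test}: statistic={stat:.2f}, p={p:.3g}")
# Scores are unitless z-values (mean 0, SD 1 across samples); the positive
# PBmu mean and tiny p-value show the polarized risk signal concentrates in
# the mucosal-like subtype.
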