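"""Post-surgical reversion of the PBmu signature and kinase-target filtering.

Paired pre/post differential expression runs separately within each
subtype: with full reversion the PBmu contrast lights up while PBT stays
null, and PBmu post-operative profiles correlate more with the pre-surgery
PBT centroid than with their own.  Kinase candidates are genes with
selective pre-surgical enhancement (fold >= 2 in PBmu vs PBT) and a
selective ~twofold post-operative decrease in PBmu but not PBT.
"""

import pbmustrat as pb

cfg = pb.SimulationConfig(n_cd_peripheral=40, n_genes=3000, n_de_genes=300,
                          de_log2fc=2.0, n_postop_pairs=20,
                          reversion_strength=1.0, seed=4)
cohort = pb.simulate.generate_postop(pb.generate_cohort(cfg), cfg)
normed, _ = pb.median_of_ratios_normalize(cohort.counts)
log2m = pb.log2_transform(normed)
meta = cohort.metadata
peri = meta[(meta.compartment == "peripheral") & (meta.disease == "CD")
            & (meta.timepoint == "surgery")]
labels = peri["subtype_label"]
post_ids = meta.index[meta.timepoint == "postop"]

rep = pb.postop.reversion_analysis(
    log2m.subset_samples(peri.index), labels,
    log2m.subset_samples(post_ids), pb.simulate.postop_pairs(cohort))
print(f"paired DE genes (p<0.001, FDR<0.013): {rep.de_counts}")
cc = rep.centroid_correlations
pbmu = cc[cc.subtype == "PBmu"]
print(f"PBmu postop samples closer to the PBT centroid: "
      f"{(pbmu.corr_pbt_centroid > pbmu.corr_pbmu_centroid).mean():.0%}")

de = pb.stratify.differential_expression(
    log2m.subset_samples(peri.index),
    labels.index[labels == "PBmu"].tolist(),
    labels.index[labels == "PBT"].tolist())
kinome = list(cohort.gene_truth.index[:400])  # stand-in kinome gene list
cands = pb.postop.kinase_filter(de, rep.paired_de["PBmu"],
                                rep.paired_de["PBT"], kinome)
print(f"kinase candidates passing all three co-occurrence rules: {len(cands)}")
print(cands.head().round(2))
# A large PBmu paired-DE count with a near-zero PBT count is the reversion
# fingerprint; each candidate row shows the pre-surgery fold and the post/pre
# folds that qualified it.
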