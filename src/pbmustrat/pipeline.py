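"""End-to-end orchestration: simulate -> normalize -> stratify -> enrich ->
TRS -> serology -> postop -> panel, with every stage artifact written to an
output directory and a single JSON report of the headline metrics."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment, panel as panel_mod, postop as postop_mod, serology as sero_mod
from . import simulate, stratify, trs as trs_mod
from .preprocess import log2_transform, median_of_ratios_normalize, write_expression

log = logging.getLogger("pbmustrat")

DEFAULT_CONFIG = {
    "seed": 0,
    "simulate": {},              # SimulationConfig overrides
    "de": {"fold_min": 2.0, "p_max": 0.001, "fdr_max": 0.002},
    "paired_de": {"p_max": 0.001, "fdr_max": 0.013},
    "classify": {"selection_p": 0.001},
    "bootstrap": {"n_boot": 100},
    "trs": {"n_egenes": 142, "frac_risk_up": 0.9},
    "serology": {"effect": 1.0},
    "panel": {"target_size": 42, "t_low": 3.5, "t_high": 7.0,
              "n_reference_profiles": 10},
    "kinase": {"pre_threshold": 2.0, "attenuation_threshold": 2.0, "pbt_band": 1.5},
}


def load_config(path=None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def full_run(config: dict, out_dir) -> dict:
    """Run the whole pipeline on a synthetic cohort; returns the report dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))

    sim_cfg = simulate.SimulationConfig(**{"seed": seed, **config.get("simulate", {})})
    sim_cfg.validate()
    log.info("simulating cohort (seed=%d)", seed)
    cohort = simulate.generate_cohort(sim_cfg)
    cohort = simulate.generate_postop(cohort)
    serology_panel = simulate.generate_serology(cohort, seed=seed + 11, **config["serology"])
    risk_table = simulate.generate_eqtl_risk_table(cohort, seed=seed + 13, **config["trs"])
    reference, target = simulate.generate_reference_profiles(
        cohort, n_profiles=config["panel"]["n_reference_profiles"], seed=seed + 17
    )

    write_expression(cohort.counts, out / "counts.tsv")
    cohort.metadata.to_csv(out / "metadata.tsv", sep="\t")
    cohort.gene_truth.to_csv(out / "gene_truth.tsv", sep="\t")
    cohort.sample_truth.to_csv(out / "sample_truth.tsv", sep="\t")
    risk_table.to_csv(out / "eqtl_risk_table.tsv", sep="\t", index=False)
    serology_panel.to_csv(out / "serology.tsv", sep="\t")
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump({**config, "simulate": asdict(sim_cfg)}, fh)

    log.info("normalizing")
    normed, factors = median_of_ratios_normalize(cohort.counts)
    log2m = log2_transform(normed)
    factors.to_csv(out / "size_factors.tsv", sep="\t")

    meta = cohort.metadata
    peri = meta[(meta["compartment"] == "peripheral") & (meta["disease"] == "CD")
                & (meta["timepoint"] == "surgery")]
    labels = peri["subtype_label"]
    peri_log2 = log2m.subset_samples(peri.index)

    log.info("stratifying")
    pca_scores, evr = stratify.run_pca(peri_log2, n_components=2)
    pca_scores.to_csv(out / "pca_scores.tsv", sep="\t")
    clusters = stratify.hierarchical_cluster(peri_log2, k=2)
    de = stratify.differential_expression(
        peri_log2,
        labels.index[labels == "PBmu"].tolist(),
        labels.index[labels == "PBT"].tolist(),
        **config["de"],
    )
    de.to_csv(out / "de_table.tsv", sep="\t")

    loo_correct = _leave_one_out_accuracy(
        peri_log2, labels, config["classify"]["selection_p"], seed
    )
    boot_rate, boot_rates = stratify.bootstrap_cv(
        peri_log2, labels, n_boot=config["bootstrap"]["n_boot"],
        selection_p=config["classify"]["selection_p"], seed=seed + 19,
    )
    pd.Series(boot_rates).to_csv(out / "bootstrap_rates.tsv", sep="\t")

    log.info("enrichment")
    signatures = {
        subset: cohort.gene_truth.index[cohort.gene_truth["subset"] == subset].tolist()
        for subset in sim_cfg.subset_signature_sizes
    }
    scores = enrichment.single_sample_enrichment(peri_log2, signatures, method="gsva")
    scores.to_csv(out / "enrichment_scores.tsv", sep="\t")

    log.info("TRS")
    trs_vec = trs_mod.compute_trs(peri_log2, risk_table)
    trs_vec.scores.to_csv(out / "trs.tsv", sep="\t")
    trs_test = trs_mod.compare_trs(trs_vec, labels)

    log.info("serology")
    qss = sero_mod.quartile_sum(serology_panel.loc[peri.index])
    qss.to_csv(out / "qss.tsv", sep="\t")
    pbmu_ids = labels.index[labels == "PBmu"]
    sero_assoc = sero_mod.associate_serology(
        qss.loc[pbmu_ids], meta.loc[pbmu_ids, "resection_length"]
    )

    log.info("postop")
    pairs = simulate.postop_pairs(cohort)
    post_ids = meta.index[meta["timepoint"] == "postop"]
    rev = postop_mod.reversion_analysis(
        peri_log2, labels, log2m.subset_samples(post_ids), pairs,
        **config["paired_de"],
    )
    kinase_universe = de.index[:200].tolist()  # stand-in kinome slice of the universe
    kinases = pd.DataFrame()
    if {"PBmu", "PBT"} <= set(rev.paired_de):
        kinases = postop_mod.kinase_filter(
            de, rev.paired_de["PBmu"], rev.paired_de["PBT"], kinase_universe,
            **config["kinase"],
        )
        kinases.to_csv(out / "kinase_candidates.tsv", sep="\t")

    log.info("panel")
    seed_panel = panel_mod.select_seed_panel(
        de, fold_min=config["de"]["fold_min"],
        t_low=config["panel"]["t_low"], t_high=config["panel"]["t_high"],
    )
    # absolute PBmu mean profile: comparable to absolute reference profiles
    query = peri_log2.data.loc[:, labels.index[labels == "PBmu"]].mean(axis=1)
    target_size = min(config["panel"]["target_size"], len(seed_panel))
    refinement = panel_mod.sequential_deletion_refine(
        seed_panel, query, reference, target,
        target_size=target_size, t_values=de["statistic"],
    )
    with open(out / "panel_genes.txt", "w") as fh:
        fh.write("\n".join(refinement.retained_genes) + "\n")
    panel_report = panel_mod.evaluate_panel(
        peri_log2, refinement.retained_genes,
        trs_scores=trs_vec.scores, subset_scores=scores, labels=labels, seed=seed,
    )

    truth = cohort.sample_truth.loc[peri.index, "subtype"]
    cluster_acc = _best_label_agreement(clusters.loc[peri.index], truth)
    report = {
        "seed": seed,
        "n_samples": int(cohort.counts.shape[1]),
        "n_genes": int(cohort.counts.shape[0]),
        "pca_explained_variance": [float(v) for v in evr],
        "cluster_accuracy_vs_truth": cluster_acc,
        "n_de_genes": int(de["passes_filter"].sum()),
        "loo_consensus_accuracy": loo_correct,
        "bootstrap_error": boot_rate,
        "trs_test": {"test": trs_test[0], "statistic": trs_test[1], "p": trs_test[2]},
        "serology_assoc_pbmu": list(map(float, sero_assoc))
        if not isinstance(sero_assoc[0], str) else
        {"test": sero_assoc[0], "statistic": float(sero_assoc[1]), "p": float(sero_assoc[2])},
        "postop_de_counts": rev.de_counts,
        "n_kinase_candidates": int(len(kinases)),
        "panel_size": len(refinement.retained_genes),
        "panel_nmf_accuracy": panel_report.get("nmf_accuracy"),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _leave_one_out_accuracy(matrix, labels, selection_p: float, seed: int) -> float:
    """Leave-one-out consensus-classification agreement with the given labels."""
    from .preprocess import ExpressionMatrix

    correct = 0
    ids = list(matrix.sample_ids)
    for sid in ids:
        train_ids = [s for s in ids if s != sid]
        train = matrix.subset_samples(train_ids)
        test = matrix.subset_samples([sid])
        calls = stratify.train_and_classify(
            train, labels.loc[train_ids], test, selection_p=selection_p, seed=seed
        )
        if calls.loc[sid, "call"] == labels.loc[sid]:
            correct += 1
    return correct / len(ids)


def _best_label_agreement(clusters: pd.Series, truth: pd.Series) -> float:
    """Cluster-vs-truth agreement maximized over the 2-label permutation."""
    accs = []
    for mapping in ({1: "PBmu", 2: "PBT"}, {1: "PBT", 2: "PBmu"}):
        mapped = clusters.map(mapping)
        accs.append(float((mapped == truth).mean()))
    return max(accs)
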