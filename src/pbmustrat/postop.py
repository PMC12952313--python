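"""Longitudinal post-surgical reversion analysis and the kinase-target filter.

Paired pre/post differential expression is run separately within each
peripheral subtype; the reversion of the PBmu signature is quantified by
(i) the paired-DE gene counts at the stated thresholds, (ii) Pearson
correlation of each post-operative profile with the pre-surgery PBT and
PBmu centroids over the subtype-defining gene panel, and (iii) paired
changes in cell-subset enrichment scores.  Candidate kinases are genes
with selectively enhanced pre-surgical expression in PBmu and a selective
post-operative decrease in PBmu but not PBT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import compare_two_groups
from .preprocess import ExpressionMatrix
from .stratify import differential_expression

__all__ = ["reversion_analysis", "kinase_filter", "ReversionReport"]


@dataclass
class ReversionReport:
    paired_de: dict                      # subtype -> DE DataFrame (pre vs post)
    de_counts: dict                      # subtype -> n genes passing thresholds
    centroid_correlations: pd.DataFrame  # postop sample x (corr_pbt, corr_pbmu, subtype)
    subset_change_tests: pd.DataFrame | None = None
    pre_panel: list = field(default_factory=list)


def _check_pairs(pairs: pd.DataFrame, pre_ids, post_ids) -> pd.DataFrame:
    need = {"postop_sample_id", "surgery_sample_id"}
    if not need.issubset(pairs.columns):
        raise ValueError(f"pairing table needs columns {sorted(need)}")
    unknown_post = set(post_ids) - set(pairs["postop_sample_id"])
    if unknown_post:
        raise ValueError(f"unpaired postop sample(s): {sorted(unknown_post)[:5]}")
    unknown_pre = set(pairs["surgery_sample_id"]) - set(pre_ids)
    if unknown_pre:
        raise ValueError(f"pairing references unknown surgery sample(s): {sorted(unknown_pre)[:5]}")
    return pairs


def reversion_analysis(
    pre: ExpressionMatrix,
    labels,
    post: ExpressionMatrix,
    pairs: pd.DataFrame,
    p_max: float = 0.001,
    fdr_max: float = 0.013,
    fold_min: float = 1.0,
    pre_fold_min: float = 2.0,
    pre_p_max: float = 0.001,
    pre_fdr_max: float = 0.002,
    scores_pre: pd.DataFrame | None = None,
    scores_post: pd.DataFrame | None = None,
) -> ReversionReport:
    """Paired pre-vs-post analysis within each subtype.

    ``labels`` maps pre-surgery sample ids to PBmu/PBT.  The paired DE
    contrast is postop minus surgery on log2 values at (p_max, fdr_max,
    fold_min), so a post-surgical decrease has log2fc < 0 and its
    post/pre fold is 2**log2fc (directly consumable by ``kinase_filter``).  Centroid correlations use the cross-sectional PBmu-vs-PBT
    panel selected at the (pre_*) thresholds.  If pre/post enrichment
    scores are supplied, each subset's paired change is compared between
    subtypes with the gated two-group test.
    """
    labels = pd.Series(labels) if not isinstance(labels, pd.Series) else labels
    pairs = _check_pairs(pairs, pre.sample_ids, post.sample_ids)
    pairs = pairs[pairs["postop_sample_id"].isin(post.sample_ids)]

    paired_de: dict[str, pd.DataFrame] = {}
    de_counts: dict[str, int] = {}
    merged = ExpressionMatrix(
        pd.concat([pre.data, post.data.loc[:, ~post.data.columns.isin(pre.data.columns)]], axis=1),
        pre.scale,
    )
    for subtype in ("PBmu", "PBT"):
        sub_pre = [
            s for s in pairs["surgery_sample_id"]
            if labels.get(s) == subtype
        ]
        sub_post = [
            pairs.set_index("surgery_sample_id").loc[s, "postop_sample_id"]
            for s in sub_pre
        ]
        if len(sub_pre) < 2:
            continue
        de = differential_expression(
            merged, sub_post, sub_pre, paired=True,
            fold_min=fold_min, p_max=p_max, fdr_max=fdr_max,
        )
        paired_de[subtype] = de
        de_counts[subtype] = int(de["passes_filter"].sum())

    # cross-sectional panel at surgery defines the centroid gene set
    pbmu_pre = labels.index[labels == "PBmu"].tolist()
    pbt_pre = labels.index[labels == "PBT"].tolist()
    pre_de = differential_expression(
        pre, pbmu_pre, pbt_pre,
        fold_min=pre_fold_min, p_max=pre_p_max, fdr_max=pre_fdr_max,
    )
    panel = pre_de.index[pre_de["passes_filter"]].tolist()
    if len(panel) < 3:
        panel = pre_de.reindex(pre_de["p_value"].sort_values().index).index[:50].tolist()
    cent_pbmu = pre.data.loc[panel, pbmu_pre].mean(axis=1).to_numpy()
    cent_pbt = pre.data.loc[panel, pbt_pre].mean(axis=1).to_numpy()
    rows = []
    pre_of = pairs.set_index("postop_sample_id")["surgery_sample_id"]
    for sid in pairs["postop_sample_id"]:
        prof = post.data.loc[panel, sid].to_numpy()
        rows.append(
            {
                "postop_sample_id": sid,
                "subtype": labels.get(pre_of[sid], "NA"),
                "corr_pbt_centroid": float(np.corrcoef(prof, cent_pbt)[0, 1]),
                "corr_pbmu_centroid": float(np.corrcoef(prof, cent_pbmu)[0, 1]),
            }
        )
    cent = pd.DataFrame(rows).set_index("postop_sample_id")

    subset_tests = None
    if scores_pre is not None and scores_post is not None:
        recs = []
        diffs = {}
        for sid in pairs["postop_sample_id"]:
            pre_id = pre_of[sid]
            if pre_id in scores_pre.columns and sid in scores_post.columns:
                diffs[sid] = (scores_post[sid] - scores_pre[pre_id], labels.get(pre_id))
        if diffs:
            ddf = pd.DataFrame({k: v[0] for k, v in diffs.items()})
            grp = np.array([v[1] for v in diffs.values()])
            for subset in ddf.index:
                vals = ddf.loc[subset].to_numpy()
                if pd.unique(grp).size == 2 and min((grp == g).sum() for g in pd.unique(grp)) >= 3:
                    name, stat, p = compare_two_groups(vals, grp)
                    recs.append({"subset": subset, "test": name, "statistic": stat, "p_value": p})
            subset_tests = pd.DataFrame(recs).set_index("subset") if recs else None

    return ReversionReport(
        paired_de=paired_de,
        de_counts=de_counts,
        centroid_correlations=cent,
        subset_change_tests=subset_tests,
        pre_panel=panel,
    )


def kinase_filter(
    pre_de: pd.DataFrame,
    pbmu_paired_de: pd.DataFrame,
    pbt_paired_de: pd.DataFrame,
    kinase_universe,
    pre_threshold: float = 2.0,
    attenuation_threshold: float = 2.0,
    pbt_band: float = 1.5,
    require_significance: bool = False,
    sig_p: float = 0.05,
) -> pd.DataFrame:
    """Kinases with selective pre-surgical enhancement and PBmu-selective decay.

    ``pre_de`` is the cross-sectional PBmu-vs-PBT contrast (log2fc = PBmu
    minus PBT); the paired inputs are postop-minus-surgery contrasts within
    each subtype.  A kinase is selective when its pre-surgery linear fold
    is >= pre_threshold, its PBmu post/pre fold is <= 1/attenuation_threshold,
    and its PBT post/pre fold lies within [1/pbt_band, pbt_band].  Sorted
    by pre-surgery fold, descending.
    """
    kinases = [k for k in kinase_universe if k in pre_de.index]
    if not kinases:
        raise ValueError("kinase universe is disjoint from the DE gene universe")
    for name, df in (("pbmu_paired_de", pbmu_paired_de), ("pbt_paired_de", pbt_paired_de)):
        missing = [k for k in kinases if k not in df.index]
        if missing:
            raise ValueError(f"{name} lacks kinase gene(s): {missing[:5]}")
    if pre_threshold <= 0 or attenuation_threshold <= 0 or pbt_band <= 0:
        raise ValueError("thresholds must be positive")

    pre_fc = 2.0 ** pre_de.loc[kinases, "log2fc"]
    post_fc_pbmu = 2.0 ** pbmu_paired_de.loc[kinases, "log2fc"]
    post_fc_pbt = 2.0 ** pbt_paired_de.loc[kinases, "log2fc"]
    selective = (
        (pre_fc >= pre_threshold)
        & (post_fc_pbmu <= 1.0 / attenuation_threshold)
        & (post_fc_pbt >= 1.0 / pbt_band)
        & (post_fc_pbt <= pbt_band)
    )
    if require_significance:
        selective &= pre_de.loc[kinases, "p_value"] < sig_p
    out = pd.DataFrame(
        {
            "pre_fc": pre_fc,
            "post_fc_pbmu": post_fc_pbmu,
            "post_fc_pbt": post_fc_pbt,
            "selective": selective,
        },
        index=pd.Index(kinases, name="gene_id"),
    )
    return out[out["selective"]].sort_values("pre_fc", ascending=False)
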