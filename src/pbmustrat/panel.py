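"""Biomarker-panel derivation and evaluation.

The seed panel is the set of up-regulated differential genes inside a
moderate t-value window (strongly but not extremely differential, the
regime where co-expression matching is informative).  The panel is then
refined by greedy backward elimination: at each step the gene whose
deletion most improves Pearson similarity between the panel-restricted
query profile and a target ("mucosal-like") reference profile is removed,
subject to the target keeping its rank among all reference profiles; ties
are broken by removing the gene with the smallest |t|.  The refined panel
is scored as a gene set (GSVA) and reported against the TRS and subset
enrichment scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import correlate, single_sample_enrichment
from .preprocess import ExpressionMatrix
from .stratify import _nmf_assign

__all__ = [
    "select_seed_panel",
    "coexpression_similarity",
    "sequential_deletion_refine",
    "evaluate_panel",
    "PanelRefinement",
]


@dataclass
class PanelRefinement:
    initial_genes: list
    retained_genes: list
    deletion_order: list
    similarity_trajectory: list
    target_rank_trajectory: list


def select_seed_panel(de: pd.DataFrame, fold_min: float = 2.0,
                      t_low: float = 3.5, t_high: float = 7.0) -> list[str]:
    """Up-regulated genes with fold >= fold_min and t in [t_low, t_high]."""
    if t_low > t_high:
        raise ValueError(f"t_low ({t_low}) exceeds t_high ({t_high})")
    mask = (
        (de["direction"] == "up")
        & (de["fold"] >= fold_min)
        & (de["statistic"] >= t_low)
        & (de["statistic"] <= t_high)
    )
    genes = de.index[mask].tolist()
    if not genes:
        raise ValueError("no gene satisfies the seed-panel window")
    return genes


def _similarities(panel, query: pd.Series, reference: pd.DataFrame) -> pd.Series:
    common = [g for g in panel if g in reference.index and g in query.index]
    if len(common) < 2:
        raise ValueError("fewer than 2 panel genes overlap the reference")
    q = query.loc[common].to_numpy(dtype=float)
    sims = {}
    for prof in reference.columns:
        r = reference.loc[common, prof].to_numpy(dtype=float)
        if q.std() == 0 or r.std() == 0:
            sims[prof] = np.nan
        else:
            sims[prof] = float(np.corrcoef(q, r)[0, 1])
    return pd.Series(sims)


def coexpression_similarity(panel, query_profile: pd.Series,
                            reference: pd.DataFrame, target: str):
    """Pearson similarity of the panel-restricted query to each reference profile.

    Returns (similarities Series sorted descending, rank of the target
    profile, 1 = most similar).
    """
    sims = _similarities(panel, query_profile, reference)
    order = sims.sort_values(ascending=False)
    rank = int(np.where(order.index == target)[0][0]) + 1
    return order, rank


def sequential_deletion_refine(
    initial,
    query_profile: pd.Series,
    reference: pd.DataFrame,
    target: str,
    target_size: int = 42,
    min_target_rank: int = 1,
    t_values: pd.Series | None = None,
) -> PanelRefinement:
    """Greedy backward elimination preserving target-profile similarity.

    At each step the deletion maximizing similarity to the target profile
    is applied (ties: smallest |t|, then lexicographic gene id), provided
    the target's rank stays <= min_target_rank; stops at ``target_size``
    or when every deletion would break the rank constraint.
    """
    initial = list(initial)
    if not (2 <= target_size <= len(initial)):
        raise ValueError("need |initial| >= target_size >= 2")
    sims0, rank0 = coexpression_similarity(initial, query_profile, reference, target)
    if rank0 > min_target_rank:
        raise ValueError(
            f"target profile ranks {rank0} (> {min_target_rank}) for the "
            "initial panel; constraint unsatisfiable at start"
        )
    panel = list(initial)
    deletion_order: list[str] = []
    sim_traj = [float(sims0[target])]
    rank_traj = [rank0]

    def tkey(g):
        if t_values is not None and g in t_values.index:
            return (abs(float(t_values[g])), str(g))
        return (float("inf"), str(g))

    while len(panel) > target_size:
        best = None  # (sim, -rank_ok) candidate
        for g in sorted(panel, key=tkey):
            trial = [x for x in panel if x != g]
            try:
                sims, rank = coexpression_similarity(trial, query_profile, reference, target)
            except ValueError:
                continue
            if rank > min_target_rank:
                continue
            sim = float(sims[target])
            if best is None or sim > best[0] + 1e-12:
                best = (sim, g, rank)
        if best is None:
            break
        sim, gene, rank = best
        panel.remove(gene)
        deletion_order.append(gene)
        sim_traj.append(sim)
        rank_traj.append(rank)
    return PanelRefinement(
        initial_genes=initial,
        retained_genes=panel,
        deletion_order=deletion_order,
        similarity_trajectory=sim_traj,
        target_rank_trajectory=rank_traj,
    )


def evaluate_panel(
    matrix: ExpressionMatrix,
    panel,
    trs_scores: pd.Series | None = None,
    subset_scores: pd.DataFrame | None = None,
    labels: pd.Series | None = None,
    seed: int = 0,
) -> dict:
    """Report the panel's association structure and classification power.

    Returns a dict with per-gene correlations to the TRS and each subset
    score, the panel GSVA score per sample, and (if labels are given) the
    rank-2 NMF 2-cluster accuracy of the panel restricted to those samples.
    """
    panel = [g for g in panel if g in matrix.gene_ids]
    if len(panel) < 2:
        raise ValueError("fewer than 2 panel genes present in the matrix")
    report: dict = {"panel": list(panel)}

    rows = []
    for g in panel:
        expr = matrix.data.loc[g]
        rec = {"gene_id": g}
        if trs_scores is not None:
            rho, p = correlate(expr.loc[trs_scores.index].to_numpy(),
                               trs_scores.to_numpy(), method="pearson")
            rec["trs_rho"], rec["trs_p"] = rho, p
        if subset_scores is not None:
            for subset in subset_scores.index:
                rho, p = correlate(
                    expr.loc[subset_scores.columns].to_numpy(),
                    subset_scores.loc[subset].to_numpy(), method="pearson",
                )
                rec[f"{subset}_rho"], rec[f"{subset}_p"] = rho, p
        rows.append(rec)
    report["gene_correlations"] = pd.DataFrame(rows).set_index("gene_id")

    report["panel_score"] = single_sample_enrichment(
        matrix, {"panel": list(panel)}, method="gsva"
    ).loc["panel"]

    if labels is not None:
        samp = labels.index
        X = matrix.data.loc[panel, samp].to_numpy(dtype=float).T
        # unsupervised 2-component NMF assignment, mapped to labels by majority
        assign = _nmf_assign(X, labels.to_numpy(), X, seed=seed)
        report["nmf_accuracy"] = float((assign == labels.to_numpy()).mean())
    return report
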