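"""Genetic transcriptional risk score (TRS).

For each eGene in an eQTL risk-direction table, expression is z-scored
across samples (population SD) and polarized by the direction of risk:
genes for which low expression carries risk (direction -1) are flipped.
The polarized z-scores are summed per sample and the sums re-standardized,
yielding a unitless per-sample score whose elevation reflects a
risk-consistent transcriptional state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import compare_two_groups
from .preprocess import ExpressionMatrix

__all__ = ["read_risk_table", "validate_risk_table", "compute_trs", "compare_trs", "TRSVector"]


@dataclass
class TRSVector:
    scores: pd.Series                 # sample_id -> standardized score
    n_egenes_used: int
    missing_egenes: list = field(default_factory=list)


def validate_risk_table(table: pd.DataFrame) -> pd.DataFrame:
    if "egene_id" not in table.columns or "direction" not in table.columns:
        raise ValueError("risk table needs 'egene_id' and 'direction' columns")
    if table["egene_id"].duplicated().any():
        dup = table["egene_id"][table["egene_id"].duplicated()].tolist()
        raise ValueError(f"duplicate eGene identifiers: {dup[:5]}")
    if not set(table["direction"]).issubset({1, -1}):
        raise ValueError("direction must be +1 or -1")
    return table


def read_risk_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    table["direction"] = table["direction"].astype(int)
    return validate_risk_table(table)


def compute_trs(
    matrix: ExpressionMatrix,
    table: pd.DataFrame,
    min_fraction_present: float = 0.5,
) -> TRSVector:
    """Compute the standardized, polarized transcriptional risk score.

    eGenes absent from the matrix or with zero variance are skipped and
    reported as missing; if the fraction present falls below
    ``min_fraction_present`` an error is raised.  The returned scores have
    mean 0 and population SD 1 across samples.
    """
    validate_risk_table(table)
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    present_mask = table["egene_id"].isin(matrix.gene_ids)
    missing = table.loc[~present_mask, "egene_id"].tolist()
    used = table[present_mask]
    if len(used) / len(table) < min_fraction_present:
        raise ValueError(
            f"only {len(used)}/{len(table)} eGenes present "
            f"(< min_fraction_present={min_fraction_present})"
        )
    X = matrix.data.loc[used["egene_id"]].to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=0)
    zero = sd == 0
    if zero.any():
        dropped = used["egene_id"].to_numpy()[zero].tolist()
        warnings.warn(f"{len(dropped)} zero-variance eGene(s) excluded: {dropped[:5]}")
        missing.extend(dropped)
        X = X[~zero]
        used = used[~zero]
        sd = sd[~zero]
    if len(used) == 0:
        raise ValueError("no usable eGene after exclusions")
    z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    polarized = z * used["direction"].to_numpy()[:, None]
    sums = polarized.sum(axis=0)
    ssd = sums.std(ddof=0)
    if ssd == 0:
        raise ValueError("degenerate TRS: all samples identical")
    scores = (sums - sums.mean()) / ssd
    return TRSVector(
        scores=pd.Series(scores, index=matrix.sample_ids, name="trs"),
        n_egenes_used=len(used),
        missing_egenes=missing,
    )


def compare_trs(trs: TRSVector, groups) -> tuple[str, float, float]:
    """Shapiro-Wilk-gated two-group comparison of the TRS between groups."""
    groups = pd.Series(groups, index=trs.scores.index) if not isinstance(groups, pd.Series) else groups.loc[trs.scores.index]
    return compare_two_groups(trs.scores.to_numpy(), groups.to_numpy())
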