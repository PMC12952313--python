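"""Serologic quartile-sum scoring of anti-microbial antibody responses.

Per analyte, cohort quartile cut-points bin each titer 1-4 (<=Q1 -> 1,
<=median -> 2, <=Q3 -> 3, else 4); the quartile sum score (QSS) is the sum
of bins over the four microbial analytes ASCA, OmpC, I2 and CBir1 (range
4-16).  ANCA is carried in the panel but excluded from the default score.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .enrichment import compare_two_groups, correlate

__all__ = ["MICROBIAL_ANALYTES", "quartile_sum", "associate_serology", "read_serology"]

MICROBIAL_ANALYTES = ("ASCA", "OmpC", "I2", "CBir1")


def read_serology(path) -> pd.DataFrame:
    panel = pd.read_csv(path, sep="\t", index_col=0)
    if (panel.to_numpy() < 0).any():
        raise ValueError("titers must be nonnegative")
    return panel


def quartile_bins(titers: pd.Series) -> pd.Series:
    """Bin one analyte's titers into cohort quartiles 1-4 (type-7 quantiles)."""
    q1, q2, q3 = np.quantile(titers.to_numpy(dtype=float), [0.25, 0.5, 0.75])
    if titers.nunique() == 1:
        warnings.warn(f"analyte {titers.name!r} has identical titers; all binned 1")
        return pd.Series(1, index=titers.index)
    bins = np.select(
        [titers <= q1, titers <= q2, titers <= q3], [1, 2, 3], default=4
    )
    return pd.Series(bins, index=titers.index)


def quartile_sum(panel: pd.DataFrame, analytes=None) -> pd.DataFrame:
    """Quartile sum score per sample.

    Returns a DataFrame with one bin column per contributing analyte and a
    ``qss`` column holding the sum.  ANCA is excluded unless explicitly
    listed in ``analytes``.
    """
    analytes = list(analytes) if analytes is not None else list(MICROBIAL_ANALYTES)
    missing = [a for a in analytes if a not in panel.columns]
    if missing:
        raise ValueError(f"analytes absent from the panel: {missing}")
    if len(panel) < 8:
        raise ValueError("need at least 8 samples for meaningful quartiles")
    out = pd.DataFrame(index=panel.index)
    for a in analytes:
        out[f"bin_{a}"] = quartile_bins(panel[a])
    out["qss"] = out.sum(axis=1)
    return out


def associate_serology(scores: pd.DataFrame | pd.Series, covariate,
                       method: str = "spearman"):
    """Associate the QSS with a covariate.

    Numeric covariates are correlated (Spearman by default); two-level
    covariates are compared with the Shapiro-Wilk-gated two-group test.
    Returns (statistic_or_rho, p) or (test_name, statistic, p).
    """
    qss = scores["qss"] if isinstance(scores, pd.DataFrame) else scores
    cov = pd.Series(covariate, index=qss.index) if not isinstance(covariate, pd.Series) else covariate.loc[qss.index]
    if cov.dtype == object or cov.nunique() == 2 and set(cov.unique()) <= {"Y", "N", 0, 1}:
        return compare_two_groups(qss.to_numpy(dtype=float), cov.to_numpy())
    return correlate(qss.to_numpy(dtype=float), cov.to_numpy(dtype=float), method=method)
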