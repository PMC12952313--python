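"""Single-sample gene-set enrichment and the group-comparison statistics.

The GSVA-style score estimates, per gene, a relative-expression statistic
via a Gaussian-kernel CDF across samples (bandwidth = per-gene SD / 4),
ranks genes within each sample, symmetrizes the ranks and runs a
Kolmogorov-Smirnov-like weighted random walk down the ranking (weight
exponent tau = 1); the enrichment score is the signed sum of the maximum
positive and maximum negative deviations.  The ssGSEA variant is the
rank-weighted running-sum area with weight exponent 0.25.  These scores
act as a deconvolution surrogate: cell-subset signatures scored per sample
stand in for cell-type abundance.

Group comparisons are Shapiro-Wilk gated: Welch t when both groups look
normal at alpha = 0.05, otherwise Mann-Whitney (permutation-exact for
groups of at most 8, tie-corrected normal approximation beyond).
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ExpressionMatrix

__all__ = [
    "read_gene_sets",
    "write_gene_sets",
    "single_sample_enrichment",
    "compare_two_groups",
    "cochran_armitage_trend",
    "correlate",
]


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def read_gene_sets(path) -> dict[str, list[str]]:
    """Read a gene-set file: one set per line, ``name<TAB>gene1,gene2,...``."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if "\t" not in line:
                raise ValueError(f"line {i}: expected 'name<TAB>genes'")
            name, genes = line.split("\t", 1)
            members = [g for g in genes.split(",") if g]
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r} at line {i}")
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            sets[name] = members
    return sets


def write_gene_sets(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write(f"{name}\t{','.join(genes)}\n")


# ---------------------------------------------------------------------------
# single-sample enrichment
# ---------------------------------------------------------------------------

def _gsva_gene_stats(X: np.ndarray) -> np.ndarray:
    """Gaussian-kernel CDF estimate of each value within its gene's row."""
    sd = X.std(axis=1, ddof=1)
    h = np.maximum(sd / 4.0, 1e-12)
    # z[i, j] = mean_k Phi((x_ij - x_ik) / h_i); chunked over genes to bound memory
    out = np.empty_like(X, dtype=float)
    chunk = max(1, int(5e7 // (X.shape[1] ** 2 * 8)) or 1)
    for start in range(0, X.shape[0], chunk):
        sl = slice(start, start + chunk)
        diff = (X[sl, :, None] - X[sl, None, :]) / h[sl, None, None]
        out[sl] = stats.norm.cdf(diff).mean(axis=2)
    return out


def _gsva_sample_score(order: np.ndarray, weights: np.ndarray,
                       in_set: np.ndarray) -> float:
    """KS-like walk over genes in ranked order; tau-weighted hits.

    ``order`` indexes genes from highest to lowest statistic; ``weights``
    are the symmetrized rank scores; ``in_set`` flags set membership.
    """
    p = len(order)
    hits = in_set[order]
    m = int(hits.sum())
    if m == 0 or m == p:
        # degenerate set (empty or the whole universe): no contrast to walk
        return 0.0
    w = weights[order] * hits
    denom_hit = w.sum()
    if denom_hit == 0:
        return 0.0
    step_miss = 1.0 / (p - m)
    walk = np.cumsum(w / denom_hit - (~hits) * step_miss)
    return float(max(walk.max(), 0.0) + min(walk.min(), 0.0))


def single_sample_enrichment(
    matrix: ExpressionMatrix,
    sets: dict[str, list[str]],
    method: str = "gsva",
    ssgsea_normalize: bool = True,
) -> pd.DataFrame:
    """Score each gene set in each sample (sets x samples DataFrame).

    Sets with no gene present in the matrix are dropped with a warning;
    dropping all sets is an error.
    """
    if method not in ("gsva", "ssgsea"):
        raise ValueError("method must be 'gsva' or 'ssgsea'")
    if method == "gsva" and matrix.shape[1] < 3:
        raise ValueError("the gsva kernel needs at least 3 samples")
    genes = matrix.gene_ids
    gene_pos = {g: i for i, g in enumerate(genes)}
    usable: dict[str, np.ndarray] = {}
    for name, members in sets.items():
        idx = np.array([gene_pos[g] for g in members if g in gene_pos], dtype=int)
        if len(idx) == 0:
            warnings.warn(f"gene set {name!r} has no gene in the matrix; dropped")
            continue
        usable[name] = idx
    if not usable:
        raise ValueError("no gene set overlaps the expression matrix")

    X = matrix.values()
    p, n = X.shape
    scores = np.zeros((len(usable), n))

    if method == "gsva":
        Z = _gsva_gene_stats(X)
        for j in range(n):
            # rank 1 = highest statistic; symmetrized rank weight |p/2 - rank|
            order = np.argsort(-Z[:, j], kind="stable")
            rank = np.empty(p)
            rank[order] = np.arange(1, p + 1)
            weights = np.abs(p / 2.0 - rank)
            for si, (name, idx) in enumerate(usable.items()):
                in_set = np.zeros(p, dtype=bool)
                in_set[idx] = True
                scores[si, j] = _gsva_sample_score(order, weights, in_set)
    else:
        alpha = 0.25
        for j in range(n):
            order = np.argsort(-X[:, j], kind="stable")
            rank = np.empty(p)
            rank[order] = np.arange(p, 0, -1)  # highest expression -> rank p
            for si, (name, idx) in enumerate(usable.items()):
                in_set = np.zeros(p, dtype=bool)
                in_set[idx] = True
                hits = in_set[order]
                m = hits.sum()
                if m == 0 or m == p:
                    scores[si, j] = 0.0
                    continue
                w = (rank[order] ** alpha) * hits
                p_in = np.cumsum(w) / w.sum()
                p_out = np.cumsum(~hits) / (p - m)
                scores[si, j] = float(np.sum(p_in - p_out))
        if ssgsea_normalize:
            rng_ = scores.max() - scores.min()
            if rng_ > 0:
                scores = (scores - scores.min()) / rng_

    return pd.DataFrame(scores, index=list(usable), columns=matrix.sample_ids)


# ---------------------------------------------------------------------------
# hypothesis tests
# ---------------------------------------------------------------------------

def _mwu_exact(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided permutation-exact Mann-Whitney via full enumeration.

    Enumerates all assignments of the pooled values to the two group sizes
    (valid with ties), and computes P(|U - n1 n2 / 2| >= observed).
    """
    pooled = np.concatenate([a, b])
    n1, n2 = len(a), len(b)
    ranks = stats.rankdata(pooled)
    def u_of(idx_set):
        r1 = ranks[list(idx_set)].sum()
        return r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    obs = abs(u_of(range(n1)) - mu)
    total = 0
    extreme = 0
    for comb in combinations(range(n1 + n2), n1):
        total += 1
        if abs(u_of(comb) - mu) >= obs - 1e-12:
            extreme += 1
    u_obs = u_of(range(n1))
    return float(u_obs), extreme / total


def compare_two_groups(values, groups) -> tuple[str, float, float]:
    """Shapiro-Wilk-gated two-group test.

    Both groups normal at alpha = 0.05 -> Welch t; otherwise Mann-Whitney,
    permutation-exact when both groups have at most 8 observations and
    tie-corrected normal approximation beyond.  Returns
    (test_name, statistic, p).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(labels)}")
    a = values[groups == labels[0]]
    b = values[groups == labels[1]]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("both groups need at least 3 observations")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return ("degenerate_constant", 0.0, 1.0)

    def _normal(x):
        if np.all(x == x[0]):
            return False  # constant group: Shapiro undefined, treat as non-normal
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return stats.shapiro(x).pvalue > 0.05

    if _normal(a) and _normal(b):
        res = stats.ttest_ind(a, b, equal_var=False)
        return ("welch_t", float(res.statistic), float(res.pvalue))
    if len(a) <= 8 and len(b) <= 8:
        u, p = _mwu_exact(a, b)
        return ("mann_whitney_exact", u, p)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return ("mann_whitney", float(res.statistic), float(res.pvalue))


def cochran_armitage_trend(table, scores=None) -> tuple[float, float]:
    """Cochran-Armitage trend test for a 2 x k ordered table.

    Rows are the two outcome groups, columns the ordered categories; the
    default scores are equally spaced (0..k-1).  Returns the standardized
    trend statistic Z and its two-sided normal p-value.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2 or table.shape[1] < 2:
        raise ValueError("expected a 2 x k table with k >= 2")
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("table must hold nonnegative integer counts")
    k = table.shape[1]
    s = np.arange(k, dtype=float) if scores is None else np.asarray(scores, dtype=float)
    n_j = table.sum(axis=0)
    if np.any(n_j == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero row or column margin")
    N = table.sum()
    A = table[0].sum()
    phat = A / N
    T = float(s @ table[0])
    E = phat * float(s @ n_j)
    var = phat * (1 - phat) * (float(s**2 @ n_j) - float(s @ n_j) ** 2 / N)
    if var == 0:
        return (0.0, 1.0)
    Z = (T - E) / np.sqrt(var)
    return (float(Z), float(2.0 * stats.norm.sf(abs(Z))))


def correlate(x, y, method: str = "spearman") -> tuple[float, float]:
    """Spearman (average ranks) or Pearson correlation with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired vectors with n >= 4")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance; correlation undefined")
    if method == "spearman":
        r = stats.spearmanr(x, y)
    elif method == "pearson":
        r = stats.pearsonr(x, y)
    else:
        raise ValueError("method must be 'spearman' or 'pearson'")
    return (float(r.statistic if hasattr(r, "statistic") else r.correlation), float(r.pvalue))
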