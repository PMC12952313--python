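"""Peripheral-subtype discovery and validation.

PCA and correlation-distance hierarchical clustering discover the two
peripheral subtypes; per-gene Welch or paired t-tests with
Benjamini-Hochberg FDR select differential genes at the joint
fold / p / FDR thresholds; a seven-classifier consensus (Bayesian compound
covariate, diagonal linear discriminant analysis, k-nearest neighbour with
k = 1 and 3, nearest centroid, linear SVM and rank-2 NMF assignment) calls
subtypes on held-out samples with feature selection nested strictly inside
the training data; stratified bootstrap cross-validation estimates the
out-of-bag misclassification rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import NMF, PCA
from sklearn.neighbors import KNeighborsClassifier, NearestCentroid
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .preprocess import ExpressionMatrix

__all__ = [
    "run_pca",
    "hierarchical_cluster",
    "differential_expression",
    "train_and_classify",
    "bootstrap_cv",
    "CLASSIFIER_NAMES",
]

CLASSIFIER_NAMES = ("BCC", "DLDA", "kNN1", "kNN3", "centroid", "SVM", "NMF")


# ---------------------------------------------------------------------------
# unsupervised
# ---------------------------------------------------------------------------

def run_pca(matrix: ExpressionMatrix, n_components: int = 2):
    """PCA of samples in gene space (genes centred across samples).

    Returns (scores DataFrame samples x PCs, explained-variance fractions).
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    max_comp = min(matrix.shape[1], matrix.shape[0])
    if n_components > max_comp:
        raise ValueError(f"n_components={n_components} exceeds min(dims)={max_comp}")
    X = matrix.values().T  # samples x genes
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores, index=matrix.sample_ids, columns=cols),
        pca.explained_variance_ratio_,
    )


def hierarchical_cluster(matrix: ExpressionMatrix, k: int = 2) -> pd.Series:
    """Average-linkage clustering on 1 - Pearson correlation between samples."""
    if matrix.shape[1] < k:
        raise ValueError(f"need at least k={k} samples")
    X = matrix.values().T
    sds = X.std(axis=1)
    if np.any(sds == 0):
        bad = matrix.sample_ids[np.argmax(sds == 0)]
        raise ValueError(f"sample {bad!r} has a constant profile; correlation undefined")
    corr = np.corrcoef(X)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=matrix.sample_ids, name="cluster")


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def _welch_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Welch t per row; zero-variance rows get t=0, p=1."""
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se2 = va / na + vb / nb
    zero = se2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    t = np.where(zero, 0.0, t)
    df = np.where(zero, 1.0, df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(zero, 1.0, p)
    return t, p


def _paired_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = a - b
    n = d.shape[1]
    m = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    zero = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    t = np.where(zero, 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    p = np.where(zero, 1.0, p)
    return t, p


def differential_expression(
    matrix: ExpressionMatrix,
    group_a,
    group_b,
    paired: bool = False,
    fold_min: float = 2.0,
    p_max: float = 0.001,
    fdr_max: float = 0.002,
) -> pd.DataFrame:
    """Per-gene two-group (Welch) or paired t-tests on log2 values.

    log2fc is mean(A) - mean(B); the linear fold is 2**|log2fc|; FDR is
    Benjamini-Hochberg across all tested genes; ``passes_filter`` requires
    fold >= fold_min AND p < p_max AND fdr < fdr_max jointly.  Genes with
    zero within-group variance are assigned t=0, p=1 and flagged.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    if paired and len(group_a) != len(group_b):
        raise ValueError("paired groups must be equal-sized and subject-matched")
    if matrix.scale != "log2":
        raise ValueError("differential expression expects log2-scale values")
    a = matrix.data.loc[:, group_a].to_numpy(dtype=float)
    b = matrix.data.loc[:, group_b].to_numpy(dtype=float)
    t, p = (_paired_t if paired else _welch_t)(a, b)
    zero_var = (t == 0.0) & (p == 1.0)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    fdr = multipletests(p, method="fdr_bh")[1]
    fold = 2.0 ** np.abs(log2fc)
    res = pd.DataFrame(
        {
            "log2fc": log2fc,
            "statistic": t,
            "p_value": p,
            "fdr": fdr,
            "direction": np.where(log2fc >= 0, "up", "down"),
            "fold": fold,
            "passes_filter": (fold >= fold_min) & (p < p_max) & (fdr < fdr_max),
            "zero_variance": zero_var,
        },
        index=matrix.gene_ids,
    )
    return res


# ---------------------------------------------------------------------------
# consensus classification
# ---------------------------------------------------------------------------

class _BCC:
    """Bayesian compound covariate: c = sum_i t_i x_i over selected genes,
    Gaussian class-conditional model of c with pooled variance, equal priors."""

    def fit(self, X, y, t_values):
        self.t = t_values
        c = X @ self.t
        self.classes_ = np.unique(y)
        self.means_ = np.array([c[y == cls].mean() for cls in self.classes_])
        pooled = np.concatenate([c[y == cls] - c[y == cls].mean() for cls in self.classes_])
        self.sd_ = max(pooled.std(ddof=1), 1e-12)
        return self

    def predict(self, X):
        c = X @ self.t
        d = np.abs(c[:, None] - self.means_[None, :]) / self.sd_
        return self.classes_[np.argmin(d, axis=1)]


class _DLDA:
    """Diagonal LDA with gene-wise pooled variances and equal priors."""

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        self.means_ = np.array([X[y == cls].mean(axis=0) for cls in self.classes_])
        resid = np.concatenate([X[y == cls] - X[y == cls].mean(axis=0) for cls in self.classes_])
        n = X.shape[0]
        var = (resid**2).sum(axis=0) / max(n - len(self.classes_), 1)
        self.var_ = np.maximum(var, 1e-12)
        return self

    def _scores(self, X):
        # negative Mahalanobis-like distance under diagonal covariance
        return -np.array(
            [((X - m) ** 2 / self.var_).sum(axis=1) for m in self.means_]
        ).T

    def predict(self, X):
        return self.classes_[np.argmax(self._scores(X), axis=1)]


def _nmf_assign(train_X, train_y, test_X, seed: int = 0):
    """Rank-2 NMF sample assignment mapped to classes by training majority."""
    X = np.vstack([train_X, test_X])
    X = X - X.min()  # shift to non-negative
    model = NMF(
        n_components=2, init="nndsvda", solver="mu", max_iter=300,
        tol=1e-5, random_state=seed,
    )
    W = model.fit_transform(X)  # samples x 2 loadings
    comp = np.argmax(W, axis=1)
    classes = np.unique(train_y)
    n_train = train_X.shape[0]
    mapping = {}
    for k in (0, 1):
        mask = comp[:n_train] == k
        if mask.sum() == 0:
            mapping[k] = classes[0]
        else:
            vals, counts = np.unique(train_y[mask], return_counts=True)
            mapping[k] = vals[np.argmax(counts)]
    return np.array([mapping[k] for k in comp[n_train:]])


def _select_features(train: pd.DataFrame, y: np.ndarray, selection_p: float):
    classes = np.unique(y)
    a = train.loc[:, train.columns[y == classes[0]]].to_numpy(dtype=float)
    b = train.loc[:, train.columns[y == classes[1]]].to_numpy(dtype=float)
    t, p = _welch_t(a, b)
    keep = p < selection_p
    return train.index[keep], t[keep]


def train_and_classify(
    train: ExpressionMatrix,
    labels,
    test: ExpressionMatrix,
    selection_p: float = 0.001,
    seed: int = 0,
) -> pd.DataFrame:
    """Consensus subtype calls for test samples.

    Feature genes are selected on the training data only (Welch t,
    p < selection_p); seven classifiers vote; the call is the majority with
    ties broken by DLDA.  Returns a DataFrame indexed by test sample with
    the consensus ``call``, per-classifier votes and ``consensus_fraction``.
    """
    labels = pd.Series(labels, index=train.sample_ids) if not isinstance(labels, pd.Series) else labels.loc[train.sample_ids]
    y = labels.to_numpy()
    classes = np.unique(y)
    if len(classes) != 2 or min((y == c).sum() for c in classes) < 2:
        raise ValueError("training data needs two classes with >=2 samples each")

    genes, t_values = _select_features(train.data, y, selection_p)
    if len(genes) == 0:
        raise ValueError(
            f"no gene passes feature selection at p<{selection_p}; "
            "increase selection_p"
        )
    Xtr = train.data.loc[genes].to_numpy(dtype=float).T
    Xte = test.data.loc[genes].to_numpy(dtype=float).T

    votes = {}
    votes["BCC"] = _BCC().fit(Xtr, y, t_values).predict(Xte)
    dlda = _DLDA().fit(Xtr, y)
    votes["DLDA"] = dlda.predict(Xte)
    votes["kNN1"] = KNeighborsClassifier(n_neighbors=1).fit(Xtr, y).predict(Xte)
    k3 = min(3, len(y))
    votes["kNN3"] = KNeighborsClassifier(n_neighbors=k3).fit(Xtr, y).predict(Xte)
    votes["centroid"] = NearestCentroid().fit(Xtr, y).predict(Xte)
    votes["SVM"] = SVC(kernel="linear", C=1.0).fit(Xtr, y).predict(Xte)
    votes["NMF"] = _nmf_assign(Xtr, y, Xte, seed=seed)

    vote_df = pd.DataFrame(votes, index=test.sample_ids)
    n_clf = len(CLASSIFIER_NAMES)
    calls, fracs = [], []
    for sid in test.sample_ids:
        row = vote_df.loc[sid]
        counts = row.value_counts()
        if len(counts) == 2 and counts.iloc[0] == counts.iloc[1]:
            call = row["DLDA"]  # tie-break (cannot occur with 7 voters unless abstention)
        else:
            call = counts.index[0]
        calls.append(call)
        fracs.append((row == call).sum() / n_clf)
    out = vote_df.copy()
    out.insert(0, "call", calls)
    out["consensus_fraction"] = fracs
    out["n_features"] = len(genes)
    return out


def bootstrap_cv(
    matrix: ExpressionMatrix,
    labels,
    n_boot: int = 100,
    selection_p: float = 0.001,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Stratified bootstrap cross-validated misclassification rate.

    Each replicate resamples samples with replacement within each class,
    trains the consensus classifier (feature selection nested inside the
    in-bag data) and scores the out-of-bag samples; a replicate whose
    out-of-bag set is empty for either class is redrawn.  Returns the mean
    rate and the per-replicate rates.
    """
    labels = pd.Series(labels, index=matrix.sample_ids) if not isinstance(labels, pd.Series) else labels.loc[matrix.sample_ids]
    y = labels
    classes = y.unique()
    if len(classes) != 2:
        raise ValueError("bootstrap CV needs exactly two classes")
    rng = np.random.default_rng(seed)
    sample_ids = matrix.sample_ids.to_numpy()
    rates = np.empty(n_boot)
    b = 0
    attempts = 0
    while b < n_boot:
        attempts += 1
        if attempts > 20 * n_boot:
            raise RuntimeError("could not draw replicates with non-empty out-of-bag sets")
        in_bag = []
        for cls in classes:
            pool = sample_ids[(y == cls).to_numpy()]
            in_bag.extend(rng.choice(pool, size=len(pool), replace=True))
        oob = [s for s in sample_ids if s not in set(in_bag)]
        oob_y = y.loc[oob]
        if len(oob) == 0 or oob_y.nunique() < 1:
            continue
        train = ExpressionMatrix(
            matrix.data.loc[:, in_bag].set_axis(
                [f"b{i}" for i in range(len(in_bag))], axis=1
            ),
            matrix.scale,
        )
        train_y = pd.Series(y.loc[in_bag].to_numpy(), index=train.sample_ids)
        if train_y.nunique() < 2:
            continue
        test = matrix.subset_samples(oob)
        calls = train_and_classify(
            train, train_y, test, selection_p=selection_p,
            seed=int(rng.integers(2**31)),
        )
        rates[b] = float((calls["call"].to_numpy() != oob_y.to_numpy()).mean())
        b += 1
    return float(rates.mean()), rates
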