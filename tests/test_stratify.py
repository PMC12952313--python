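import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pbmustrat as pb
from pbmustrat.preprocess import ExpressionMatrix
from pbmustrat.stratify import (
    bootstrap_cv,
    differential_expression,
    hierarchical_cluster,
    run_pca,
    train_and_classify,
)


def _em(values, scale="log2", genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), scale)


def _bh_step_up(pvals):
    """Independent Benjamini-Hochberg step-up enumeration (adjusted p)."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        prev = min(prev, pvals[i] * m / rank_from_top)
        adj[i] = prev
    return adj


class TestPCA:
    def test_separated_clouds_on_pc1(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.01, (20, 10))
        b = rng.normal(5, 0.01, (20, 10))
        m = _em(np.hstack([a, b]))
        scores, evr = run_pca(m, 2)
        assert evr[0] > 0.99
        pc1 = scores["PC1"]
        assert (pc1.iloc[:10] * pc1.iloc[10:].to_numpy() < 0).all() or (
            np.sign(pc1.iloc[:10]).nunique() == 1
            and np.sign(pc1.iloc[10:]).nunique() == 1
        )

    def test_matches_gram_matrix_eigendecomposition(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5, 4))  # 5 genes x 4 samples
        m = _em(X)
        scores, evr = run_pca(m, 3)
        C = X.T - X.T.mean(axis=0)
        gram = C @ C.T
        w, v = np.linalg.eigh(gram)
        w, v = w[::-1], v[:, ::-1]
        expected_scores = v * np.sqrt(np.maximum(w, 0.0))
        for k in range(3):
            got = scores.iloc[:, k].to_numpy()
            exp = expected_scores[:, k]
            assert min(np.abs(got - exp).max(), np.abs(got + exp).max()) < 1e-8
        np.testing.assert_allclose(evr, (w / w.sum())[:3], atol=1e-10)

    def test_sample_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(8, 6))
        m = _em(X)
        scores, _ = run_pca(m, 2)
        perm = [3, 0, 5, 1, 4, 2]
        m2 = _em(X[:, perm], samples=[m.sample_ids[p] for p in perm])
        scores2, _ = run_pca(m2, 2)
        aligned = scores2.loc[scores.index]
        for k in range(2):
            a, b = scores.iloc[:, k].to_numpy(), aligned.iloc[:, k].to_numpy()
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_component_bound(self):
        with pytest.raises(ValueError):
            run_pca(_em(np.ones((3, 2))), 5)


class TestHierarchicalCluster:
    def test_recovers_planted_groups(self, peripheral):
        mat, labels = peripheral
        clusters = hierarchical_cluster(mat, 2)
        agree = max(
            (clusters.map({1: "PBmu", 2: "PBT"}) == labels).mean(),
            (clusters.map({1: "PBT", 2: "PBmu"}) == labels).mean(),
        )
        assert agree >= 0.95

    def test_k1_single_label(self):
        m = _em(np.random.default_rng(0).normal(size=(10, 5)))
        assert hierarchical_cluster(m, 1).nunique() == 1

    def test_duplicate_sample_clusters_with_twin(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 4))
        X = np.hstack([X, X[:, [0]]])  # twin of sample 0
        m = _em(X)
        clusters = hierarchical_cluster(m, 4)
        assert clusters.iloc[0] == clusters.iloc[4]

    def test_constant_profile_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        X[:, 1] = 2.0
        with pytest.raises(ValueError, match="s1"):
            hierarchical_cluster(_em(X), 2)


class TestDifferentialExpression:
    def test_identical_groups_no_fold(self):
        X = np.random.default_rng(4).normal(size=(10, 4))
        m = _em(np.hstack([X, X]), samples=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)])
        de = differential_expression(m, [f"a{i}" for i in range(4)],
                                     [f"b{i}" for i in range(4)], fold_min=1.01)
        assert (de["log2fc"] == 0).all()
        assert not de["passes_filter"].any()

    def test_welch_and_bh_oracles(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(4, 6))
        m = _em(X, samples=list("abcdef"))
        de = differential_expression(m, list("abc"), list("def"))
        for i in range(4):
            a, b = X[i, :3], X[i, 3:]
            # brute-force Welch formula
            se2 = a.var(ddof=1) / 3 + b.var(ddof=1) / 3
            t = (a.mean() - b.mean()) / np.sqrt(se2)
            df = se2**2 / ((a.var(ddof=1) / 3) ** 2 / 2 + (b.var(ddof=1) / 3) ** 2 / 2)
            p = 2 * stats.t.sf(abs(t), df)
            assert de["statistic"].iloc[i] == pytest.approx(t, abs=1e-10)
            assert de["p_value"].iloc[i] == pytest.approx(p, abs=1e-10)
        np.testing.assert_allclose(
            de["fdr"].to_numpy(), _bh_step_up(de["p_value"].to_numpy()), atol=1e-12
        )

    def test_bh_enumeration_on_larger_instance(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=18)
        from statsmodels.stats.multitest import multipletests
        np.testing.assert_allclose(
            multipletests(p, method="fdr_bh")[1], _bh_step_up(p), atol=1e-12
        )

    def test_planted_recovery_precision_recall(self, cohort, log2_matrix):
        meta = cohort.metadata
        peri = meta[(meta["compartment"] == "peripheral")
                    & (meta["disease"] == "CD")
                    & (meta["timepoint"] == "surgery")]
        labels = peri["subtype_label"]
        de = differential_expression(
            log2_matrix.subset_samples(peri.index),
            labels.index[labels == "PBmu"].tolist(),
            labels.index[labels == "PBT"].tolist(),
        )
        truth = cohort.gene_truth
        planted = set(pb.simulate.planted_differential(cohort))
        recall = de.loc[truth.index[truth["is_de"]], "passes_filter"].mean()
        precision = de.index[de["passes_filter"]].isin(planted).mean()
        assert recall >= 0.9 and precision >= 0.9

    def test_zero_variance_flagged(self):
        X = np.ones((2, 6))
        X[1] = np.random.default_rng(7).normal(size=6)
        m = _em(X, samples=list("abcdef"))
        de = differential_expression(m, list("abc"), list("def"))
        assert de["zero_variance"].iloc[0]
        assert de["p_value"].iloc[0] == 1.0 and de["statistic"].iloc[0] == 0.0

    def test_paired_requires_equal_sizes(self):
        m = _em(np.random.default_rng(8).normal(size=(3, 5)), samples=list("abcde"))
        with pytest.raises(ValueError, match="paired"):
            differential_expression(m, list("ab"), list("cde"), paired=True)


class TestConsensusClassifier:
    def test_training_sample_reproduces_its_label(self):
        rng = np.random.default_rng(9)
        X = np.vstack([rng.normal(0, 1, (30, 6)), rng.normal(2, 1, (30, 6))])
        m = _em(X, samples=[f"s{j}" for j in range(6)])
        labels = pd.Series(["A", "A", "A", "B", "B", "B"], index=m.sample_ids)
        calls = train_and_classify(m, labels, m, selection_p=0.5)
        assert (calls["kNN1"] == labels).all()

    def test_separated_gaussians_high_accuracy(self):
        rng = np.random.default_rng(10)
        n_genes, shift_genes = 200, 50
        def draw(n, cls):
            X = rng.normal(size=(n_genes, n))
            if cls == "B":
                X[:shift_genes] += 3.0  # 3 pooled SD
            return X
        train = np.hstack([draw(25, "A"), draw(25, "B")])
        test = np.hstack([draw(50, "A"), draw(50, "B")])
        m_train = _em(train, samples=[f"tr{j}" for j in range(50)])
        m_test = _em(test, genes=list(m_train.gene_ids),
                     samples=[f"te{j}" for j in range(100)])
        y = pd.Series(["A"] * 25 + ["B"] * 25, index=m_train.sample_ids)
        calls = train_and_classify(m_train, y, m_test, selection_p=0.001)
        truth = np.array(["A"] * 50 + ["B"] * 50)
        assert (calls["call"].to_numpy() == truth).mean() >= 0.98

    def test_label_permutation_is_chance(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(300, 60))
        m = _em(X, samples=[f"s{j}" for j in range(60)])
        y = pd.Series(rng.permutation(["A"] * 30 + ["B"] * 30), index=m.sample_ids)
        test = _em(rng.normal(size=(300, 100)), genes=list(m.gene_ids),
                   samples=[f"t{j}" for j in range(100)])
        calls = train_and_classify(m, y, test, selection_p=0.05)
        frac_a = (calls["call"] == "A").mean()
        # chance assignment: inside the 95% binomial band around 0.5 at n=100
        assert 0.5 - 1.96 * 0.05 <= frac_a <= 0.5 + 1.96 * 0.05

    def test_no_features_errors(self):
        m = _em(np.random.default_rng(12).normal(size=(5, 8)),
                samples=list("abcdefgh"))
        y = pd.Series(list("AAAABBBB"), index=m.sample_ids)
        with pytest.raises(ValueError, match="selection_p"):
            train_and_classify(m, y, m, selection_p=1e-12)


class TestBootstrapCV:
    def test_determinism(self, peripheral):
        mat, labels = peripheral
        small = mat.subset_genes(mat.gene_ids[:400])
        r1, rates1 = bootstrap_cv(small, labels, n_boot=5, seed=3)
        r2, rates2 = bootstrap_cv(small, labels, n_boot=5, seed=3)
        np.testing.assert_array_equal(rates1, rates2)

    def test_null_labels_near_chance(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(2000, 60))
        m = _em(X, samples=[f"s{j}" for j in range(60)])
        y = pd.Series(["A"] * 30 + ["B"] * 30, index=m.sample_ids)
        rate, _ = bootstrap_cv(m, y, n_boot=100, selection_p=0.01, seed=5)
        assert abs(rate - 0.5) <= 0.1
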