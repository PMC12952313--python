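import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pbmustrat.enrichment import (
    cochran_armitage_trend,
    compare_two_groups,
    correlate,
    read_gene_sets,
    single_sample_enrichment,
    write_gene_sets,
)
from pbmustrat.preprocess import ExpressionMatrix


def _em(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), "log2")


def _gsva_brute_force(X, set_idx):
    """Independent slow re-derivation: kernel CDF, symmetric ranks, KS walk."""
    p, n = X.shape
    sd = X.std(axis=1, ddof=1)
    h = np.maximum(sd / 4.0, 1e-12)
    z = np.zeros_like(X)
    for i in range(p):
        for j in range(n):
            z[i, j] = np.mean([stats.norm.cdf((X[i, j] - X[i, k]) / h[i]) for k in range(n)])
    scores = np.zeros(n)
    for j in range(n):
        order = sorted(range(p), key=lambda i: (-z[i, j], i))
        rank = {g: r + 1 for r, g in enumerate(order)}
        w = {g: abs(p / 2.0 - rank[g]) for g in range(p)}
        denom = sum(w[g] for g in set_idx)
        m = len(set_idx)
        walk, cur, mx, mn = [], 0.0, 0.0, 0.0
        for g in order:
            if g in set_idx:
                cur += w[g] / denom
            else:
                cur -= 1.0 / (p - m)
            mx, mn = max(mx, cur), min(mn, cur)
        scores[j] = mx + mn
    return scores


class TestSingleSampleEnrichment:
    def test_gsva_matches_brute_force(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 4))
        m = _em(X)
        sets = {"S": ["g1", "g4", "g7"]}
        scores = single_sample_enrichment(m, sets, method="gsva")
        expected = _gsva_brute_force(X, {1, 4, 7})
        np.testing.assert_allclose(scores.loc["S"].to_numpy(), expected, atol=1e-10)

    def test_whole_universe_set_scores_zero(self):
        rng = np.random.default_rng(1)
        m = _em(rng.normal(size=(20, 5)))
        scores = single_sample_enrichment(m, {"all": list(m.gene_ids)}, method="gsva")
        assert np.all(np.abs(scores.to_numpy()) < 2.0 / 20)

    def test_gene_order_and_shift_invariance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(15, 5))
        m = _em(X)
        sets = {"S": ["g2", "g9", "g13"]}
        base = single_sample_enrichment(m, sets, method="gsva")
        perm = rng.permutation(15)
        m2 = ExpressionMatrix(m.data.iloc[perm], "log2")
        np.testing.assert_allclose(
            single_sample_enrichment(m2, sets, method="gsva").to_numpy(),
            base.to_numpy(), atol=1e-12,
        )
        shifted = m.data.copy()
        shifted.loc["g2"] += 100.0  # per-gene kernel CDF is shift invariant
        np.testing.assert_allclose(
            single_sample_enrichment(ExpressionMatrix(shifted, "log2"), sets,
                                     method="gsva").to_numpy(),
            base.to_numpy(), atol=1e-12,
        )

    def test_subset_directions_recovered(self, peripheral, subset_scores):
        _, labels = peripheral
        nkt = subset_scores.loc["NKT"]
        cd8 = subset_scores.loc["CD8_naive"]
        _, _, p_nkt = compare_two_groups(nkt.to_numpy(), labels.to_numpy())
        _, _, p_cd8 = compare_two_groups(cd8.to_numpy(), labels.to_numpy())
        assert p_nkt < 0.01 and p_cd8 < 0.01
        assert nkt[labels == "PBmu"].median() > nkt[labels == "PBT"].median()
        assert cd8[labels == "PBmu"].median() < cd8[labels == "PBT"].median()

    def test_null_label_permutations_rarely_significant(self, subset_scores, peripheral):
        _, labels = peripheral
        rng = np.random.default_rng(3)
        vals = subset_scores.loc["NKT"].to_numpy()
        n_sig = 0
        for _ in range(100):
            perm = rng.permutation(labels.to_numpy())
            p = stats.mannwhitneyu(vals[perm == "PBmu"], vals[perm == "PBT"],
                                   alternative="two-sided").pvalue
            n_sig += p < 0.05
        assert n_sig <= 10

    def test_unmatched_sets_dropped_or_error(self):
        m = _em(np.random.default_rng(4).normal(size=(5, 4)))
        with pytest.warns(UserWarning):
            scores = single_sample_enrichment(
                m, {"ok": ["g0", "g1"], "gone": ["zz"]}, method="gsva"
            )
        assert list(scores.index) == ["ok"]
        with pytest.raises(ValueError):
            single_sample_enrichment(m, {"gone": ["zz"]}, method="gsva")

    def test_ssgsea_runs_and_separates(self, peripheral, subset_signatures):
        mat, labels = peripheral
        scores = single_sample_enrichment(mat, subset_signatures, method="ssgsea")
        nkt = scores.loc["NKT"]
        assert nkt[labels == "PBmu"].median() > nkt[labels == "PBT"].median()

    def test_gene_set_file_round_trip(self, tmp_path):
        sets = {"A": ["g1", "g2"], "B": ["g3"]}
        path = tmp_path / "sets.tsv"
        write_gene_sets(sets, path)
        assert read_gene_sets(path) == sets


class TestCompareTwoGroups:
    def test_identical_groups_p1(self):
        vals = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        grp = np.array(["a"] * 3 + ["b"] * 3)
        name, _, p = compare_two_groups(vals, grp)
        assert p == 1.0

    def test_exact_mann_whitney_enumeration(self):
        # {1,2,3,4} vs {10,11,12,13}: only the 2 extreme assignments of 70
        # reach the observed separation
        from pbmustrat.enrichment import _mwu_exact

        _, p = _mwu_exact(np.array([1.0, 2, 3, 4]), np.array([10.0, 11, 12, 13]))
        assert p == pytest.approx(2 / 70, abs=1e-12)
        # verify against independent enumeration over scipy's U statistic
        from itertools import combinations
        from scipy.stats import mannwhitneyu

        vals = np.array([1, 2, 3, 4, 10, 11, 12, 13], dtype=float)
        u_obs = mannwhitneyu(vals[:4], vals[4:], alternative="two-sided",
                             method="asymptotic").statistic
        extreme = sum(
            abs(mannwhitneyu(vals[list(c)],
                             vals[[i for i in range(8) if i not in c]],
                             alternative="two-sided",
                             method="asymptotic").statistic - 8) >= abs(u_obs - 8)
            for c in combinations(range(8), 4)
        )
        assert p == pytest.approx(extreme / 70, abs=1e-12)

    def test_gate_routes_non_normal_small_samples_to_exact(self):
        # heavy outliers make Shapiro-Wilk reject; groups of <=8 use the
        # permutation-exact branch
        a = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 100.0])
        b = np.array([2.0, 2.0, 2.0, 2.0, 2.0, 200.0])
        name, _, _ = compare_two_groups(
            np.concatenate([a, b]), np.array(["a"] * 6 + ["b"] * 6)
        )
        assert name == "mann_whitney_exact"

    def test_welch_branch_matches_closed_form(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 20)
        b = rng.normal(1, 1, 25)
        name, t, p = compare_two_groups(
            np.concatenate([a, b]), np.array(["a"] * 20 + ["b"] * 25)
        )
        assert name == "welch_t"
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_minimum_group_size(self):
        with pytest.raises(ValueError):
            compare_two_groups([1, 2, 3, 4], ["a", "a", "b", "b"])


class TestCochranArmitage:
    def test_flat_proportions_null(self):
        z, p = cochran_armitage_trend([[10, 10, 10], [5, 5, 5]])
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_hand_computation(self):
        table = np.array([[10, 10, 10], [2, 6, 12]])
        z, p = cochran_armitage_trend(table)
        # hand computation of the weighted-difference trend statistic
        s = np.array([0.0, 1.0, 2.0])
        n_j = table.sum(axis=0)
        N, A = table.sum(), table[0].sum()
        phat = A / N
        T = s @ table[0]
        E = phat * (s @ n_j)
        var = phat * (1 - phat) * ((s**2) @ n_j - (s @ n_j) ** 2 / N)
        z_hand = (T - E) / np.sqrt(var)
        assert z == pytest.approx(z_hand, abs=1e-12)
        assert p == pytest.approx(2 * stats.norm.sf(abs(z_hand)), abs=1e-12)

    def test_column_reversal_negates_statistic(self):
        table = np.array([[10, 10, 10], [2, 6, 12]])
        z, p = cochran_armitage_trend(table)
        z_r, p_r = cochran_armitage_trend(table[:, ::-1])
        assert z_r == pytest.approx(-z, abs=1e-12)
        assert p_r == pytest.approx(p, abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            cochran_armitage_trend([[0, 5], [0, 5]])


class TestCorrelate:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert correlate(x, x)[0] == pytest.approx(1.0)
        assert correlate(x, -x)[0] == pytest.approx(-1.0)

    def test_spearman_with_tie_matches_rank_formula(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.0, 8.0])
        rho, _ = correlate(x, y, method="spearman")
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]  # Pearson on average ranks
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate([1, 1, 1, 1], [1, 2, 3, 4])
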