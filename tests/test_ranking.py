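"""Decompositions, list merging and the three rankers."""

import numpy as np
import pytest
from scipy import stats

from plsstab.dataset import ExpressionDataset
from plsstab.pls import fit_nipals
from plsstab.ranking import (
    RankedGeneList,
    decompose_ovo,
    decompose_ovr,
    encode_mclass,
    gene_importance,
    merge_ranked_lists,
    pooled_t_statistic,
    rank_custom,
    rank_pls,
    rank_rfe,
    rank_ttest,
)


def _rl(ids):
    return RankedGeneList(tuple(ids), tuple(float(len(ids) - i) for i in range(len(ids))), len(ids))


class TestGeneImportance:
    def test_single_component_is_elementwise_square(self, rng):
        X = rng.normal(size=(15, 6))
        Xc = X - X.mean(axis=0)
        y = rng.normal(size=15)
        m = fit_nipals(Xc, y - y.mean(), 2)
        np.testing.assert_allclose(gene_importance(m, 1), m.weights[:, 0] ** 2)

    def test_matches_double_loop_oracle(self, rng):
        X = rng.normal(size=(15, 6))
        Xc = X - X.mean(axis=0)
        y = rng.normal(size=15)
        m = fit_nipals(Xc, y - y.mean(), 3)
        expected = np.zeros(6)
        for j in range(6):
            for i in range(3):
                expected[j] += m.weights[j, i] ** 2
        np.testing.assert_allclose(gene_importance(m, 3), expected)

    def test_s_out_of_range_rejected(self, rng):
        X = rng.normal(size=(15, 6))
        y = rng.normal(size=15)
        m = fit_nipals(X - X.mean(axis=0), y - y.mean(), 2)
        with pytest.raises(ValueError):
            gene_importance(m, 3)


class TestDecompositions:
    def test_ovr_coding_and_order(self):
        probs = decompose_ovr([1, 2, 3, 2])
        assert [p.name for p in probs] == ["1vR", "2vR", "3vR"]
        np.testing.assert_array_equal(probs[1].coded_labels, [-1, 1, -1, 1])
        assert all(p.sample_index.size == 4 for p in probs)

    def test_ovr_two_classes_are_sign_flips(self):
        p1, p2 = decompose_ovr([1, 2, 1, 2])
        np.testing.assert_array_equal(p1.coded_labels, -p2.coded_labels)

    def test_ovr_count(self):
        assert len(decompose_ovr([1, 2, 3, 4] * 2)) == 4

    def test_ovo_count(self):
        assert len(decompose_ovo([1, 2, 3, 4] * 2)) == 6

    def test_ovo_sample_restriction(self):
        probs = decompose_ovo([1, 1, 2, 3])
        p12 = probs[0]
        assert p12.name == "1v2"
        np.testing.assert_array_equal(p12.sample_index, [0, 1, 2])
        np.testing.assert_array_equal(p12.coded_labels, [1, 1, -1])

    def test_ovo_two_classes_covers_all_samples(self):
        labels = [1, 2, 1, 2, 2]
        (povo,) = decompose_ovo(labels)
        povr = decompose_ovr(labels)[0]
        np.testing.assert_array_equal(povo.sample_index, povr.sample_index)

    def test_absent_class_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            decompose_ovr([1, 3, 3, 1])

    def test_mclass_coding(self):
        Y = encode_mclass([1, 2, 3, 2])
        np.testing.assert_array_equal(Y[0], [1, -1, -1])
        np.testing.assert_array_equal(Y.sum(axis=1), [2 - 3] * 4)

    def test_mclass_column_mean_tracks_class_frequency(self, rng):
        labels = rng.integers(1, 4, size=60)
        labels[:3] = [1, 2, 3]  # all classes present
        Y = encode_mclass(labels)
        for k in range(1, 4):
            p_k = np.mean(labels == k)
            assert np.isclose(Y[:, k - 1].mean(), 2 * p_k - 1)


class TestMergeRankedLists:
    def test_hand_traced_round_robin(self):
        merged = merge_ranked_lists([_rl("abc"), _rl("dae")], 5)
        assert merged.gene_ids == ("a", "d", "b", "e", "c")

    def test_single_sublist_identity(self):
        merged = merge_ranked_lists([_rl("abcde")], 3)
        assert merged.gene_ids == ("a", "b", "c")

    def test_identical_sublists(self):
        merged = merge_ranked_lists([_rl("abc"), _rl("abc")], 3)
        assert merged.gene_ids == ("a", "b", "c")

    def test_g_exceeding_union_rejected(self):
        with pytest.raises(ValueError):
            merge_ranked_lists([_rl("abc"), _rl("abd")], 5)

    @pytest.mark.parametrize("seed", range(5))
    def test_no_duplicates_and_prefix_of_union(self, seed):
        rng = np.random.default_rng(seed)
        universe = [f"g{i}" for i in range(12)]
        subs = []
        for _ in range(3):
            perm = rng.permutation(12)
            subs.append(_rl([universe[i] for i in perm]))
        g = int(rng.integers(1, 13))
        merged = merge_ranked_lists(subs, g)
        assert len(merged.gene_ids) == g
        assert len(set(merged.gene_ids)) == g
        assert set(merged.gene_ids) <= set(universe)


class TestRankPls:
    def test_planted_pairwise_markers_lead_ovo_lists(self, small_dataset):
        ds, markers = small_dataset
        pairwise = {g for g, m in markers.items() if m["type"] == "pairwise"}
        lst = rank_pls(ds, "ovo", "simpls", 1, 3 * 3)  # 3 pairs x top 3
        assert pairwise <= set(lst.gene_ids)

    @pytest.mark.parametrize("algo", ["nipals", "simpls"])
    def test_two_class_modes_agree(self, two_class_dataset, algo):
        ds = two_class_dataset
        g = 10
        sets = [
            set(rank_pls(ds, mode, algo, 1, g).gene_ids)
            for mode in ("ovo", "ovr", "mclass")
        ]
        assert sets[0] == sets[1] == sets[2]

    def test_mclass_k2_order_matches_univariate(self, two_class_dataset):
        ds = two_class_dataset
        a = rank_pls(ds, "mclass", "simpls", 1, ds.m)
        b = rank_pls(ds, "ovo", "simpls", 1, ds.m)
        assert a.gene_ids == b.gene_ids

    def test_unit_variance_first_component_reproduces_f_order(self, rng):
        X = rng.normal(size=(26, 15))
        y = np.array([1] * 13 + [2] * 13)
        X[y == 1, :4] += 1.5
        Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        ds = ExpressionDataset(Xs + 5.0, y)  # shift: ranker centers internally
        lst = rank_pls(ds, "ovo", "nipals", 1, ds.m)
        F = np.array(
            [stats.f_oneway(X[y == 1, j], X[y == 2, j]).statistic for j in range(15)]
        )
        expected = [ds.gene_ids[j] for j in np.argsort(-F, kind="stable")]
        assert list(lst.gene_ids) == expected

    def test_nipals_r_weight_ranking_available(self, small_dataset):
        ds, _ = small_dataset
        lst = rank_pls(ds, "ovo", "nipals", 3, 10, use_r_weights=True)
        assert len(lst) == 10
        assert lst.method["use_r_weights"] is True

    def test_deterministic(self, small_dataset):
        ds, _ = small_dataset
        a = rank_pls(ds, "ovr", "simpls", 2, 15)
        b = rank_pls(ds, "ovr", "simpls", 2, 15)
        assert a.gene_ids == b.gene_ids and a.scores == b.scores


class TestRankTtest:
    def test_zero_statistic_for_identical_groups(self):
        X = np.array(
            [[1.0, 0.0], [2.0, 0.0], [1.0, 1.0], [2.0, 1.0]]
        )
        t = pooled_t_statistic(X, np.array([1, 1, -1, -1]))
        assert t[0] == 0.0  # groups (1,2) vs (1,2): zero mean difference
        assert t[1] == 0.0  # groups (0,0) vs (1,1): zero pooled variance rule

    def test_zero_pooled_variance_maps_to_zero(self):
        X = np.array([[0.0], [0.0], [1.0], [1.0]])
        t = pooled_t_statistic(X, np.array([1, 1, -1, -1]))
        assert t[0] == 0.0

    def test_degenerate_gene_ranked_last(self, rng):
        X = rng.normal(size=(12, 5))
        X[:, 2] = 3.14  # constant gene: zero pooled variance
        ds = ExpressionDataset(X, np.array([1] * 6 + [2] * 6))
        lst = rank_ttest(ds, "ovo", 5)
        assert lst.gene_ids[-1] == ds.gene_ids[2]

    def test_top_gene_matches_scipy_recomputation(self, rng):
        X = rng.normal(size=(20, 10))
        y = np.array([1] * 10 + [2] * 10)
        X[y == 1, 4] += 2.0
        ds = ExpressionDataset(X, y)
        lst = rank_ttest(ds, "ovo", 10)
        t_ref = [
            abs(stats.ttest_ind(X[y == 1, j], X[y == 2, j], equal_var=True).statistic)
            for j in range(10)
        ]
        assert lst.gene_ids[0] == ds.gene_ids[int(np.argmax(t_ref))]
        np.testing.assert_allclose(
            sorted(lst.scores, reverse=True), sorted(t_ref, reverse=True), atol=1e-10
        )

    def test_tiny_group_rejected(self):
        X = np.zeros((3, 2))
        X[0] = 1.0
        with pytest.raises(ValueError):
            pooled_t_statistic(X, np.array([1, -1, -1]))


class TestRankRfe:
    def test_separating_genes_survive(self, rng):
        X = rng.normal(size=(24, 22))
        y = np.array([1] * 12 + [2] * 12)
        X[y == 1, 0] += 4.0
        X[y == 2, 1] += 4.0
        ds = ExpressionDataset(X, y)
        lst = rank_rfe(ds, "ovo", 2, step_fraction=0.2)
        assert set(lst.gene_ids[:2]) == {ds.gene_ids[0], ds.gene_ids[1]}

    def test_full_list_matches_single_fit_when_g_equals_m(self, rng):
        from sklearn.svm import SVC

        X = rng.normal(size=(16, 5))
        y = np.array([1] * 8 + [2] * 8)
        X[y == 1, 3] += 2.0
        ds = ExpressionDataset(X, y)
        lst = rank_rfe(ds, "ovo", 5, step_fraction=0.2)
        clf = SVC(kernel="linear", C=1.0)
        clf.fit(X - X.mean(axis=0), (y == 1).astype(int))
        coef2 = np.ravel(clf.coef_) ** 2
        expected = [ds.gene_ids[j] for j in np.argsort(-coef2, kind="stable")]
        assert list(lst.gene_ids) == expected

    def test_invalid_step_rejected(self, two_class_dataset):
        with pytest.raises(ValueError):
            rank_rfe(two_class_dataset, "ovo", 5, step_fraction=1.5)

    def test_deterministic(self, two_class_dataset):
        a = rank_rfe(two_class_dataset, "ovr", 8)
        b = rank_rfe(two_class_dataset, "ovr", 8)
        assert a.gene_ids == b.gene_ids


class TestRankCustom:
    def test_plugin_scorer_decomposed_and_merged(self, small_dataset):
        ds, _ = small_dataset

        def mean_gap(problem, X):
            pos = X[problem.coded_labels > 0].mean(axis=0)
            neg = X[problem.coded_labels < 0].mean(axis=0)
            return np.abs(pos - neg)

        lst = rank_custom(ds, mean_gap, mode="ovr", g=12, name="gap")
        assert len(lst) == 12
        assert lst.method["selector"] == "gap"

    def test_bad_scorer_shape_reported(self, small_dataset):
        ds, _ = small_dataset
        with pytest.raises(ValueError, match="shape"):
            rank_custom(ds, lambda p, X: np.ones(3), mode="ovo", g=5)
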