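"""Scoring core: class statistics, DCFE, cluster separation, blending, ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sdcfe import (
    OmicsMatrix,
    SDCFEParams,
    class_stats,
    cluster_separation_scores,
    combine_scores,
    dcfe_scores,
    kmeans_partition,
    mad_per_gene,
    rank_features,
    score_features,
    select_top_fraction,
    select_top_k,
    stability_cutoff,
    simulate_expression,
    SimulationConfig,
)

from conftest import make_matrix


def brute_force_fisher(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Independent weighted between/within variance ratio, plain loops."""
    n, p = values.shape
    classes = sorted(set(labels))
    out = np.zeros(p)
    for j in range(p):
        col = values[:, j]
        grand = col.mean()
        between = within = 0.0
        for c in classes:
            sub = col[np.asarray(labels) == c]
            w = len(sub) / n
            between += w * (sub.mean() - grand) ** 2
            within += w * sub.var()  # population variance
        out[j] = between / (within + 1e-12)
    return out


class TestClassStats:
    def test_hand_arithmetic_two_class(self, two_class_toy):
        m, y = two_class_toy
        st = class_stats(m, y)
        assert st.class_means.loc["A", "g1"] == 1.0
        assert st.class_means.loc["B", "g1"] == 5.0
        assert st.grand_mean["g1"] == 3.0
        np.testing.assert_allclose(st.weights, [0.5, 0.5])

    def test_grand_mean_is_weighted_class_mean(self, random_matrix):
        y = pd.Series(["A"] * 8 + ["B"] * 5 + ["C"] * 7,
                      index=random_matrix.sample_ids)
        st = class_stats(random_matrix, y)
        recombined = st.class_means.mul(st.weights, axis=0).sum(axis=0)
        np.testing.assert_allclose(recombined, random_matrix.values.mean(axis=0))
        assert st.weights.sum() == pytest.approx(1.0)

    def test_balanced_three_class_weights(self):
        m = make_matrix(np.arange(12.0).reshape(6, 2))
        y = ["A", "A", "B", "B", "C", "C"]
        st = class_stats(m, y)
        np.testing.assert_allclose(st.weights, [1 / 3] * 3)

    def test_single_class_rejected(self, two_class_toy):
        m, _ = two_class_toy
        with pytest.raises(ValueError, match="2 classes"):
            class_stats(m, ["A"] * 4)

    def test_class_below_two_samples_rejected(self, two_class_toy):
        m, _ = two_class_toy
        with pytest.raises(ValueError, match="fewer than 2"):
            class_stats(m, ["A", "A", "A", "B"])


class TestMad:
    def test_hand_computed(self):
        m = make_matrix([[0.0], [2.0], [4.0], [6.0]])
        assert mad_per_gene(m).iloc[0] == 2.0

    def test_constant_gene_zero(self):
        m = make_matrix([[5.0], [5.0], [5.0]])
        assert mad_per_gene(m).iloc[0] == 0.0

    def test_single_sample_zero(self):
        m = make_matrix([[3.0]])
        assert mad_per_gene(m).iloc[0] == 0.0


class TestDcfe:
    def test_toy_with_mad_regularization(self, two_class_toy):
        m, y = two_class_toy
        assert dcfe_scores(m, y, lam=0.1).iloc[0] == pytest.approx(4 / 1.2, rel=1e-9)

    def test_toy_without_regularization(self, two_class_toy):
        m, y = two_class_toy
        assert dcfe_scores(m, y, lam=0.0).iloc[0] == pytest.approx(4.0, rel=1e-9)

    def test_constant_gene_scores_zero(self):
        m = make_matrix([[1.0, 0.0], [1.0, 2.0], [1.0, 4.0], [1.0, 6.0]])
        scores = dcfe_scores(m, ["A", "A", "B", "B"], lam=0.1)
        assert scores.iloc[0] == 0.0
        assert scores.iloc[1] > 0

    def test_matches_brute_force_oracle_at_lambda_zero(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            vals = rng.normal(size=(24, 15))
            labels = rng.choice(["a", "b", "c"], size=24)
            while min(np.sum(labels == c) for c in "abc") < 2:
                labels = rng.choice(["a", "b", "c"], size=24)
            m = make_matrix(vals)
            ours = dcfe_scores(m, labels, lam=0.0).to_numpy()
            oracle = brute_force_fisher(vals, labels)
            np.testing.assert_allclose(ours, oracle, atol=1e-9)

    def test_sample_permutation_invariance(self, random_matrix):
        y = np.array(["A"] * 10 + ["B"] * 10)
        base = dcfe_scores(random_matrix, y, lam=0.1)
        rng = np.random.default_rng(0)
        perm = rng.permutation(20)
        m2 = random_matrix.with_values(random_matrix.values.iloc[perm])
        permuted = dcfe_scores(m2, y[perm], lam=0.1)
        pd.testing.assert_series_equal(base, permuted)

    def test_class_relabeling_invariance(self, random_matrix):
        y = np.array(["A"] * 10 + ["B"] * 10)
        renamed = np.where(y == "A", "tumor", "normal")
        np.testing.assert_array_equal(
            dcfe_scores(random_matrix, y, 0.1).to_numpy(),
            dcfe_scores(random_matrix, renamed, 0.1).to_numpy(),
        )

    def test_scale_invariance_at_lambda_zero(self, random_matrix):
        y = ["A"] * 10 + ["B"] * 10
        base = dcfe_scores(random_matrix, y, lam=0.0)
        scaled_m = random_matrix.with_values(random_matrix.values * 7.5)
        scaled = dcfe_scores(scaled_m, y, lam=0.0)
        np.testing.assert_allclose(base, scaled, rtol=1e-9)

    def test_monotone_in_class_separation(self):
        # fixed within-class spread, growing gap between class means
        scores = []
        for gap in (1.0, 2.0, 4.0, 8.0):
            m = make_matrix([[0.0], [2.0], [gap], [gap + 2.0]])
            scores.append(dcfe_scores(m, ["A", "A", "B", "B"], 0.0).iloc[0])
        assert scores == sorted(scores)
        assert len(set(scores)) == len(scores)


class TestKmeansPartition:
    def test_obvious_two_groups(self):
        m = make_matrix([[0.0], [0.1], [10.0], [10.1]])
        assign = kmeans_partition(m, K=2, seed=0)
        assert assign[0] == assign[1]
        assert assign[2] == assign[3]
        assert assign[0] != assign[2]

    def test_k_equal_samples_gives_singletons(self):
        m = make_matrix(np.arange(4.0).reshape(4, 1) * 10)
        assign = kmeans_partition(m, K=4, seed=0)
        assert len(set(assign)) == 4

    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(2)
        a = rng.normal(-5, 1, size=(30, 5))
        b = rng.normal(5, 1, size=(30, 5))
        m = make_matrix(np.vstack([a, b]))
        assign = kmeans_partition(m, K=2, seed=0)
        first, second = set(assign[:30]), set(assign[30:])
        assert len(first) == 1 and len(second) == 1 and first != second

    def test_k_above_samples_rejected(self):
        m = make_matrix(np.eye(3))
        with pytest.raises(ValueError):
            kmeans_partition(m, K=4)

    def test_deterministic_given_seed(self, random_matrix):
        a1 = kmeans_partition(random_matrix, K=3, seed=9)
        a2 = kmeans_partition(random_matrix, K=3, seed=9)
        np.testing.assert_array_equal(a1, a2)

    def test_per_gene_mode_shape(self, random_matrix):
        assign = kmeans_partition(random_matrix, K=2, seed=0, mode="per_gene")
        assert assign.shape == (random_matrix.n_features,
                                random_matrix.n_samples)


class TestClusterSeparation:
    def test_hand_anova(self):
        m = make_matrix([[0.0], [2.0], [10.0], [12.0]])
        f = cluster_separation_scores(m, np.array([0, 0, 1, 1]))
        assert f.iloc[0] == pytest.approx(50.0, rel=1e-9)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(30, 6))
        assign = rng.integers(0, 3, size=30)
        m = make_matrix(vals)
        ours = cluster_separation_scores(m, assign).to_numpy()
        groups = [vals[assign == k] for k in range(3)]
        expected = sps.f_oneway(*groups).statistic
        np.testing.assert_allclose(ours, expected, rtol=1e-8)

    def test_constant_gene_zero(self):
        m = make_matrix([[1.0], [1.0], [1.0], [1.0]])
        f = cluster_separation_scores(m, np.array([0, 0, 1, 1]))
        assert f.iloc[0] == 0.0

    def test_zero_within_variance_capped(self):
        m = make_matrix([[0.0], [0.0], [1.0], [1.0]])
        f = cluster_separation_scores(m, np.array([0, 0, 1, 1]))
        assert f.iloc[0] == pytest.approx(1e12)

    def test_cluster_label_permutation_invariance(self, random_matrix):
        assign = np.array([0, 1, 2] * 6 + [0, 1])
        swapped = np.array([2, 0, 1] * 6 + [2, 0])
        pd.testing.assert_series_equal(
            cluster_separation_scores(random_matrix, assign),
            cluster_separation_scores(random_matrix, swapped),
        )

    def test_single_cluster_rejected(self, random_matrix):
        with pytest.raises(ValueError):
            cluster_separation_scores(random_matrix, np.zeros(20, dtype=int))


class TestCombineScores:
    def test_alpha_one_returns_dcfe_component(self):
        d = pd.Series([4.0, 1.0, 0.0], index=list("abc"))
        c = pd.Series([9.0, 0.0, 3.0], index=list("abc"))
        out = combine_scores(d, c, alpha=1.0, norm="minmax")
        np.testing.assert_allclose(out, [1.0, 0.25, 0.0])

    def test_alpha_zero_returns_cs_component(self):
        d = pd.Series([4.0, 1.0], index=list("ab"))
        c = pd.Series([10.0, 0.0], index=list("ab"))
        out = combine_scores(d, c, alpha=0.0, norm="minmax")
        np.testing.assert_allclose(out, [1.0, 0.0])

    def test_minmax_blend_hand_example(self):
        d = pd.Series([4.0, 0.0], index=list("ab"))
        c = pd.Series([50.0, 0.0], index=list("ab"))
        out = combine_scores(d, c, alpha=0.7, norm="minmax")
        np.testing.assert_allclose(out, [1.0, 0.0])

    def test_raw_mode_is_literal_weighted_sum(self):
        d = pd.Series([4.0, 0.0], index=list("ab"))
        c = pd.Series([50.0, 10.0], index=list("ab"))
        out = combine_scores(d, c, alpha=0.7, norm="raw")
        np.testing.assert_allclose(out, [0.7 * 4 + 0.3 * 50, 0.3 * 10])

    def test_minmax_output_bounded(self):
        rng = np.random.default_rng(1)
        d = pd.Series(rng.gamma(1, 5, 50))
        c = pd.Series(rng.gamma(1, 50, 50))
        out = combine_scores(d, c, alpha=0.7)
        assert out.between(0, 1).all()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            combine_scores(pd.Series([1.0]), pd.Series([1.0, 2.0]), 0.5)


class TestRankingAndSelection:
    def _table(self, scores: dict[str, float]) -> pd.DataFrame:
        s = pd.Series(scores)
        return rank_features(s * 0, s * 0, s)

    def test_descending_rank(self):
        t = self._table({"g2": 5.0, "g1": 7.0})
        assert t["feature_id"].tolist() == ["g1", "g2"]
        assert t["rank"].tolist() == [1, 2]

    def test_ties_break_by_feature_id(self):
        t = self._table({"b": 3.0, "a": 3.0})
        assert t["feature_id"].tolist() == ["a", "b"]

    def test_ranks_are_permutation(self):
        rng = np.random.default_rng(4)
        t = self._table({f"g{i}": rng.random() for i in range(921)})
        assert sorted(t["rank"]) == list(range(1, 922))
        assert (t["sdcfe"].diff().dropna() <= 0).all()

    def test_nan_scores_rejected(self):
        s = pd.Series({"a": np.nan, "b": 1.0})
        with pytest.raises(ValueError):
            rank_features(s, s, s)

    @pytest.mark.parametrize("n,fraction,expected",
                             [(921, 0.5, 461), (10, 1.0, 10), (7, 0.5, 4)])
    def test_ceiling_fraction_cutoff(self, n, fraction, expected):
        t = self._table({f"g{i:04d}": float(i) for i in range(n)})
        assert len(select_top_fraction(t, fraction)) == expected

    def test_bad_fraction_rejected(self):
        t = self._table({"a": 1.0})
        for frac in (0.0, 1.5, -0.1):
            with pytest.raises(ValueError):
                select_top_fraction(t, frac)

    def test_top_k_returns_best_ranked(self):
        t = self._table({"a": 1.0, "b": 3.0, "c": 2.0})
        assert list(select_top_k(t, 2)) == ["b", "c"]


class TestPipelineDeterminism:
    def test_score_features_reproducible(self):
        cfg = SimulationConfig(n_classes=3, n_per_class=20, n_genes=80,
                               n_informative=8, seed=7)
        m, y, _, _ = simulate_expression(cfg)
        t1 = score_features(m, y, SDCFEParams(seed=11))
        t2 = score_features(m, y, SDCFEParams(seed=11))
        pd.testing.assert_frame_equal(t1, t2)

    def test_alpha_extremes_change_ranking_toward_components(self):
        # class-block genes should lead at alpha=1, subtype-block at alpha=0
        from sdcfe.simulate import subtype_gene_ids

        cfg = SimulationConfig(n_classes=2, n_per_class=30, n_genes=120,
                               n_informative=10, effect_size=2.0,
                               n_subtypes=2, subtype_effect=5.0,
                               n_subtype_genes=10, seed=3)
        m, y, planted, _ = simulate_expression(cfg)
        sub_genes = set(subtype_gene_ids(cfg))
        # cluster on the subtype-bearing structure
        sup = score_features(m, y, SDCFEParams(alpha=1.0, seed=5))
        unsup = score_features(m, y, SDCFEParams(alpha=0.0, seed=5))
        top_sup = set(sup.sort_values("rank")["feature_id"].iloc[:10])
        top_unsup = set(unsup.sort_values("rank")["feature_id"].iloc[:10])
        assert len(top_sup & set(planted)) >= 8
        assert len(top_unsup & sub_genes) > len(top_sup & sub_genes)


class TestStabilityCutoff:
    def test_plateau_detected_with_planted_signal(self):
        cfg = SimulationConfig(n_classes=2, n_per_class=50, n_genes=200,
                               n_informative=20, effect_size=3.0, seed=1)
        m, y, _, _ = simulate_expression(cfg)
        report = stability_cutoff(m, y, SDCFEParams(seed=1),
                                  k_grid=[10, 20, 40, 80], B=4, cv_folds=4)
        assert report.chosen_k in report.k_grid
        assert report.chosen_k <= 40
        assert all(0 <= s <= 1 for s in report.stability)
        assert all(0 <= a <= 1 for a in report.cv_accuracy)

    def test_full_feature_set_has_unit_stability(self):
        cfg = SimulationConfig(n_classes=2, n_per_class=20, n_genes=30,
                               n_informative=5, seed=2)
        m, y, _, _ = simulate_expression(cfg)
        report = stability_cutoff(m, y, SDCFEParams(seed=2),
                                  k_grid=[30], B=3, cv_folds=3)
        assert report.stability == [1.0]

    def test_empty_grid_rejected(self, two_class_toy):
        m, y = two_class_toy
        with pytest.raises(ValueError):
            stability_cutoff(m, y, SDCFEParams(), k_grid=[], B=3)
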