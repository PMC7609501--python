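"""RF classification, per-feature statistics and combined selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from bfikit.discovery import (
    ContrastSpec,
    FeatureStats,
    RFParams,
    aggregate_rank_of,
    build_contrast,
    classify_urine_classes,
    compute_feature_stats,
    feature_auc,
    mds_embed,
    select_features,
    welch_t,
)
from bfikit.simulate import two_class_spike_scenario


def brute_force_auc(pos, neg):
    wins = sum(
        1.0 if a > b else 0.5 if a == b else 0.0 for a in pos for b in neg
    )
    return wins / (len(pos) * len(neg))


class TestFeatureAuc:
    def test_all_ties_give_half(self):
        values = [1.0] * 10
        labels = np.array(["b"] * 5 + ["e"] * 5)
        assert feature_auc(values, labels, "e") == 0.5

    def test_perfect_separation(self):
        labels = np.array(["b"] * 3 + ["e"] * 3)
        assert feature_auc([1, 2, 3, 10, 11, 12], labels, "e") == 1.0

    def test_worked_pair_counting_example(self):
        # exposed {3,5} vs baseline {1,4}: 3 wins, 1 loss of 4 pairs
        labels = np.array(["e", "e", "b", "b"])
        assert feature_auc([3, 5, 1, 4], labels, "e") == 0.75

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            feature_auc([1.0, 2.0], np.array(["b", "b"]), "e")

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        pos=st.lists(st.integers(-5, 5), min_size=1, max_size=100),
        neg=st.lists(st.integers(-5, 5), min_size=1, max_size=100),
    )
    def test_equals_brute_force_pair_counting(self, pos, neg):
        """Rank-based AUC equals exhaustive pair counting (<= 200 samples)."""
        values = np.array(pos + neg, dtype=float)
        labels = np.array(["e"] * len(pos) + ["b"] * len(neg))
        assert feature_auc(values, labels, "e") == pytest.approx(
            brute_force_auc(pos, neg), abs=1e-12
        )

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        pos=st.lists(st.floats(-10, 10), min_size=1, max_size=30),
        neg=st.lists(st.floats(-10, 10), min_size=1, max_size=30),
    )
    def test_label_swap_antisymmetry(self, pos, neg):
        values = np.array(pos + neg)
        labels = np.array(["e"] * len(pos) + ["b"] * len(neg))
        assert feature_auc(values, labels, "e") == pytest.approx(
            1.0 - feature_auc(values, labels, "b"), abs=1e-12
        )


class TestWelchT:
    def test_matches_direct_formula(self):
        """Welch statistic and Welch-Satterthwaite p recomputed from the
        textbook formulas."""
        a = np.array([3.1, 2.9, 3.4, 3.0, 2.8])
        b = np.array([2.1, 2.4, 2.0, 2.6])
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        t_exp = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        p_exp = 2 * sps.t.sf(abs(t_exp), df)
        values = np.concatenate([a, b])
        labels = np.array(["e"] * 5 + ["b"] * 4)
        t, p = welch_t(values, labels, "e")
        assert t == pytest.approx(t_exp, abs=1e-10)
        assert p == pytest.approx(p_exp, abs=1e-10)

    def test_large_shift_gives_vanishing_p(self):
        values = np.r_[np.zeros(10), np.full(10, 100.0)] + np.tile(
            [0.0, 0.01], 10
        )
        labels = np.array(["b"] * 10 + ["e"] * 10)
        _, p = welch_t(values, labels, "e")
        assert p < 1e-20

    def test_pooled_switch_matches_student(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=12)
        labels = np.array(["e"] * 6 + ["b"] * 6)
        t, p = welch_t(values, labels, "e", pooled=True)
        t_ref, p_ref = sps.ttest_ind(values[:6], values[6:], equal_var=True)
        assert (t, p) == (pytest.approx(t_ref), pytest.approx(p_ref))

    def test_degenerate_inputs_rejected(self):
        labels = np.array(["e", "e", "b", "b"])
        with pytest.raises(ValueError):
            welch_t([1.0, 1.0, 2.0, 2.0], labels, "e")  # zero variance both
        with pytest.raises(ValueError):
            welch_t([1.0, 2.0, 3.0], np.array(["e", "b", "b"]), "e")


class TestSelectFeatures:
    def _stats(self, rng, n):
        return [
            FeatureStats(
                mz=100.0 + i, rf_importance=float(rng.uniform(0, 0.01)),
                auc=float(rng.uniform(0.3, 0.7)),
                t_statistic=float(rng.normal()), p_value=float(rng.uniform(0.2, 1)),
            )
            for i in range(n)
        ]

    def test_triple_winner_is_first_with_minimal_score(self):
        rng = np.random.default_rng(0)
        fs = self._stats(rng, 20)
        fs[7] = FeatureStats(
            mz=107.0, rf_importance=1.0, auc=1.0, t_statistic=50.0, p_value=1e-30
        )
        selected = select_features(fs, k=5, fdr_alpha=0.05)
        assert selected[0].mz == 107.0
        assert selected[0].aggregate_rank == 1
        assert aggregate_rank_of(fs, 107.0) == 1

    def test_null_features_not_selected(self):
        rng = np.random.default_rng(1)
        selected = select_features(self._stats(rng, 200), k=25, fdr_alpha=0.05)
        assert selected == []

    def test_permutation_invariance_of_selection(self):
        rng = np.random.default_rng(2)
        fs = self._stats(rng, 50)
        fs[3] = FeatureStats(
            mz=103.0, rf_importance=0.9, auc=0.99, t_statistic=30.0, p_value=1e-20
        )
        shuffled = list(fs)
        rng.shuffle(shuffled)
        a = [f.mz for f in select_features(fs, k=10, fdr_alpha=0.05)]
        b = [f.mz for f in select_features(shuffled, k=10, fdr_alpha=0.05)]
        assert a == b

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            select_features([], k=0)
        with pytest.raises(ValueError):
            select_features([], k=5, fdr_alpha=1.0)


class TestClassifier:
    def test_strong_marker_gives_high_oob_auc(self, full_panel_sim):
        from bfikit.processing import normalize_dilution, transform_log

        matrix, truth, _ = full_panel_sim
        mn = transform_log(normalize_dilution(matrix))
        idx, labels = build_contrast(mn, truth, ContrastSpec(target="garden peas"))
        X = mn.intensities[idx]
        metrics, proximity = classify_urine_classes(
            X, labels, positive_class="exposed",
            params=RFParams(n_trees=300), seed=0,
        )
        assert metrics.auc > 0.9
        assert metrics.out_of_bag
        n = len(labels)
        assert proximity.shape == (n, n)
        assert np.allclose(proximity, proximity.T)
        assert np.allclose(np.diag(proximity), 1.0)

    def test_reproducible_for_fixed_seed(self):
        X, labels, _ = two_class_spike_scenario(
            fold=3.0, n_features=100, n_per_class=10, seed=4
        )
        m1, p1 = classify_urine_classes(X, labels, params=RFParams(100), seed=7)
        m2, p2 = classify_urine_classes(X, labels, params=RFParams(100), seed=7)
        assert m1 == m2 and np.array_equal(p1, p2)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(12, 5))
        with pytest.raises(ValueError, match="two classes"):
            classify_urine_classes(X, ["a"] * 12)

    def test_small_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(8, 5))
        with pytest.raises(ValueError, match=">= 5"):
            classify_urine_classes(X, ["a"] * 4 + ["b"] * 4)

    def test_too_few_features_rejected(self):
        X = np.random.default_rng(0).normal(size=(12, 1))
        with pytest.raises(ValueError, match="features"):
            classify_urine_classes(X, ["a"] * 6 + ["b"] * 6)

    def test_contradictory_duplicates_are_anti_predicted_out_of_bag(self):
        # each sample's identical twin carries the opposite label; when the
        # sample is out of bag its twin is usually in bag, so OOB votes are
        # systematically anti-correlated: the margin is strongly negative,
        # not zero (vote symmetry only holds pooled over in- and out-of-bag)
        rng = np.random.default_rng(3)
        base = rng.normal(size=(12, 30))
        X = np.vstack([base, base])
        labels = np.array(["a"] * 12 + ["b"] * 12)
        metrics, _ = classify_urine_classes(
            X, labels, params=RFParams(n_trees=400), seed=0
        )
        assert metrics.mean_margin < -0.3
        assert metrics.accuracy < 0.5


class TestMds:
    def test_three_equidistant_points_form_equilateral_triangle(self):
        prox = np.eye(3)
        coords = mds_embed(prox, dims=2)
        d = [
            np.linalg.norm(coords[i] - coords[j])
            for i in range(3) for j in range(i + 1, 3)
        ]
        assert np.allclose(d, d[0], atol=1e-9)

    def test_two_perfect_clusters_collapse_to_two_points(self):
        prox = np.zeros((6, 6))
        prox[:3, :3] = 1.0
        prox[3:, 3:] = 1.0
        coords = mds_embed(prox, dims=2)
        assert np.allclose(coords[:3], coords[0], atol=1e-6)
        assert np.allclose(coords[3:], coords[3], atol=1e-6)
        assert np.linalg.norm(coords[0] - coords[3]) > 0.5

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 1, size=(8, 8))
        prox = (a + a.T) / 2
        np.fill_diagonal(prox, 1.0)
        c1, c2 = mds_embed(prox), mds_embed(prox)
        assert np.array_equal(c1, c2)
        for k in range(c1.shape[1]):
            assert c1[np.argmax(np.abs(c1[:, k])), k] >= 0

    def test_asymmetric_input_rejected(self):
        bad = np.array([[1.0, 0.2], [0.4, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            mds_embed(bad)

    def test_embedding_preserves_distance_ranks(self):
        """Embedded distances track RF proximity distances (Spearman > 0.8)."""
        X, labels, _ = two_class_spike_scenario(
            fold=5.0, n_features=200, n_per_class=15, seed=2
        )
        _, proximity = classify_urine_classes(
            X, labels, params=RFParams(n_trees=300), seed=2
        )
        coords = mds_embed(proximity)
        iu = np.triu_indices(len(labels), k=1)
        input_d = (1.0 - proximity)[iu]
        embed_d = np.sqrt(
            ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
        )[iu]
        rho = sps.spearmanr(input_d, embed_d).statistic
        assert rho > 0.8


class TestContrast:
    def test_fmv_vs_bedtime_on_exposure_days(self, full_panel_sim):
        matrix, truth, _ = full_panel_sim
        idx, labels = build_contrast(
            matrix, truth, ContrastSpec(target="garden peas")
        )
        assert len(idx) > 0
        types = {matrix.sample_meta[i].urine_type for i in idx}
        assert types == {"FMV", "bed_time"}
        assert set(labels) == {"baseline", "exposed"}
        # one FMV baseline per exposed bed-time sample day
        assert (labels == "exposed").sum() == (labels == "baseline").sum()

    def test_unknown_target_rejected(self, full_panel_sim):
        matrix, truth, _ = full_panel_sim
        with pytest.raises(ValueError, match="no column"):
            build_contrast(matrix, truth, ContrastSpec(target="dragon fruit"))


class TestFeatureStatsComputation:
    def test_constant_feature_marked_uninformative(self):
        X = np.c_[np.ones(12), np.r_[np.zeros(6), np.ones(6)]]
        labels = np.array(["b"] * 6 + ["e"] * 6)
        fs = compute_feature_stats(X, labels, [100.5, 101.5], "e", np.array([0.5, 0.5]))
        assert fs[0].auc == 0.5 and fs[0].p_value == 1.0
        assert fs[1].auc == 1.0 and fs[1].p_value < 1e-6
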