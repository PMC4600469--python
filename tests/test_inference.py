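"""LOSO classification, permutation inference, g-maps and univariate tests."""

import numpy as np
import pandas as pd
import pytest

from phconn.features import assemble_cross_features, assemble_features, assemble_ordinal_features
from phconn.inference import (
    ContrastAnalysis,
    bonferroni_adjust,
    compute_gmap,
    correlate_covariate,
    cross_model_confusion,
    loso_classify,
    orgp_fit_predict,
    paired_node_ttests,
    permutation_pvalue,
)
from phconn.synthetic import planted_dc_delta
from tests.conftest import make_dc_map
from phconn.synthetic import CohortConfig


class TestLosoClassify:
    def test_overwhelming_effect_classified_perfectly(self, strong_features):
        res = loso_classify(strong_features)
        assert res.accuracy == 1.0
        assert res.n_test_items == 16  # 8 subjects x 2 conditions

    def test_accuracy_quantised_by_item_count(self, strong_features):
        res = loso_classify(strong_features, theta_mode="shared")
        assert (res.accuracy * res.n_test_items) == pytest.approx(
            round(res.accuracy * res.n_test_items)
        )

    def test_probability_table_covers_all_items(self, strong_features):
        res = loso_classify(strong_features)
        df = res.per_subject_probabilities
        assert len(df) == res.n_test_items
        assert set(df["condition"]) == {"ketamine", "saline"}
        assert df["probability"].between(0, 1).all()

    def test_unknown_theta_mode_rejected(self, strong_features):
        with pytest.raises(ValueError, match="theta_mode"):
            loso_classify(strong_features, theta_mode="banana")

    def test_needs_three_subjects(self, rng):
        from phconn.features import CentralityFeatureSet

        fs = CentralityFeatureSet(
            features=rng.standard_normal((8, 3)),
            labels=np.tile([1, -1], 4),
            subject_ids=np.repeat(["s0", "s1"], 4),
            conditions=np.tile(["a", "b"], 4),
            window_index=np.zeros(8, int),
            node_labels=["n0", "n1", "n2"],
            contrast=("a", "b"),
        )
        with pytest.raises(ValueError, match="3 subjects"):
            loso_classify(fs)


class TestPermutation:
    def test_strong_effect_attains_minimum_p(self, strong_features):
        p = permutation_pvalue(strong_features, n_perm=19, seed=0)
        assert p == pytest.approx(1.0 / 20.0)

    def test_p_bounded_by_add_one_rule(self, strong_features):
        p, null = permutation_pvalue(
            strong_features, n_perm=9, seed=1, return_null=True
        )
        assert 1.0 / 10.0 <= p <= 1.0
        assert len(null) == 9

    def test_true_accuracy_below_null_gives_one(self, strong_features):
        p = permutation_pvalue(
            strong_features, true_accuracy=0.0, n_perm=9, seed=2
        )
        assert p == 1.0

    def test_reproducible_given_seed(self, strong_features):
        p1 = permutation_pvalue(strong_features, n_perm=9, seed=3)
        p2 = permutation_pvalue(strong_features, n_perm=9, seed=3)
        assert p1 == p2


class TestBonferroni:
    def test_textbook_examples(self):
        adj, sig = bonferroni_adjust([0.003, 0.02, 0.9], family_size=4)
        np.testing.assert_allclose(adj, [0.012, 0.08, 1.0])
        assert list(sig) == [True, False, False]

    def test_family_defaults_to_count(self):
        adj, _ = bonferroni_adjust([0.01, 0.01])
        np.testing.assert_allclose(adj, [0.02, 0.02])

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="0, 1"):
            bonferroni_adjust([1.5])
        with pytest.raises(ValueError, match="family"):
            bonferroni_adjust([0.1, 0.2, 0.3], family_size=2)


class TestGMap:
    def test_antisymmetry_under_label_swap(self, strong_cohort):
        _, dc_map, truth = strong_cohort
        fs_ab = assemble_features(dc_map, "ketamine", "saline", truth.node_labels)
        fs_ba = assemble_features(dc_map, "saline", "ketamine", truth.node_labels)
        g_ab = compute_gmap(
            loso_classify(fs_ab, theta_mode="shared").fold_models,
            truth.node_labels,
        )
        g_ba = compute_gmap(
            loso_classify(fs_ba, theta_mode="shared").fold_models,
            truth.node_labels,
        )
        np.testing.assert_allclose(g_ab.node_weights, -g_ba.node_weights,
                                   atol=1e-8)

    def test_fold_weights_reproduce_latent_mean(self, strong_features):
        res = loso_classify(strong_features)
        X = strong_features.features[:7]
        for m in res.fold_models:
            mu, _ = m.predict_latent(X)
            np.testing.assert_allclose(mu, X @ m.weights, atol=1e-10)

    def test_weights_track_planted_truth(self, strong_cohort):
        # On the small 8-subject toy the per-node sign of mid-rank nodes is
        # noisy, but the recovered pattern must correlate strongly with the
        # planted centrality change (full-size top-20 sign agreement is
        # exercised in the acceptance suite).
        _, dc_map, truth = strong_cohort
        fs = assemble_features(dc_map, "ketamine", "saline", truth.node_labels)
        res = loso_classify(fs, theta_mode="shared")
        gm = compute_gmap(res.fold_models, truth.node_labels)
        dd = planted_dc_delta(truth, "ketamine")
        r = np.corrcoef(gm.node_weights, dd)[0, 1]
        assert r > 0.5

    def test_export_frame_and_radius(self, strong_features):
        res = loso_classify(strong_features, theta_mode="shared")
        gm = compute_gmap(
            res.fold_models,
            strong_features.node_labels,
            mni_centroids=np.zeros((len(strong_features.node_labels), 3)),
        )
        df = gm.to_frame()
        assert {"label", "weight", "sign", "radius", "mni_x"} <= set(df.columns)
        assert df["radius"].max() == pytest.approx(1.0)

    def test_non_gpc_models_rejected(self):
        with pytest.raises(ValueError, match="linear-kernel"):
            compute_gmap([object()], ["n0"])


class TestCrossModel:
    @pytest.fixture(scope="class")
    def three_condition_maps(self):
        cfg = CohortConfig(
            n_subjects=8, n_nodes=30, n_volumes=150,
            conditions=("saline", "ketamine", "third"),
            condition_effects={"ketamine": 1.0, "third": 1.0},
            effect_size=2.0, seed=23,
        )
        return make_dc_map(cfg)

    def test_condition_matching_class_a_assigned_to_a(self, three_condition_maps):
        dc_map, truth = three_condition_maps
        tr_fs, te_fs = assemble_cross_features(
            dc_map, "ketamine", "saline", "third", truth.node_labels
        )
        df = cross_model_confusion(tr_fs, te_fs, theta_mode="shared")
        props = df.attrs["proportions"]
        assert props["ketamine"] + props["saline"] == pytest.approx(1.0)
        assert props["ketamine"] >= 0.75

    def test_overlapping_test_condition_rejected(self, three_condition_maps):
        dc_map, truth = three_condition_maps
        with pytest.raises(ValueError, match="overlap"):
            assemble_cross_features(
                dc_map, "ketamine", "saline", "saline", truth.node_labels
            )


class TestOrdinalLoso:
    def test_two_class_reduction_agrees_with_binary_gpc(self, strong_cohort):
        _, dc_map, truth = strong_cohort
        fs_bin = assemble_features(dc_map, "ketamine", "saline", truth.node_labels)
        fs_ord = assemble_ordinal_features(
            dc_map, ["saline", "ketamine"], truth.node_labels
        )
        res_bin = loso_classify(fs_bin)
        res_ord = orgp_fit_predict(fs_ord)
        bp = res_bin.per_subject_probabilities.set_index(
            ["subject_id", "condition"]
        )["prediction"]
        op = res_ord.per_subject_probabilities.set_index(
            ["subject_id", "condition"]
        )["predicted_class"]
        agree = np.mean(
            [(1 if bp[k] == 1 else 0) == op[k] for k in bp.index]
        )
        assert agree >= 0.95
        assert np.all(np.diff(res_ord.thresholds.reshape(-1)) > 0) or len(
            res_ord.thresholds
        ) == 1

    def test_confusion_rows_normalised(self, strong_cohort):
        _, dc_map, truth = strong_cohort
        fs_ord = assemble_ordinal_features(
            dc_map, ["saline", "ketamine"], truth.node_labels
        )
        res = orgp_fit_predict(fs_ord)
        np.testing.assert_allclose(res.confusion_matrix.sum(axis=1), 1.0)


class TestUnivariate:
    def test_equal_inputs_give_null_t(self, rng):
        dc = rng.standard_normal((6, 4))
        df = paired_node_ttests(dc, dc.copy())
        np.testing.assert_allclose(df["t"], 0.0)
        np.testing.assert_allclose(df["p"], 1.0)

    def test_hand_computed_t_value(self):
        dc_b = np.zeros((4, 1))
        dc_a = np.array([[1.0], [2.0], [3.0], [4.0]])
        df = paired_node_ttests(dc_a, dc_b)
        assert df["t"][0] == pytest.approx(2.5 / (1.2909944 / 2.0), abs=1e-4)
        assert df["t"][0] == pytest.approx(3.873, abs=1e-3)

    def test_constant_nonzero_delta_flagged_degenerate(self):
        dc_b = np.zeros((5, 2))
        dc_a = np.column_stack([np.full(5, 2.0), np.zeros(5)])
        df = paired_node_ttests(dc_a, dc_b)
        assert bool(df["degenerate"][0]) and np.isinf(df["t"][0])
        assert df["p"][0] == 0.0
        assert not df["degenerate"][1]

    def test_matches_scipy_ttest(self, rng):
        from scipy import stats

        a = rng.standard_normal((10, 3))
        b = rng.standard_normal((10, 3))
        df = paired_node_ttests(a, b)
        t_ref, p_ref = stats.ttest_rel(a, b, axis=0)
        np.testing.assert_allclose(df["t"], t_ref, atol=1e-10)
        np.testing.assert_allclose(df["p"], p_ref, atol=1e-10)


class TestCovariateCorrelation:
    def test_perfect_correlations(self):
        x = np.array([0.1, 0.4, 0.6, 0.9])
        assert correlate_covariate(x, x)[0] == pytest.approx(1.0)
        assert correlate_covariate(x, -x)[0] == pytest.approx(-1.0)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlate_covariate(np.array([0.1, 0.5, 0.9]), np.ones(3))

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(77)
        ps = []
        for _ in range(200):
            r, p = correlate_covariate(
                rng.standard_normal(16), rng.standard_normal(16)
            )
            ps.append(p)
        frac = np.mean(np.array(ps) <= 0.05)
        assert 0.01 <= frac <= 0.10


class TestContrastAnalysisWrapper:
    def test_fit_permute_gmap_summary(self, strong_features):
        model = ContrastAnalysis(strong_features)
        res = model.fit(theta_mode="shared")
        assert res.accuracy == 1.0
        p = res.permutation_test(n_perm=9, seed=4)
        assert res.result.permutation_p == p
        gm = res.gmap()
        assert len(gm.node_weights) == len(strong_features.node_labels)
        text = res.summary()
        assert "accuracy" in text and "permutation p" in text
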