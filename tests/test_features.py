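"""Taper, windowing, weighted correlation, degree centrality, feature sets."""

import numpy as np
import pytest

from phconn.features import (
    CentralityFeatureSet,
    assemble_features,
    assemble_ordinal_features,
    compute_adjacency_stack,
    degree_centrality,
    density_normalize,
    gaussian_taper,
    weighted_correlation_matrix,
    window_series,
)
from phconn.preprocess import ParcellatedTimeSeries


class TestTaper:
    def test_unit_weight_at_center(self):
        tw = gaussian_taper(120)
        assert tw.weights[tw.offsets == 0][0] == 1.0

    def test_symmetric_about_center(self):
        tw = gaussian_taper(120)
        np.testing.assert_allclose(tw.weights, tw.weights[::-1])

    def test_edge_value_closed_form(self):
        # t = +/- T/2 = +/- 3s gives exp(-4.5)
        tw = gaussian_taper(120, 20)
        assert tw.weights[0] == pytest.approx(np.exp(-4.5), abs=1e-12)
        assert tw.weights[0] == pytest.approx(0.011109, abs=1e-6)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            gaussian_taper(120, 0.0)


class TestWindowSeries:
    def test_150_volumes_default_geometry_gives_eight_windows(self):
        segs = window_series(np.zeros((150, 3)))
        assert len(segs) == 8

    def test_centers_follow_half_step_convention(self):
        segs = window_series(np.zeros((150, 3)))
        assert [s.center for s in segs] == [10, 30, 50, 70, 90, 110, 130, 150]
        # boundary-clipped windows keep at least T/2 samples
        assert min(len(s.indices) for s in segs) >= 60

    def test_single_window_when_length_equals_step(self):
        assert len(window_series(np.zeros((20, 2)), length_T=120, s=20)) == 1

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            window_series(np.zeros((10, 2)), length_T=120, s=20)

    def test_taper_truncated_with_clipping(self):
        segs = window_series(np.zeros((150, 2)))
        first = segs[0]
        assert first.indices[0] == 0
        np.testing.assert_allclose(
            first.weights,
            np.exp(-((first.indices - first.center) ** 2) / (2 * 20.0**2)),
        )


class TestWeightedCorrelation:
    def test_identical_and_negated_nodes(self, rng):
        x = rng.standard_normal(40)
        seg = np.column_stack([x, x, -x])
        C = weighted_correlation_matrix(seg, rng.uniform(0.2, 1.0, 40))
        assert C[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert C[0, 2] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_weighted_moment_oracle(self, rng):
        seg = rng.standard_normal((30, 2))
        w = rng.uniform(0.1, 1.0, 30)
        C = weighted_correlation_matrix(seg, w)
        mean = (w @ seg) / w.sum()
        cen = seg - mean
        cov = (cen * w[:, None]).T @ cen / w.sum()
        oracle = cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1])
        assert C[0, 1] == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_node_named(self, rng):
        seg = np.column_stack([rng.standard_normal(20), np.ones(20)])
        with pytest.raises(ValueError, match="node index 1"):
            weighted_correlation_matrix(seg, np.ones(20))

    def test_needs_three_positive_weights(self, rng):
        seg = rng.standard_normal((10, 2))
        w = np.zeros(10)
        w[:2] = 1.0
        with pytest.raises(ValueError, match="3 samples"):
            weighted_correlation_matrix(seg, w)

    def test_node_relabelling_equivariance(self, rng):
        seg = rng.standard_normal((50, 6))
        w = rng.uniform(0.1, 1.0, 50)
        perm = rng.permutation(6)
        C = weighted_correlation_matrix(seg, w)
        Cp = weighted_correlation_matrix(seg[:, perm], w)
        np.testing.assert_allclose(Cp, C[np.ix_(perm, perm)], atol=1e-12)


class TestDegreeCentrality:
    def test_complete_and_star_graphs(self):
        complete = np.ones((3, 3)) - np.eye(3)
        np.testing.assert_allclose(degree_centrality(complete), [2, 2, 2])
        star = np.zeros((4, 4))
        star[0, 1:] = star[1:, 0] = 1.0
        np.testing.assert_allclose(degree_centrality(star), [3, 1, 1, 1])

    def test_zero_matrix(self):
        np.testing.assert_allclose(degree_centrality(np.zeros((5, 5))), 0.0)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            degree_centrality(np.zeros((3, 4)))

    def test_matches_bruteforce_double_loop(self, rng):
        A = rng.standard_normal((10, 10))
        A = 0.5 * (A + A.T)
        want = np.array(
            [sum(A[i, j] for j in range(10) if j != i) for i in range(10)]
        )
        np.testing.assert_allclose(degree_centrality(A), want, atol=1e-12)


class TestDensityNormalize:
    def test_uniform_complete_graph_scale_free(self):
        for c in (0.2, 5.0):
            A = c * (np.ones((6, 6)) - np.eye(6))
            out = density_normalize(degree_centrality(A), A)
            np.testing.assert_allclose(out, 5.0)  # N - 1, independent of c

    def test_positive_scaling_cancels(self, rng):
        A = rng.standard_normal((8, 8))
        A = 0.5 * (A + A.T)
        np.fill_diagonal(A, 0.0)
        a = density_normalize(degree_centrality(A), A)
        b = density_normalize(degree_centrality(3.7 * A), 3.7 * A)
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_zero_density_rejected(self):
        A = np.zeros((4, 4))
        with pytest.raises(ValueError, match="density"):
            density_normalize(degree_centrality(A), A)


class TestAdjacencyStack:
    def test_default_stack_geometry(self, rng):
        ts = ParcellatedTimeSeries(
            data=rng.standard_normal((150, 12)),
            tr=2.0,
            node_labels=[f"n{i}" for i in range(12)],
        )
        stack = compute_adjacency_stack(ts)
        assert stack.matrices.shape == (8, 12, 12)
        for k in range(8):
            np.testing.assert_allclose(
                stack.matrices[k], stack.matrices[k].T, atol=1e-12
            )
            np.testing.assert_allclose(np.diag(stack.matrices[k]), 1.0)


def _dc_map(rng, subjects, conditions, K=4, N=5, offset=None):
    out = {}
    for s in subjects:
        for c in conditions:
            dc = rng.standard_normal((K, N))
            if offset is not None:
                dc = dc + offset.get((s, c), 0.0)
            out[(s, c)] = dc
    return out


class TestAssembleFeatures:
    def test_subject_centering_and_counts(self, rng):
        subs = [f"s{i}" for i in range(16)]
        dc = _dc_map(rng, subs, ["a", "b"], K=8, N=6)
        fs = assemble_features(dc, "a", "b", [f"n{i}" for i in range(6)])
        assert fs.n_samples == 16 * 2 * 8
        for s in subs:
            rows = fs.features[fs.subject_ids == s]
            assert np.abs(rows.mean(axis=0)).max() < 1e-10
        assert set(np.unique(fs.labels)) == {-1, 1}

    def test_identical_condition_stacks_carry_no_class_signal(self, rng):
        # With both conditions producing the same DC stack the class means
        # coincide exactly; with a window-invariant stack every centred row
        # is identically zero.
        dc = {}
        for s in ["s0", "s1", "s2"]:
            block = rng.standard_normal((4, 5))
            dc[(s, "a")] = block
            dc[(s, "b")] = block.copy()
        fs = assemble_features(dc, "a", "b", [f"n{i}" for i in range(5)])
        diff = fs.features[fs.labels == 1].mean(axis=0) - fs.features[
            fs.labels == -1
        ].mean(axis=0)
        assert np.abs(diff).max() < 1e-12

        flat = {}
        for s in ["s0", "s1"]:
            row = rng.standard_normal(5)
            flat[(s, "a")] = np.tile(row, (4, 1))
            flat[(s, "b")] = np.tile(row, (4, 1))
        fs2 = assemble_features(flat, "a", "b", [f"n{i}" for i in range(5)])
        assert np.abs(fs2.features).max() < 1e-12

    def test_missing_condition_named(self, rng):
        dc = _dc_map(rng, ["s0", "s1"], ["a", "b"])
        del dc[("s1", "b")]
        with pytest.raises(ValueError, match="s1"):
            assemble_features(dc, "a", "b", [f"n{i}" for i in range(5)])

    def test_tsv_roundtrip(self, tmp_path, rng):
        dc = _dc_map(rng, ["s0", "s1", "s2"], ["a", "b"])
        fs = assemble_features(dc, "a", "b", [f"n{i}" for i in range(5)])
        path = tmp_path / "features.tsv"
        fs.to_tsv(path)
        back = CentralityFeatureSet.from_tsv(path)
        np.testing.assert_allclose(back.features, fs.features, atol=1e-9)
        assert list(back.labels) == list(fs.labels)
        assert back.contrast == ("a", "b")


class TestAssembleOrdinal:
    def test_class_indices_follow_supplied_order(self, rng):
        dc = _dc_map(rng, ["s0", "s1", "s2"], ["low", "mid", "high"])
        fs = assemble_ordinal_features(
            dc, ["low", "mid", "high"], [f"n{i}" for i in range(5)]
        )
        assert fs.class_index is not None
        for ci, cond in enumerate(["low", "mid", "high"]):
            assert set(fs.class_index[fs.conditions == cond]) == {ci}
        for s in ["s0", "s1", "s2"]:
            rows = fs.features[fs.subject_ids == s]
            assert np.abs(rows.mean(axis=0)).max() < 1e-10

    def test_duplicate_conditions_rejected(self, rng):
        dc = _dc_map(rng, ["s0"], ["a", "b"])
        with pytest.raises(ValueError, match="duplicates"):
            assemble_ordinal_features(dc, ["a", "a"], ["n0"])
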