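"""Pixel clustering, mask arithmetic, feature extraction, clustering, gating."""

import numpy as np
import pytest
from scipy import ndimage
from sklearn.metrics import adjusted_rand_score

from scspamet import phenotyping as ph
from scspamet.io_formats import CellTable, ChannelPanel, IonImageStack, LabelMask

from conftest import make_cell_table


def two_population_stack(seed, h=24, w=24):
    """Pixels drawn from two well-separated Gaussians, left/right halves."""
    rng = np.random.default_rng(seed)
    data = np.empty((3, h, w))
    truth = np.zeros((h, w), dtype=int)
    truth[:, w // 2 :] = 1
    for c in range(3):
        mu = (c + 1.0, 10.0 * (c + 1.0))
        data[c] = np.where(truth == 0,
                           rng.normal(mu[0], 0.3, size=(h, w)),
                           rng.normal(mu[1], 0.3, size=(h, w)))
    data = np.abs(data)
    panel = ChannelPanel.from_names([f"mz_{i}" for i in range(3)], "metabolite",
                                    mz=[1.0, 2.0, 3.0])
    return IonImageStack(data, panel, 1.0), truth


class TestClusterPixels:
    def test_recovers_planted_populations(self):
        stack, truth = two_population_stack(0)
        planes, _ = ph.cluster_pixels([stack], downsample=4, resolution=0.3, seed=0)
        ari = adjusted_rand_score(truth.ravel(), planes[0].ravel())
        assert ari >= 0.9

    def test_downsample_one_keeps_sampled_labels(self):
        stack, _ = two_population_stack(1)
        planes, model = ph.cluster_pixels([stack], downsample=1, resolution=0.3, seed=0)
        np.testing.assert_array_equal(planes[0].ravel(), model.sampled_labels)

    def test_seed_deterministic(self):
        stack, _ = two_population_stack(2)
        a, _ = ph.cluster_pixels([stack], downsample=4, seed=7)
        b, _ = ph.cluster_pixels([stack], downsample=4, seed=7)
        np.testing.assert_array_equal(a[0], b[0])

    def test_assignment_matches_brute_force_majority_vote(self):
        stack, _ = two_population_stack(3, h=20, w=20)
        planes, model = ph.cluster_pixels([stack], downsample=4, k_assign=30, seed=0)
        X = stack.data.reshape(3, -1).T
        Xs = (X[:, model.kept_channels] - model.scaler_mean) / model.scaler_sd
        k = min(model.k_assign, len(model.sampled_features))
        assigned = np.setdiff1d(np.arange(400), model.sample_indices)
        for i in assigned[::7]:  # spot-check a spread of assigned pixels
            d = np.linalg.norm(model.sampled_features - Xs[i], axis=1)
            nearest = np.argsort(d, kind="stable")[:k]
            votes = np.bincount(model.sampled_labels[nearest],
                                minlength=model.sampled_labels.max() + 1)
            assert planes[0].ravel()[i] in np.nonzero(votes == votes.max())[0]

    def test_constant_channel_dropped_with_warning(self):
        stack, _ = two_population_stack(4)
        stack.data[1] = 2.0
        with pytest.warns(UserWarning, match="constant channel"):
            planes, model = ph.cluster_pixels([stack], downsample=2, seed=0)
        assert 1 not in model.kept_channels


class TestMakeCellMasks:
    def test_single_nucleus_expansion_matches_distance_oracle(self):
        labels = np.zeros((15, 15), dtype=np.int32)
        labels[6:9, 6:9] = 1  # 3x3 nucleus
        whole, cyto = ph.make_cell_masks(LabelMask(labels, 1.0))
        # oracle: pixels within Euclidean distance 2 of the nucleus
        dist = ndimage.distance_transform_edt(labels == 0)
        np.testing.assert_array_equal(whole.labels > 0, dist <= 2)
        np.testing.assert_array_equal(cyto.labels > 0, (dist <= 2) & (labels == 0))

    def test_collision_split_at_equidistance(self):
        labels = np.zeros((9, 20), dtype=np.int32)
        labels[3:6, 3:6] = 1
        labels[3:6, 9:12] = 2  # 3 px gap
        whole, _ = ph.make_cell_masks(LabelMask(labels, 1.0))
        # brute-force nearest-nucleus assignment oracle
        d1 = ndimage.distance_transform_edt(labels != 1)
        d2 = ndimage.distance_transform_edt(labels != 2)
        grown = whole.labels
        covered = grown > 0
        assert not np.any((grown == 1) & (d2 < d1))
        assert not np.any((grown == 2) & (d1 < d2))
        assert np.all(np.minimum(d1, d2)[covered] <= 2)

    def test_cyto_disjoint_from_nuclei(self, rng):
        labels = np.zeros((30, 30), dtype=np.int32)
        for k, (r, c) in enumerate(rng.integers(4, 26, size=(6, 2)), start=1):
            labels[r - 1 : r + 2, c - 1 : c + 2] = k
        nuc = LabelMask(labels, 1.0)
        _, cyto = ph.make_cell_masks(nuc)
        assert not np.any((cyto.labels > 0) & (nuc.labels > 0))

    def test_maxproj_mode_falls_back_with_warning(self, rng):
        labels = np.zeros((10, 10), dtype=np.int32)
        labels[4:6, 4:6] = 1
        panel = ChannelPanel.from_names(["a", "b"], "protein")
        from scspamet.io_formats import MarkerImageStack
        stack = MarkerImageStack(rng.uniform(0, 1, (2, 10, 10)), panel, 1.0)
        with pytest.warns(UserWarning, match="falling back"):
            whole, _ = ph.make_cell_masks(
                LabelMask(labels, 1.0), stack, ["a"], mode="maxproj_minus_nuclei"
            )
        assert whole.labels.max() == 1


class TestExtractCellFeatures:
    def test_one_pixel_cell(self):
        labels = np.zeros((5, 5), dtype=np.int32)
        labels[2, 3] = 1
        panel = ChannelPanel.from_names(["a"], "protein")
        from scspamet.io_formats import MarkerImageStack
        data = np.arange(25, dtype=float).reshape(1, 5, 5)
        t = ph.extract_cell_features(LabelMask(labels, 1.0),
                                     [MarkerImageStack(data, panel, 1.0)])
        assert t.df["a"].iloc[0] == 13.0
        assert t.df["centroid_x_um"].iloc[0] == pytest.approx(3.5)
        assert t.df["centroid_y_um"].iloc[0] == pytest.approx(2.5)

    def test_uniform_image_every_mean_equals_value(self, rng):
        labels = rng.integers(0, 5, size=(20, 20)).astype(np.int32)
        panel = ChannelPanel.from_names(["a"], "protein")
        from scspamet.io_formats import MarkerImageStack
        stack = MarkerImageStack(np.full((1, 20, 20), 6.25), panel, 1.0)
        t = ph.extract_cell_features(LabelMask(labels, 1.0), [stack])
        np.testing.assert_allclose(t.df["a"], 6.25)

    def test_matches_brute_force_label_means(self, rng):
        labels = rng.integers(0, 8, size=(25, 25)).astype(np.int32)
        panel = ChannelPanel.from_names(["a", "b"], "protein")
        from scspamet.io_formats import MarkerImageStack
        stack = MarkerImageStack(rng.uniform(0, 10, (2, 25, 25)), panel, 1.0)
        t = ph.extract_cell_features(LabelMask(labels, 1.0), [stack])
        for _, row in t.df.iterrows():
            sel = labels == row["cell_id"]
            assert row["a"] == pytest.approx(stack.data[0][sel].mean())
            assert row["b"] == pytest.approx(stack.data[1][sel].mean())

    def test_shape_mismatch_rejected(self, rng):
        labels = np.ones((5, 5), dtype=np.int32)
        panel = ChannelPanel.from_names(["a"], "protein")
        from scspamet.io_formats import MarkerImageStack
        stack = MarkerImageStack(rng.uniform(0, 1, (1, 6, 6)), panel, 1.0)
        with pytest.raises(ValueError, match="does not match"):
            ph.extract_cell_features(LabelMask(labels, 1.0), [stack])


class TestClusterCells:
    def _two_type_table(self, rng, n=200):
        types = rng.integers(0, 2, size=n)
        X = np.where(types[:, None] == 0,
                     rng.normal(1.0, 0.2, size=(n, 4)),
                     rng.normal(6.0, 0.2, size=(n, 4)))
        return make_cell_table(rng.uniform(0, 100, (n, 2)),
                               **{f"p{i}": X[:, i] for i in range(4)}), types

    def test_disjoint_profiles_recovered(self, rng):
        t, types = self._two_type_table(rng)
        labels = ph.cluster_cells(t, [f"p{i}" for i in range(4)],
                                  resolution=0.3, seed=0)
        assert adjusted_rand_score(types, labels) >= 0.95

    def test_low_resolution_gives_one_cluster(self, rng):
        # on a connected neighbour graph the resolution -> 0 limit merges all
        X = rng.normal(0.0, 1.0, size=(150, 4))
        t = make_cell_table(rng.uniform(0, 100, (150, 2)),
                            **{f"p{i}": X[:, i] for i in range(4)})
        labels = ph.cluster_cells(t, [f"p{i}" for i in range(4)],
                                  resolution=1e-4, seed=0)
        assert labels.max() == 0

    def test_seed_deterministic(self, rng):
        t, _ = self._two_type_table(rng)
        a = ph.cluster_cells(t, [f"p{i}" for i in range(4)], seed=3)
        b = ph.cluster_cells(t, [f"p{i}" for i in range(4)], seed=3)
        np.testing.assert_array_equal(a, b)

    def test_batch_hook_contract(self, rng):
        t, _ = self._two_type_table(rng, n=60)
        t.df["patient_id"] = np.repeat(["a", "b"], 30)
        calls = {}

        def hook(X, batches):
            calls["shape"] = X.shape
            return X

        ph.cluster_cells(t, [f"p{i}" for i in range(4)], seed=0,
                         batch_key="patient_id", batch_hook=hook)
        assert calls["shape"] == (60, 4)

    def test_small_n_reduces_k_with_warning(self, rng):
        t, _ = self._two_type_table(rng, n=10)
        with pytest.warns(UserWarning, match="reducing k"):
            ph.cluster_cells(t, [f"p{i}" for i in range(4)], k=15, seed=0)


class TestGatePositive:
    def _bimodal_table(self, rng, n=2000, mu=(1.0, 5.0), sigma=0.1):
        half = n // 2
        x = np.concatenate([rng.normal(mu[0], sigma, half),
                            rng.normal(mu[1], sigma, n - half)])
        truth = np.concatenate([np.zeros(half, bool), np.ones(n - half, bool)])
        order = rng.permutation(n)
        t = make_cell_table(rng.uniform(0, 100, (n, 2)), cd31=np.abs(x[order]))
        return t, truth[order]

    def test_well_separated_mixture_high_accuracy(self):
        rng = np.random.default_rng(0)
        t, truth = self._bimodal_table(rng)
        gate = ph.gate_positive(t, "cd31", seed=0)
        acc = np.mean(gate.positive == truth)
        assert acc >= 0.99
        assert 2.0 < gate.threshold < 4.0

    def test_all_identical_rejected(self, rng):
        t = make_cell_table(rng.uniform(0, 10, (25, 2)), cd31=np.full(25, 2.0))
        with pytest.raises(ValueError, match="not bimodal"):
            ph.gate_positive(t, "cd31", seed=0)

    def test_component_order_invariance(self):
        # the gate depends only on the fitted density, not on component ids:
        # different seeds (hence possibly swapped component order) agree
        rng = np.random.default_rng(1)
        t, _ = self._bimodal_table(rng, n=500)
        a = ph.gate_positive(t, "cd31", seed=0)
        b = ph.gate_positive(t, "cd31", seed=99)
        np.testing.assert_array_equal(a.positive, b.positive)
        assert a.component_means[0] < a.component_means[1]

    def test_threshold_monotone_in_high_mean(self):
        rng = np.random.default_rng(2)
        thresholds = []
        for mu_high in (4.0, 6.0, 8.0):
            t, _ = self._bimodal_table(np.random.default_rng(5), n=1000,
                                       mu=(1.0, mu_high))
            thresholds.append(ph.gate_positive(t, "cd31", seed=0).threshold)
        assert thresholds[0] < thresholds[1] < thresholds[2]

    def test_too_few_cells_rejected(self, rng):
        t = make_cell_table(rng.uniform(0, 10, (5, 2)), cd31=rng.uniform(0, 1, 5))
        with pytest.raises(ValueError, match="20 cells"):
            ph.gate_positive(t, "cd31", seed=0)
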