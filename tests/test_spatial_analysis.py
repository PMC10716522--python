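"""Neighbour graphs, competition ratios, gradients, spatial signatures."""

import numpy as np
import pandas as pd
import pytest

from scspamet import spatial_analysis as sa
from scspamet import synthetic_data as sd
from scspamet.io_formats import CellTable, LabelMask

from conftest import make_cell_table


class TestBuildGraph:
    def test_radius_boundary_inside(self):
        t = make_cell_table([[0.0, 0.0], [19.0, 0.0]])
        g = sa.build_graph(t, mode="radius", radius_um=20.0)
        assert list(g.neighbors[0]) == [1]

    def test_radius_boundary_outside(self):
        t = make_cell_table([[0.0, 0.0], [21.0, 0.0]])
        g = sa.build_graph(t, mode="radius", radius_um=20.0)
        assert list(g.neighbors[0]) == []

    def test_radius_graph_equals_brute_force(self, rng):
        pts = rng.uniform(0, 300, size=(400, 2))
        g = sa.build_graph(make_cell_table(pts), mode="radius", radius_um=20.0)
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        for i in range(len(pts)):
            expected = sorted(j for j in range(len(pts))
                              if j != i and d[i, j] <= 20.0)
            assert list(g.neighbors[i]) == expected

    def test_contact_graph_equals_pairwise_dilation_oracle(self):
        tissue = sd.simulate_tissue(60, field_um=220.0, seed=3)
        g = sa.build_graph(tissue.cell_mask, mode="contact", dilation_px=1)
        from skimage.morphology import binary_dilation, disk
        labels = tissue.cell_mask.labels
        selem = disk(1)
        dil = {l: binary_dilation(labels == l, selem) for l in range(1, 61)}
        for i in range(60):
            expected = sorted(
                j for j in range(60)
                if j != i and np.any(dil[i + 1] & dil[j + 1])
            )
            assert list(g.neighbors[i]) == expected

    def test_no_self_edges_and_symmetry(self, rng):
        pts = rng.uniform(0, 100, size=(80, 2))
        g = sa.build_graph(make_cell_table(pts), mode="radius", radius_um=15.0)
        for i, nb in enumerate(g.neighbors):
            assert i not in nb
            for j in nb:
                assert i in g.neighbors[j]


class TestCompetitionRatio:
    def test_uniform_field_is_exactly_one(self):
        t = make_cell_table([[0, 0], [10, 0], [5, 8]], m=[4.0, 4.0, 4.0])
        g = sa.build_graph(t, mode="radius", radius_um=20.0)
        comp = sa.competition_ratio(t, g, ["m"])
        np.testing.assert_array_equal(comp.ratios["m"].to_numpy(), 1.0)

    def test_double_intensity_gives_ratio_two(self):
        t = make_cell_table([[0, 0], [10, 0], [5, 8]], m=[8.0, 4.0, 4.0])
        g = sa.build_graph(t, mode="radius", radius_um=20.0)
        comp = sa.competition_ratio(t, g, ["m"], aggregator="mean")
        assert comp.ratios["m"].iloc[0] == pytest.approx(2.0)

    def test_isolated_cell_is_missing(self):
        t = make_cell_table([[0, 0], [100, 100]], m=[1.0, 2.0])
        g = sa.build_graph(t, mode="radius", radius_um=20.0)
        comp = sa.competition_ratio(t, g, ["m"])
        assert comp.ratios["m"].isna().all()

    def test_invariant_under_channel_rescaling(self, rng):
        pts = rng.uniform(0, 150, size=(60, 2))
        vals = rng.uniform(1, 5, size=60)
        t1 = make_cell_table(pts, m=vals)
        t2 = make_cell_table(pts, m=vals * 37.5)
        g = sa.build_graph(t1, mode="radius", radius_um=25.0)
        r1 = sa.competition_ratio(t1, g, ["m"]).ratios
        r2 = sa.competition_ratio(t2, g, ["m"]).ratios
        pd.testing.assert_frame_equal(r1, r2)

    def test_median_aggregator_available(self):
        t = make_cell_table([[0, 0], [5, 0], [10, 0]], m=[6.0, 2.0, 10.0])
        g = sa.build_graph(t, mode="radius", radius_um=6.0)
        comp = sa.competition_ratio(t, g, ["m"], aggregator="median")
        # middle cell has neighbours 6 and 10 -> median 8
        assert comp.ratios["m"].iloc[1] == pytest.approx(2.0 / 8.0)

    def test_unknown_aggregator_rejected(self):
        t = make_cell_table([[0, 0], [5, 0]], m=[1.0, 1.0])
        g = sa.build_graph(t, mode="radius", radius_um=10.0)
        with pytest.raises(ValueError, match="aggregator"):
            sa.competition_ratio(t, g, ["m"], aggregator="mode")


class TestDistanceToPositive:
    def test_positive_cells_get_zero(self):
        t = make_cell_table([[0, 0], [30, 40]])
        d = sa.distance_to_positive(t, np.array([True, False]))
        assert d[0] == 0.0

    def test_pythagoras(self):
        t = make_cell_table([[0, 0], [30, 40]])
        d = sa.distance_to_positive(t, np.array([True, False]))
        assert d[1] == pytest.approx(50.0)

    def test_matches_brute_force(self, rng):
        pts = rng.uniform(0, 200, size=(150, 2))
        pos = rng.random(150) < 0.1
        pos[0] = True
        t = make_cell_table(pts)
        d = sa.distance_to_positive(t, pos)
        brute = np.sqrt(((pts[:, None] - pts[pos][None]) ** 2).sum(-1)).min(axis=1)
        np.testing.assert_allclose(d, brute, atol=1e-9)

    def test_cross_table_query(self, rng):
        ref = make_cell_table(rng.uniform(0, 400, size=(100, 2)))
        small = make_cell_table(rng.uniform(100, 200, size=(20, 2)))
        pos = np.ones(100, dtype=bool)
        d = sa.distance_to_positive(small, pos, reference_table=ref)
        assert d.shape == (20,)

    def test_no_positive_rejected(self):
        t = make_cell_table([[0, 0], [1, 1]])
        with pytest.raises(ValueError, match="no positive"):
            sa.distance_to_positive(t, np.array([False, False]))


class TestGradientProfile:
    def test_planted_decay_strictly_decreasing(self, noiseless_dataset):
        tissue, model, cells = noiseless_dataset
        ch = model.gradient_channels[0][0]
        d = cells.df["distance_to_vessel_um"].to_numpy()
        prof = sa.gradient_profile(d, cells, [ch], n_bins=20)
        vals = prof.normalized[ch].dropna().to_numpy()
        assert np.all(np.diff(vals) < 0)

    def test_normalization_hits_zero_and_one(self, noiseless_dataset):
        tissue, model, cells = noiseless_dataset
        ch = model.gradient_channels[0][0]
        d = cells.df["distance_to_vessel_um"].to_numpy()
        prof = sa.gradient_profile(d, cells, [ch], n_bins=20)
        vals = prof.normalized[ch].dropna()
        assert vals.min() == 0.0 and vals.max() == 1.0

    def test_constant_channel_flagged_flat(self, rng):
        pts = rng.uniform(0, 100, size=(50, 2))
        t = make_cell_table(pts, flat=np.full(50, 3.0))
        d = rng.uniform(0, 80, size=50)
        prof = sa.gradient_profile(d, t, ["flat"], n_bins=10)
        assert "flat" in prof.flat_channels
        assert np.nanmax(prof.normalized["flat"].to_numpy()) == 0.0

    def test_single_distance_rejected(self):
        t = make_cell_table([[0, 0], [1, 0]], m=[1.0, 2.0])
        with pytest.raises(ValueError, match="single distance"):
            sa.gradient_profile(np.zeros(2), t, ["m"])


class TestCorrelateWithDistance:
    def test_identity_channel_r_one(self, rng):
        pts = rng.uniform(0, 100, size=(40, 2))
        d = rng.uniform(0, 90, size=40)
        t = make_cell_table(pts, m=d)
        r = sa.correlate_with_distance(d, t, ["m"])
        assert r["m"] == pytest.approx(1.0)

    def test_planted_decay_strongly_negative(self, noiseless_dataset):
        tissue, model, cells = noiseless_dataset
        ch = model.gradient_channels[0][0]
        d = cells.df["distance_to_vessel_um"].to_numpy()
        r = sa.correlate_with_distance(d, cells, [ch])
        assert r[ch] <= -0.9

    def test_shuffled_channel_uncorrelated(self, rng):
        n = 400
        d = rng.uniform(0, 100, size=n)
        hits = 0
        for trial in range(50):
            t = make_cell_table(np.zeros((n, 2)), m=rng.permutation(d))
            r = sa.correlate_with_distance(d, t, ["m"])["m"]
            hits += abs(r) <= 2.0 / np.sqrt(n)
        assert hits >= 44  # ~95 % inside +-2/sqrt(n)

    def test_zero_variance_missing(self, rng):
        t = make_cell_table(rng.uniform(0, 10, size=(10, 2)), m=np.ones(10))
        r = sa.correlate_with_distance(np.arange(10.0), t, ["m"])
        assert np.isnan(r["m"])


class TestCompetitionVsDistance:
    def test_planted_sink_ratio_curves(self, noiseless_dataset):
        tissue, model, cells = noiseless_dataset
        ch, sink_type, g = model.competition_channels[0]
        graph = sa.build_graph(cells, mode="radius", radius_um=20.0)
        comp = sa.competition_ratio(cells, graph, [ch])
        d = cells.df["distance_to_vessel_um"].to_numpy()
        types = cells.df["cell_type"].to_numpy()
        curves = sa.competition_vs_distance(comp, d, types, sink_type, 2, n_bins=10)
        sink_curve = curves[sink_type][ch].dropna()
        other_curve = curves[2][ch].dropna()
        assert (sink_curve > 1.0).all()
        # non-sink cells are depleted or neutral, never above parity
        assert (other_curve <= 1.0 + 1e-12).all()

    def test_uniform_field_both_curves_one(self, rng):
        pts = rng.uniform(0, 150, size=(80, 2))
        types = np.repeat([1, 2], 40)
        t = make_cell_table(pts, m=np.full(80, 2.0))
        g = sa.build_graph(t, mode="radius", radius_um=30.0)
        comp = sa.competition_ratio(t, g, ["m"])
        d = rng.uniform(0, 100, size=80)
        curves = sa.competition_vs_distance(comp, d, types, 1, 2, n_bins=5)
        for ty in (1, 2):
            np.testing.assert_allclose(curves[ty]["m"].dropna(), 1.0)

    def test_matches_groupby_oracle(self, rng):
        pts = rng.uniform(0, 200, size=(100, 2))
        vals = rng.uniform(1, 5, size=100)
        types = rng.choice([1, 2], size=100)
        d = rng.uniform(0, 100, size=100)
        t = make_cell_table(pts, m=vals)
        g = sa.build_graph(t, mode="radius", radius_um=25.0)
        comp = sa.competition_ratio(t, g, ["m"])
        curves = sa.competition_vs_distance(comp, d, types, 1, 2, n_bins=20)
        edges = curves["bin_edges"]
        idx = np.clip(np.digitize(d, edges[1:-1]), 0, 19)
        r = comp.ratios["m"].to_numpy()
        for ty in (1, 2):
            for b in range(20):
                sel = (types == ty) & (idx == b)
                got = curves[ty]["m"].iloc[b]
                if sel.sum() == 0:
                    assert np.isnan(got)
                else:
                    expected = np.nanmean(r[sel]) if np.isfinite(r[sel]).any() else np.nan
                    np.testing.assert_allclose(got, expected, equal_nan=True)

    def test_absent_type_rejected(self, rng):
        t = make_cell_table(rng.uniform(0, 50, size=(10, 2)), m=np.ones(10))
        g = sa.build_graph(t, mode="radius", radius_um=30.0)
        comp = sa.competition_ratio(t, g, ["m"])
        with pytest.raises(ValueError, match="absent"):
            sa.competition_vs_distance(comp, np.arange(10.0), np.ones(10), 1, 99)


class TestNeighborhoodSignature:
    def test_vectors_sum_to_one(self, rng):
        pts = rng.uniform(0, 200, size=(120, 2))
        labels = rng.integers(0, 4, size=120)
        t = make_cell_table(pts)
        sig, _, _ = sa.neighborhood_signature(t, labels, radius_um=25.0, seed=0)
        np.testing.assert_allclose(sig.sum(axis=1), 1.0, atol=1e-12)

    def test_isolated_cell_one_hot(self):
        pts = np.array([[0.0, 0.0], [500.0, 500.0], [505.0, 500.0]])
        labels = np.array([2, 0, 1])
        t = make_cell_table(pts)
        sig, _, _ = sa.neighborhood_signature(t, labels, radius_um=25.0, seed=0)
        np.testing.assert_array_equal(sig[0], [0.0, 0.0, 1.0])

    def test_segregated_blocks_give_two_signatures(self, rng):
        # two label blocks far apart: compositions are block-pure
        a = rng.uniform(0, 80, size=(60, 2))
        b = rng.uniform(0, 80, size=(60, 2)) + [500.0, 0.0]
        pts = np.vstack([a, b])
        labels = np.repeat([0, 1], 60)
        t = make_cell_table(pts)
        _, sig_labels, _ = sa.neighborhood_signature(t, labels, radius_um=25.0,
                                                     resolution=0.5, seed=0)
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(labels, sig_labels) == 1.0

    def test_group_frequency_table(self, rng):
        pts = rng.uniform(0, 100, size=(40, 2))
        t = make_cell_table(pts)
        t.df["patient_id"] = np.repeat(["p1", "p2"], 20)
        _, _, freq = sa.neighborhood_signature(
            t, rng.integers(0, 2, 40), radius_um=25.0, seed=0, group_key="patient_id"
        )
        np.testing.assert_allclose(freq.sum(axis=1), 1.0)

    def test_invalid_radius_rejected(self, rng):
        t = make_cell_table(rng.uniform(0, 10, size=(5, 2)))
        with pytest.raises(ValueError, match="radius"):
            sa.neighborhood_signature(t, np.zeros(5, dtype=int), radius_um=0.0)
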