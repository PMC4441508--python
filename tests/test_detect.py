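"""Slice detector, anatomical prior, mean shift, ranking, seeds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rvlvcad import detect as dm
from rvlvcad.core import CTVolume
from rvlvcad.phantom import PhantomSpec, generate_phantom, truth_slice_box


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _disk_fixtures(rng, n=30, size=64):
    """Bright disks on noise: a fixture with known separability."""
    fixtures, negatives = [], []
    for _ in range(n):
        img = rng.normal(40.0, 15.0, (size, size))
        cx, cy = rng.integers(20, size - 20, 2)
        r = rng.integers(7, 11)
        X, Y = np.ogrid[:size, :size]
        img[(X - cx) ** 2 + (Y - cy) ** 2 <= r * r] = 330.0
        fixtures.append((img, {"RV": (cx - r, cy - r, cx + r, cy + r)}))
        negatives.append(rng.normal(40.0, 15.0, (size, size)))
    return fixtures, negatives


class TestTrainDetector:
    def test_training_is_deterministic(self):
        rng = np.random.default_rng(0)
        fixtures, negatives = _disk_fixtures(rng)
        m1 = dm.train_detector(fixtures, negatives, seed=7,
                               window_sizes_mm=(14, 18, 22))
        m2 = dm.train_detector(fixtures, negatives, seed=7,
                               window_sizes_mm=(14, 18, 22))
        assert np.array_equal(m1.chambers["RV"]["coef"],
                              m2.chambers["RV"]["coef"])
        assert m1.chambers["RV"]["intercept"] == m2.chambers["RV"]["intercept"]

    def test_separable_fixture_auc(self):
        """Bright disks vs pure noise: held-out separation must be near 1."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        fixtures, negatives = _disk_fixtures(rng, n=40)
        model = dm.train_detector(fixtures[:25], negatives[:25], seed=0,
                                  window_sizes_mm=(14, 18, 22))
        scores, labels = [], []
        for img, boxes in fixtures[25:]:
            x0, y0, x1, y1 = boxes["RV"]
            f = dm.window_features(img, [(x0, y0, x1 + 1, y1 + 1)])
            scores.append(dm.score_windows(model, "RV", f)[0])
            labels.append(1)
        for img in negatives[25:]:
            f = dm.window_features(img, [(20, 20, 40, 40)])
            scores.append(dm.score_windows(model, "RV", f)[0])
            labels.append(0)
        assert roc_auc_score(labels, scores) >= 0.99

    def test_swapped_labels_swap_models(self):
        rng = np.random.default_rng(2)
        fixtures, negatives = _disk_fixtures(rng, n=20)
        swapped = [(img, {"LV": box for box in boxes.values()})
                   for img, boxes in fixtures]
        m1 = dm.train_detector(fixtures, negatives, seed=3,
                               window_sizes_mm=(14, 18, 22))
        m2 = dm.train_detector(swapped, negatives, seed=3,
                               window_sizes_mm=(14, 18, 22))
        assert np.allclose(m1.chambers["RV"]["coef"],
                           m2.chambers["LV"]["coef"])

    def test_zero_variance_features_rejected(self):
        img = np.full((64, 64), 100.0)
        with pytest.raises(ValueError, match="degenerate|zero-variance"):
            dm.train_detector([(img, {"RV": (20, 20, 40, 40)})], [img],
                              seed=0, window_sizes_mm=(14,))

    def test_model_json_round_trip(self, detector_model):
        back = dm.DetectorModel.from_json(detector_model.to_json())
        assert back.window_sizes_mm == detector_model.window_sizes_mm
        for ch in detector_model.chambers:
            for k in ("coef", "mean", "scale"):
                assert np.allclose(back.chambers[ch][k],
                                   detector_model.chambers[ch][k])


# ---------------------------------------------------------------------------
# Detection on volumes
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def phantom_case():
    spec = PhantomSpec(noise_sigma=8.0, rng_seed=21)
    return generate_phantom(spec)


class TestDetectSlices:
    def test_pure_lung_volume_yields_nothing(self, detector_model):
        vol = CTVolume(np.full((96, 96, 6), -800.0, dtype=np.float32),
                       (0.7, 0.7, 1.0))
        assert dm.detect_slices(vol, detector_model) == []

    def test_mid_ventricular_slice_detected_with_iou(self, detector_model,
                                                     phantom_case):
        vol, truth = phantom_case
        dets = dm.detect_slices(vol, detector_model)
        k = vol.shape[2] // 2
        for chamber, mask in (("RV", truth.rv_mask), ("LV", truth.lv_mask)):
            tb = truth_slice_box(mask, k)
            tbox = (tb[0], tb[1], tb[2] + 1, tb[3] + 1)
            cands = [d for d in dets
                     if d.chamber == chamber and d.slice_index == k]
            assert cands, f"no {chamber} detection on mid slice"
            assert max(dm.box_iou(d.box, tbox) for d in cands) >= 0.5

    def test_detection_is_deterministic(self, detector_model, phantom_case):
        vol, _ = phantom_case
        d1 = dm.detect_slices(vol, detector_model)
        d2 = dm.detect_slices(vol, detector_model)
        assert [(d.slice_index, d.box, d.score) for d in d1] \
            == [(d.slice_index, d.box, d.score) for d in d2]


class TestAnatomyPrior:
    def _vol(self):
        return CTVolume(np.full((128, 128, 4), 300.0, dtype=np.float32),
                        (0.7, 0.7, 1.0))

    def test_oversized_box_removed(self):
        vol = self._vol()
        big = dm.Detection(1, (10, 10, 10 + int(200 / 0.7), 100), 1.0, "RV")
        assert dm.filter_by_anatomy_prior([big], vol) == []

    def test_marginal_box_removed(self):
        vol = self._vol()
        corner = dm.Detection(1, (0, 0, 20, 20), 1.0, "RV")  # outer margin
        assert dm.filter_by_anatomy_prior([corner], vol) == []

    def test_dark_box_removed(self):
        vol = CTVolume(np.full((128, 128, 4), -50.0, dtype=np.float32),
                       (0.7, 0.7, 1.0))
        dark = dm.Detection(1, (40, 40, 80, 80), 1.0, "RV")
        assert dm.filter_by_anatomy_prior([dark], vol) == []

    def test_phantom_truth_boxes_survive(self, phantom_case):
        vol, truth = phantom_case
        dets = []
        for k in range(20, 52, 4):
            for chamber, mask in (("RV", truth.rv_mask),
                                  ("LV", truth.lv_mask)):
                tb = truth_slice_box(mask, k)
                if tb:
                    dets.append(dm.Detection(
                        k, (tb[0], tb[1], tb[2] + 1, tb[3] + 1), 1.0, chamber))
        kept = dm.filter_by_anatomy_prior(dets, vol)
        assert len(kept) == len(dets)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 100), st.integers(0, 100),
                              st.integers(5, 80), st.integers(5, 80),
                              st.floats(-2, 5)), max_size=12))
    def test_filter_returns_subset(self, raw):
        vol = self._vol()
        dets = [dm.Detection(0, (x, y, min(x + w, 127), min(y + h, 127)),
                             s, "RV")
                for x, y, w, h, s in raw if w > 1 and h > 1]
        kept = dm.filter_by_anatomy_prior(dets, vol)
        assert all(d in dets for d in kept)


# ---------------------------------------------------------------------------
# Mean shift
# ---------------------------------------------------------------------------

def grid_mode_search(points, weights, bandwidth, lo, hi, step=0.5):
    """Independent oracle: exhaustive KDE evaluation on a regular grid."""
    axes = [np.arange(lo[d], hi[d] + step, step) for d in range(3)]
    G = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    d2 = ((G[:, None, :] - points[None, :, :]) ** 2).sum(axis=2)
    dens = (weights[None, :] * np.exp(-0.5 * d2 / bandwidth**2)).sum(axis=1)
    return G, dens


class TestMeanShift:
    def test_single_point_is_its_own_mode(self):
        [(mode, members)] = dm.mean_shift_cluster([[3.0, 4.0, 5.0]],
                                                  bandwidth=10.0)
        assert np.allclose(mode, [3.0, 4.0, 5.0])
        assert members == [0]

    def test_identical_points_one_cluster(self):
        pts = [[1.0, 2.0, 3.0]] * 5
        out = dm.mean_shift_cluster(pts, bandwidth=5.0)
        assert len(out) == 1
        assert out[0][1] == [0, 1, 2, 3, 4]
        assert np.allclose(out[0][0], [1.0, 2.0, 3.0])

    def test_two_groups_modes_near_weighted_means(self):
        rng = np.random.default_rng(0)
        g1 = rng.normal([0, 0, 0], 2.0, (8, 3))
        g2 = rng.normal([100, 0, 0], 2.0, (8, 3))
        pts = np.vstack([g1, g2])
        w = rng.uniform(0.5, 2.0, 16)
        out = dm.mean_shift_cluster(pts, w, bandwidth=20.0)
        assert len(out) == 2
        for mode, members in out:
            grp = pts[members]
            gw = w[members]
            assert np.linalg.norm(mode - gw @ grp / gw.sum()) < 1.0

    def test_modes_match_grid_oracle(self):
        """On random <=30-point sets in a 50 mm cube, ascent endpoints agree
        with exhaustive grid mode search within 1 mm."""
        rng = np.random.default_rng(42)
        for trial in range(5):
            n = rng.integers(5, 31)
            pts = rng.uniform(0, 50, (n, 3))
            w = rng.uniform(0.5, 2.0, n)
            h = 8.0
            clusters = dm.mean_shift_cluster(pts, w, bandwidth=h)
            G, dens = grid_mode_search(pts, w, h, [-5] * 3, [55] * 3)
            for mode, _ in clusters:
                near = np.linalg.norm(G - np.asarray(mode), axis=1) <= 1.0
                # the KDE value at the mode must match the best grid value
                # in its neighbourhood: the mode is a genuine local max
                d2 = ((np.asarray(mode) - pts) ** 2).sum(axis=1)
                mode_dens = float((w * np.exp(-0.5 * d2 / h**2)).sum())
                assert mode_dens >= dens[near].max() * (1 - 1e-3)

    def test_order_independence(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 50, (12, 3))
        out1 = dm.mean_shift_cluster(pts, bandwidth=10.0)
        perm = rng.permutation(12)
        out2 = dm.mean_shift_cluster(pts[perm], bandwidth=10.0)
        m1 = sorted(tuple(np.round(m, 6)) for m, _ in out1)
        m2 = sorted(tuple(np.round(m, 6)) for m, _ in out2)
        assert m1 == m2

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            dm.mean_shift_cluster([[0, 0, 0]], bandwidth=0.0)


# ---------------------------------------------------------------------------
# Ranking and seeds
# ---------------------------------------------------------------------------

def _cluster(chamber, n, score, mean_slice=10, mode=(50.0, 50.0, 10.0)):
    members = [dm.Detection(mean_slice + i % 3, (40, 40, 60, 60), score,
                            chamber) for i in range(n)]
    return dm.DetectionCluster(members=members, mode=mode,
                               rank_score=float("nan"), chamber=chamber)


class TestRankAndSelect:
    def test_single_cluster_selected(self):
        c = _cluster("RV", 1, 0.1)
        assert dm.rank_and_select([c])["RV"] is c

    def test_ranking_formula_persistence_beats_one_loud_box(self):
        # 10 members at 1.0 vs 1 member at 5.0; alpha=0.5: 10*sqrt(10) > 5
        a = _cluster("RV", 10, 1.0)
        b = _cluster("RV", 1, 5.0)
        best = dm.rank_and_select([a, b], alpha=0.5)
        assert best["RV"] is a
        assert a.rank_score == pytest.approx(10 * np.sqrt(10))
        assert b.rank_score == pytest.approx(5.0)

    def test_no_clusters_means_failure_flag_not_exception(self):
        best = dm.rank_and_select([])
        assert best == {"RV": None, "LV": None}

    def test_tie_breaks_to_more_cranial_cluster(self):
        a = _cluster("LV", 4, 1.0, mean_slice=20)
        b = _cluster("LV", 4, 1.0, mean_slice=5)
        assert dm.rank_and_select([a, b])["LV"] is b

    def test_pair_constraint_rejects_coincident_modes(self):
        rv = _cluster("RV", 10, 1.0, mode=(50.0, 50.0, 10.0))
        lv_same = _cluster("LV", 8, 1.0, mode=(51.0, 50.0, 10.0))
        lv_away = _cluster("LV", 2, 0.5, mode=(90.0, 50.0, 10.0))
        best = dm.rank_and_select([rv, lv_same, lv_away],
                                  min_mode_separation_mm=15.0,
                                  spacing=(1.0, 1.0, 1.0))
        assert best["RV"] is rv
        assert best["LV"] is lv_away


class TestSeeds:
    def test_seed_at_center_of_uniform_pool(self):
        vox = np.full((64, 64, 4), 300.0, dtype=np.float32)
        vol = CTVolume(vox, (1.0, 1.0, 1.0))
        c = dm.DetectionCluster(
            members=[dm.Detection(2, (20, 20, 40, 40), 1.0, "RV")],
            mode=(30.0, 30.0, 2.0), rank_score=1.0, chamber="RV")
        [seed] = dm.seeds_from_cluster(c, vol)
        assert seed.position == (30, 30, 2)

    def test_seed_snaps_to_bright_neighbour(self):
        vox = np.full((64, 64, 4), 300.0, dtype=np.float32)
        vox[30, 30, 2] = 80.0     # dark trabecula at the box centre
        vox[32, 31, 2] = 420.0    # bright pool voxel within radius 3
        vol = CTVolume(vox, (1.0, 1.0, 1.0))
        c = dm.DetectionCluster(
            members=[dm.Detection(2, (20, 20, 40, 40), 1.0, "RV")],
            mode=(30.0, 30.0, 2.0), rank_score=1.0, chamber="RV")
        [seed] = dm.seeds_from_cluster(c, vol)
        assert seed.position == (32, 31, 2)

    def test_seeds_sorted_by_slice_one_per_slice(self):
        vox = np.full((64, 64, 8), 300.0, dtype=np.float32)
        vol = CTVolume(vox, (1.0, 1.0, 1.0))
        members = [dm.Detection(k, (20, 20, 40, 40), s, "LV")
                   for k, s in ((5, 0.2), (3, 1.0), (5, 0.9), (1, 0.5))]
        c = dm.DetectionCluster(members=members, mode=(30, 30, 3),
                                rank_score=1.0, chamber="LV")
        seeds = dm.seeds_from_cluster(c, vol)
        assert [s.position[2] for s in seeds] == [1, 3, 5]
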