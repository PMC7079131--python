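"""Localization, drift correction, clustering, NN distances and KS tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial import cKDTree

from navclust import simulate as sim
from navclust import storm


def _table(xy, frame=None):
    xy = np.asarray(xy, dtype=float)
    return pd.DataFrame({
        "frame": np.zeros(len(xy), dtype=int) if frame is None else frame,
        "x_nm": xy[:, 0], "y_nm": xy[:, 1],
        "intensity": np.full(len(xy), 100.0),
        "precision_nm": np.full(len(xy), 5.0),
    })


class TestLocalization:
    def test_blank_movie_yields_empty_table(self, rng):
        movie = rng.poisson(100.0, size=(5, 32, 32)).astype(np.uint16)
        table = storm.localize_frames(movie, peak_mask=9, snr_min=6)
        assert len(table) == 0

    def test_constant_frames_are_skipped(self):
        movie = np.full((3, 32, 32), 7, dtype=np.uint16)
        assert len(storm.localize_frames(movie)) == 0

    def test_single_emitter_within_tenth_of_a_pixel(self):
        # one bright emitter at a known sub-pixel position, no noise
        yy, xx = np.mgrid[0:32, 0:32]
        x0, y0 = 15.3, 17.7
        frame = 100 + 500 * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * 1.2**2))
        movie = frame[None].astype(np.float64)
        # tiny deterministic ripple so the noise estimate is nonzero
        movie += np.indices(movie.shape)[2] % 2
        table = storm.localize_frames(movie, peak_mask=9, snr_min=6)
        assert len(table) == 1
        assert table["x_nm"].iloc[0] == pytest.approx(x0 * 100, abs=10.0)
        assert table["y_nm"].iloc[0] == pytest.approx(y0 * 100, abs=10.0)

    def test_two_emitters_in_one_window_are_discarded(self):
        yy, xx = np.mgrid[0:32, 0:32]
        frame = np.zeros((32, 32)) + 100.0
        for x0, y0 in [(14.0, 16.0), (17.0, 16.0)]:  # 3 px apart, one 9-px window
            frame += 500 * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * 1.0**2))
        movie = frame[None] + np.indices((1, 32, 32))[2] % 2
        table = storm.localize_frames(movie, peak_mask=9, snr_min=6)
        assert len(table) == 0

    def test_even_peak_mask_rejected(self, rng):
        movie = rng.poisson(100.0, size=(1, 16, 16)).astype(float)
        with pytest.raises(ValueError, match="odd"):
            storm.localize_frames(movie, peak_mask=8)

    def test_isolated_emitter_recall_and_precision(self):
        # pipeline-level invariant: >= 90% of isolated emitters localized,
        # with mean error below the nominal localization precision
        cfg = sim.LocSimConfig(field_size=(5000, 5000), n_clusters=0,
                               clustered_fraction=None, background_density=1.0,
                               loc_error_sd=0.0,
                               blinks_per_molecule=sim.DistSpec(20, 0), seed=4)
        movie, truth = sim.simulate_blinking_movie(
            cfg, psf_sigma=1.2, frames=60, snr=15, image_shape=(50, 50))
        table = storm.localize_frames(movie)
        n_iso = n_hit = 0
        errs = []
        for f, grp in truth.groupby("frame"):
            pts = grp[["x_nm", "y_nm"]].to_numpy()
            det = table.loc[table["frame"] == f, ["x_nm", "y_nm"]].to_numpy()
            for i, p in enumerate(pts):
                others = np.delete(pts, i, axis=0)
                if len(others) and np.min(np.linalg.norm(others - p, axis=1)) < 900:
                    continue
                if not (500 <= p[0] <= 4500 and 500 <= p[1] <= 4500):
                    continue
                n_iso += 1
                if len(det):
                    d = np.min(np.linalg.norm(det - p, axis=1))
                    if d < 150:
                        n_hit += 1
                        errs.append(d)
        assert n_iso > 50
        assert n_hit / n_iso >= 0.90
        assert np.mean(errs) < 12.0  # ~ sigma/sqrt(photons) at this SNR


class TestDriftCorrection:
    @staticmethod
    def _static_pattern(seed=9):
        cfg = sim.LocSimConfig(field_size=(4000, 4000), n_clusters=60,
                               molecules_per_cluster=sim.DistSpec(10, 0),
                               cluster_radius=sim.DistSpec(10, 0),
                               clustered_fraction=0.8, loc_error_sd=5.0, seed=seed)
        table, _ = sim.simulate_localization_pattern(cfg)
        return table

    def test_zero_drift_estimated_near_zero(self):
        table = self._static_pattern()
        _, drift = storm.drift_correct(table, n_bins=6, hist_bin_nm=20.0)
        assert drift[["dx_nm", "dy_nm"]].abs().to_numpy().max() <= 10.0  # half a pixel

    def test_linear_drift_slope_recovered_within_ten_percent(self):
        table = self._static_pattern()
        rate = 0.05  # nm per frame over 10000 frames
        drifted = table.assign(x_nm=table["x_nm"] + rate * table["frame"])
        _, drift = storm.drift_correct(drifted, n_bins=8)
        slope = np.polyfit(drift["frame_center"], drift["dx_nm"], 1)[0]
        assert slope == pytest.approx(rate, rel=0.10)

    def test_single_bin_request_rejected(self):
        table = self._static_pattern()
        with pytest.raises(ValueError, match="n_bins"):
            storm.drift_correct(table, n_bins=1)

    def test_sparse_bins_suggest_fewer(self):
        table = self._static_pattern().head(30)
        with pytest.raises(ValueError, match="fewer bins"):
            storm.drift_correct(table, n_bins=10)


class TestClusterDetection:
    def test_identical_points_single_zero_radius_cluster(self):
        table = _table(np.tile([[100.0, 200.0]], (10, 1)))
        cs = storm.detect_clusters(table, eps=20, min_pts=3)
        assert len(cs.clusters) == 1
        assert cs.clusters["radius_nm"].iloc[0] == 0.0
        assert cs.percent_clustered == 100.0

    def test_two_planted_clusters_recovered(self):
        rng = np.random.default_rng(5)
        a = rng.normal([200, 200], 8, size=(50, 2))
        b = rng.normal([700, 200], 8, size=(50, 2))
        bg = rng.uniform(0, 900, size=(5, 2))
        cs = storm.detect_clusters(_table(np.vstack([a, b, bg])), eps=20, min_pts=3)
        assert len(cs.clusters) == 2
        truth = np.r_[np.zeros(50), np.ones(50), np.full(5, -1)]
        found = cs.assignments[:100]
        # member recall >= 95% per planted cluster (up to label permutation)
        for t in (0, 1):
            ids, counts = np.unique(found[truth[:100] == t], return_counts=True)
            assert counts.max() >= 47

    def test_planted_clustered_fraction_recovered(self):
        cfg = sim.LocSimConfig(clustered_fraction=0.4,
                               blinks_per_molecule=sim.DistSpec(1.0, 0), seed=12)
        table, truth = sim.simulate_localization_pattern(cfg)
        cs = storm.detect_clusters(table, eps=20, min_pts=3)
        assert cs.percent_clustered == pytest.approx(40.0, abs=5.0)

    def test_permutation_invariance(self, rng):
        cfg = sim.LocSimConfig(seed=8)
        table, _ = sim.simulate_localization_pattern(cfg)
        perm = rng.permutation(len(table))
        cs1 = storm.detect_clusters(table, eps=20, min_pts=3)
        cs2 = storm.detect_clusters(table.iloc[perm].reset_index(drop=True),
                                    eps=20, min_pts=3)
        assert cs1.percent_clustered == pytest.approx(cs2.percent_clustered)
        # assignments agree up to relabeling
        a, b = cs1.assignments[perm], cs2.assignments
        mapping = {}
        for x, y in zip(a, b):
            if x == -1 or y == -1:
                assert x == y
            else:
                assert mapping.setdefault(x, y) == y

    def test_empty_table_gives_empty_clusterset(self):
        cs = storm.detect_clusters(_table(np.zeros((0, 2))))
        assert len(cs.clusters) == 0 and cs.percent_clustered == 0.0


class TestNearestNeighbors:
    def test_square_grid_spacing(self):
        g = np.mgrid[0:5, 0:5].reshape(2, -1).T * 30.0
        nn = storm.nearest_neighbor_distances(_table(g))
        np.testing.assert_allclose(nn.distances, 30.0)

    def test_matches_brute_force_exactly(self, rng):
        xy = rng.uniform(0, 1000, size=(200, 2))
        nn = storm.nearest_neighbor_distances(_table(xy))
        diff = xy[:, None, :] - xy[None, :, :]
        d2 = np.sqrt((diff**2).sum(-1))
        np.fill_diagonal(d2, np.inf)
        np.testing.assert_array_equal(nn.distances, d2.min(axis=1))

    def test_density_integrates_to_one(self, rng):
        xy = rng.uniform(0, 500, size=(300, 2))
        nn = storm.nearest_neighbor_distances(_table(xy), bin_width=2.0)
        assert np.sum(nn.density * np.diff(nn.bin_edges)) == pytest.approx(1.0)

    def test_dimer_tetramer_mixture_is_bimodal(self):
        table, truth = sim.simulate_oligomer_pattern(
            n_dimers=2500, n_tetramers=1250, seed=22)
        nn = storm.nearest_neighbor_distances(table, bin_width=2.0)
        dens = nn.density
        centers = 0.5 * (nn.bin_edges[:-1] + nn.bin_edges[1:])
        peaks = sorted(
            [(dens[i], centers[i]) for i in range(1, len(dens) - 1)
             if dens[i] >= dens[i - 1] and dens[i] > dens[i + 1]])[-2:]
        modes = sorted(c for _, c in peaks)
        assert abs(modes[0] - 6.0) <= 2.0  # within one 2-nm bin
        assert abs(modes[1] - 12.0) <= 2.0

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(ValueError):
            storm.nearest_neighbor_distances(_table(np.zeros((1, 2))))


class TestKSTest:
    def test_identical_samples_d_zero_p_one(self, rng):
        a = rng.normal(size=100)
        d, p = storm.ks_two_sample(a, a)
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_disjoint_supports_d_one(self):
        d, _ = storm.ks_two_sample([1, 2, 3], [10, 11, 12])
        assert d == 1.0

    def test_interleaved_example_one_third(self):
        d, _ = storm.ks_two_sample([1, 2, 3], [1.5, 2.5, 3.5])
        assert d == pytest.approx(1 / 3)

    def test_statistic_matches_brute_force_ecdf_walk(self, rng):
        for n_a, n_b in [(17, 31), (100, 100), (5, 200)]:
            a = np.sort(rng.normal(size=n_a))
            b = np.sort(rng.normal(0.3, size=n_b))
            d, _ = storm.ks_two_sample(a, b)
            grid = np.concatenate([a, b])
            brute = max(abs((a <= g).mean() - (b <= g).mean()) for g in grid)
            assert d == brute

    def test_statistic_matches_scipy(self, rng):
        a = rng.normal(size=500)
        b = rng.normal(0.2, size=400)
        d, p = storm.ks_two_sample(a, b)
        ref = stats.ks_2samp(a, b, method="asymp")
        assert d == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=0.2)

    def test_null_pvalues_uniform(self):
        # 500 replicates of equal-distribution samples: the p values should
        # themselves pass a KS test against U(0,1) at alpha = 0.01
        rng = np.random.default_rng(77)
        pvals = [storm.ks_two_sample(rng.normal(size=1000), rng.normal(size=1000))[1]
                 for _ in range(500)]
        stat = stats.kstest(pvals, "uniform")
        assert stat.pvalue > 0.01

    def test_permutation_pvalue_agrees_with_asymptotic(self, rng):
        a = rng.normal(size=150)
        b = rng.normal(0.4, size=150)
        _, p_asym = storm.ks_two_sample(a, b)
        _, p_perm = storm.ks_two_sample(a, b, n_permutations=400, seed=3)
        assert p_perm == pytest.approx(p_asym, abs=0.05)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            storm.ks_two_sample([], [1.0])


class TestRoiSummary:
    def test_single_roi_pool_is_identity(self, rng):
        xy = rng.uniform(0, 500, size=(200, 2))
        cs = storm.detect_clusters(_table(xy), eps=20, min_pts=3)
        nn = storm.nearest_neighbor_distances(_table(xy))
        s = storm.summarize_rois([cs], [nn])
        assert s["percent_clustered"] == pytest.approx(cs.percent_clustered)
        np.testing.assert_array_equal(s["nn_distances_nm"], nn.distances)

    def test_pooled_counts_are_sums(self):
        rng = np.random.default_rng(3)
        css, nns, total = [], [], 0
        for k in range(12):
            n = 50 + 10 * k
            xy = rng.uniform(0, 800, size=(n, 2))
            css.append(storm.detect_clusters(_table(xy), eps=25, min_pts=3))
            nns.append(storm.nearest_neighbor_distances(_table(xy)))
            total += n
        s = storm.summarize_rois(css, nns)
        assert s["n_localizations"] == total
        assert s["n_rois"] == 12
        assert s["n_clusters"] == sum(len(c.clusters) for c in css)

    def test_condition_compared_with_itself(self, rng):
        x = rng.exponential(10, size=400)
        d, p = storm.ks_two_sample(x, x)
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_roi_restriction_half_open(self):
        t = _table([[0.0, 0.0], [50.0, 50.0], [100.0, 100.0]])
        roi = {"x": 0.0, "y": 0.0, "width": 100.0, "height": 100.0}
        out = storm.restrict_to_roi(t, roi)
        assert len(out) == 2  # upper edge excluded
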