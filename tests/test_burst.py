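"""Otsu segmentation, connected regions, burst selection, and morphology."""

import itertools

import numpy as np
import pytest

from emgcwt import (
    analyze_cycle_map,
    burst_metrics,
    connected_regions,
    highest_class_mask,
    otsu_multiclass,
    select_burst,
    weighted_centroid,
)

from conftest import make_cycle_map


def brute_force_otsu_boundaries(values, n_classes=4, bins=64):
    """Exhaustive O(bins^3) maximizer of between-class variance (oracle)."""
    v = np.asarray(values, dtype=float).ravel()
    edges = np.linspace(0.0, v.max(), bins + 1)
    counts, _ = np.histogram(v, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = counts / counts.sum()
    cw = np.concatenate(([0.0], np.cumsum(w)))
    cm = np.concatenate(([0.0], np.cumsum(w * centers)))

    def score(i, j):
        W = cw[j] - cw[i]
        M = cm[j] - cm[i]
        return M * M / W if W > 0 else 0.0

    best, best_b = -np.inf, None
    for b in itertools.combinations(range(1, bins), n_classes - 1):
        cuts = (0,) + b + (bins,)
        s = sum(score(cuts[c], cuts[c + 1]) for c in range(n_classes))
        if s > best:
            best, best_b = s, b
    return np.array(best_b), edges


def mixture_values(rng, n=4000):
    comps = [
        rng.normal(loc, scale, size=n // 4)
        for loc, scale in ((1.0, 0.3), (4.0, 0.5), (8.0, 0.7), (14.0, 1.0))
    ]
    v = np.concatenate(comps)
    return np.clip(v, 0.0, None)


class TestOtsu:
    def test_point_masses_split_between_modes(self):
        v = np.repeat([0.0, 10.0, 20.0, 30.0], 50)
        thr = otsu_multiclass(v, n_classes=4).thresholds
        assert 0.0 < thr[0] < 10.0 < thr[1] < 20.0 < thr[2] < 30.0

    def test_bimodal_two_class(self):
        v = np.concatenate([np.zeros(90), np.ones(10)])
        thr = otsu_multiclass(v, n_classes=2).thresholds
        assert thr.size == 1 and 0.0 < thr[0] < 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_search_on_64_bin_histograms(self, seed):
        rng = np.random.default_rng(seed)
        v = mixture_values(rng)
        res = otsu_multiclass(v, n_classes=4, bins=64)
        oracle_b, oracle_edges = brute_force_otsu_boundaries(v, 4, 64)
        np.testing.assert_allclose(res.thresholds, oracle_edges[oracle_b])

    @pytest.mark.parametrize("bins", [128, 512])
    def test_top_class_stable_across_bin_counts(self, bins):
        # the analysis only consumes the top class; its threshold and mask must
        # be robust to the histogram resolution
        rng = np.random.default_rng(42)
        v = mixture_values(rng)
        res = otsu_multiclass(v, n_classes=4, bins=bins)
        ref = otsu_multiclass(v, n_classes=4, bins=256)
        binwidth = v.max() / min(bins, 256)
        assert abs(res.thresholds[-1] - ref.thresholds[-1]) <= 2 * binwidth
        agree = np.mean((v > res.thresholds[-1]) == (v > ref.thresholds[-1]))
        assert agree > 0.99

    def test_matches_skimage_partition(self):
        """Cross-check the optimal histogram partition against scikit-image."""
        skfilters = pytest.importorskip("skimage.filters")
        rng = np.random.default_rng(3)
        v = mixture_values(rng)
        v[0] = 0.0  # pin the range so both tools bin over [0, max]
        bins = 128
        res = otsu_multiclass(v, n_classes=4, bins=bins)
        sk_thr = skfilters.threshold_multiotsu(v, classes=4, nbins=bins)
        mine = np.searchsorted(res.bin_edges, res.thresholds)
        # skimage thresholds are bin centers; recover their boundary indices
        theirs = np.searchsorted(res.bin_edges, sk_thr, side="right")
        np.testing.assert_array_equal(mine, theirs)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            otsu_multiclass(np.full(100, 5.0), n_classes=4)
        with pytest.raises(ValueError):
            otsu_multiclass(np.array([0.0, 1.0, 2.0]), n_classes=4)


class TestMaskAndRegions:
    def test_hot_plateau_is_isolated(self):
        rng = np.random.default_rng(0)
        power = rng.uniform(0.0, 0.05, size=(40, 50))
        power[10:20, 15:25] = 1.0 + rng.uniform(0.0, 0.05, size=(10, 10))
        cmap = make_cycle_map(power)
        otsu = otsu_multiclass(cmap.power)
        mask = highest_class_mask(cmap, otsu)
        expected = np.zeros_like(power, dtype=bool)
        expected[10:20, 15:25] = True
        np.testing.assert_array_equal(mask, expected)

    def test_constant_map_rejected(self):
        cmap = make_cycle_map(np.full((10, 10), 2.0))
        with pytest.raises(ValueError):
            otsu_multiclass(cmap.power)

    def test_diagonal_blobs_are_separate_under_4_connectivity(self):
        mask = np.zeros((6, 6), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        power = np.ones((6, 6))
        assert len(connected_regions(mask, power, connectivity=1)) == 2
        assert len(connected_regions(mask, power, connectivity=2)) == 1

    def test_solid_block_single_region(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:7, 3:8] = True
        regions = connected_regions(mask, np.ones((10, 10)))
        assert len(regions) == 1
        assert regions[0].area == 25

    def test_checkerboard_one_region_per_pixel(self):
        mask = np.indices((8, 8)).sum(axis=0) % 2 == 0
        regions = connected_regions(mask, np.ones((8, 8)))
        assert len(regions) == mask.sum()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            connected_regions(np.zeros((4, 4), dtype=bool), np.ones((4, 4)))


class TestSelection:
    def two_region_map(self):
        power = np.zeros((30, 40))
        power[5:10, 5:13] = 2.0  # area 40
        power[20:27, 30:31] = 5.0  # area 7, hotter
        return make_cycle_map(power)

    def test_max_area_and_max_power_criteria(self):
        cmap = self.two_region_map()
        regions = connected_regions(cmap.power > 1.0, cmap.power)
        assert select_burst(regions, "max_area").area == 40
        assert select_burst(regions, "max_mean_power").mean_power == pytest.approx(5.0)

    def test_tie_broken_by_lower_centroid_frequency(self):
        power = np.zeros((30, 40))
        power[4:6, 10:12] = 1.0
        power[20:22, 10:12] = 1.0  # identical area and power, higher rows
        regions = connected_regions(power > 0.5, power)
        chosen = select_burst(regions, "max_area")
        assert chosen.centroid_row == pytest.approx(4.5)

    def test_single_burst_concordance_of_criteria(self, short_session, settings):
        from emgcwt.pipeline import analyze_session

        cmap = analyze_session(short_session, settings)["first10"].cycle_map
        otsu = otsu_multiclass(cmap.power)
        regions = connected_regions(highest_class_mask(cmap, otsu), cmap.power)
        a = select_burst(regions, "max_area")
        b = select_burst(regions, "max_mean_power")
        assert (a.centroid_row, a.centroid_col) == (b.centroid_row, b.centroid_col)


class TestCentroidAndMetrics:
    def test_uniform_rectangle_geometric_centre(self):
        power = np.zeros((496, 401))
        power[90:101, 160:241] = 1.0  # 95-105 Hz, 40-60 %
        cmap = make_cycle_map(power)
        region = connected_regions(power > 0.5, power)[0]
        freq, pct = weighted_centroid(region, cmap)
        assert freq == pytest.approx(100.0)
        assert pct == pytest.approx(50.0)

    def test_single_pixel(self):
        power = np.zeros((496, 401))
        power[75, 100] = 3.0
        cmap = make_cycle_map(power)
        region = connected_regions(power > 0, power)[0]
        freq, pct = weighted_centroid(region, cmap)
        assert freq == pytest.approx(80.0)  # row 75 -> 5 + 75 Hz
        assert pct == pytest.approx(25.0)  # col 100 -> 25 %

    def test_three_pixel_hand_computation(self):
        power = np.zeros((496, 401))
        power[0, 0:3] = [1.0, 2.0, 3.0]
        cmap = make_cycle_map(power)
        region = connected_regions(power > 0, power)[0]
        _, pct = weighted_centroid(region, cmap)
        assert pct == pytest.approx(1.0 / 3.0)

    def test_matches_skimage_regionprops(self):
        """Cross-check centroid/area/mean against scikit-image regionprops."""
        skmeasure = pytest.importorskip("skimage.measure")
        rng = np.random.default_rng(9)
        power = rng.uniform(0.0, 1.0, size=(60, 80))
        mask = power > 0.8
        regions = connected_regions(mask, power)
        labels = skmeasure.label(mask, connectivity=1)
        props = {
            tuple(np.round(p.centroid_weighted, 9)): p
            for p in skmeasure.regionprops(labels, intensity_image=power)
        }
        for r in regions:
            key = tuple(np.round((r.centroid_row, r.centroid_col), 9))
            assert key in props
            p = props[key]
            assert r.area == p.area
            assert r.mean_power == pytest.approx(p.intensity_mean)

    def test_metrics_homogeneity(self):
        power = np.zeros((50, 60))
        power[10:15, 20:25] = 2.0
        cmap = make_cycle_map(power)
        region = connected_regions(power > 1.0, power)[0]
        m = burst_metrics(region, cmap)
        assert m.mean_power == pytest.approx(2.0)
        assert m.area_px == 25
        cmap2 = make_cycle_map(2.0 * power)
        m2 = burst_metrics(region, cmap2)
        assert m2.mean_power == pytest.approx(4.0)
        assert m2.main_frequency_hz == pytest.approx(m.main_frequency_hz)
        assert m2.area_px == m.area_px

    def test_zero_power_region_rejected(self):
        power = np.zeros((10, 10))
        mask = np.zeros((10, 10), dtype=bool)
        mask[2, 2] = True
        region = connected_regions(mask, power)[0]
        with pytest.raises(ValueError):
            weighted_centroid(region, make_cycle_map(power))

    def test_analyze_cycle_map_end_to_end(self):
        rng = np.random.default_rng(12)
        power = rng.uniform(0.0, 0.02, size=(496, 401))
        rr, cc = np.meshgrid(np.arange(496), np.arange(401), indexing="ij")
        power += np.exp(-((rr - 75) ** 2) / 200.0 - ((cc - 80) ** 2) / 800.0)
        m = analyze_cycle_map(make_cycle_map(power))
        assert abs(m.main_frequency_hz - 80.0) < 3.0  # row 75 -> 80 Hz
        assert m.area_px > 0
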