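"""Cycle extraction, percent-of-cycle remapping, averaging, and normalization."""

import numpy as np
import pytest

from emgcwt import (
    PERCENT_AXIS,
    FrequencyGrid,
    average_block,
    build_cycle_map,
    extract_cycle,
    normalize_conditions,
    remap_to_percent,
    scalogram,
)
from emgcwt.cyclemap import ScalogramSegment

from conftest import make_cycle_map

FS = 2048.0


def toy_scalogram(n_cols=2048, n_rows=30, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n_cols)
    grid = FrequencyGrid(np.arange(50.0, 50.0 + n_rows * 5.0, 5.0), FS)
    return scalogram(x, grid)


def segment(power):
    power = np.asarray(power, dtype=float)
    return ScalogramSegment(
        power=power,
        frequencies=np.arange(power.shape[0], dtype=float) + 5.0,
        times=np.arange(power.shape[1]) / FS,
    )


class TestExtractCycle:
    def test_column_selection_half_open(self):
        scal = toy_scalogram()
        seg = extract_cycle(scal, 100 / FS, 200 / FS)
        assert seg.power.shape[1] == 100
        np.testing.assert_array_equal(seg.power, scal.power[:, 100:200])

    def test_adjacent_cycles_partition_columns(self):
        scal = toy_scalogram()
        a = extract_cycle(scal, 0.0, 0.3)
        b = extract_cycle(scal, 0.3, 0.6)
        both = extract_cycle(scal, 0.0, 0.6)
        assert a.power.shape[1] + b.power.shape[1] == both.power.shape[1]
        np.testing.assert_array_equal(np.hstack([a.power, b.power]), both.power)

    def test_zero_length_and_out_of_span_rejected(self):
        scal = toy_scalogram()
        with pytest.raises(ValueError):
            extract_cycle(scal, 0.5, 0.5)
        with pytest.raises(ValueError):
            extract_cycle(scal, 0.9, 1.5)


class TestRemap:
    def test_node_aligned_input_is_exact(self):
        rng = np.random.default_rng(1)
        power = rng.uniform(0.1, 1.0, size=(16, 401))
        out = remap_to_percent(segment(power))
        np.testing.assert_allclose(out, power, atol=1e-9)

    def test_constant_reproduced(self):
        out = remap_to_percent(segment(np.full((8, 123), 3.25)))
        np.testing.assert_allclose(out, 3.25, rtol=1e-12)

    def test_linear_ramp_reproduced(self):
        m = 157
        ramp = np.tile(np.linspace(2.0, 7.0, m), (6, 1))
        out = remap_to_percent(segment(ramp))
        expected = np.tile(np.interp(PERCENT_AXIS, [0, 100], [2.0, 7.0]), (6, 1))
        np.testing.assert_allclose(out, expected, rtol=1e-6)

    def test_commutes_with_scalar_multiplication(self):
        rng = np.random.default_rng(2)
        power = rng.uniform(size=(10, 77))
        np.testing.assert_allclose(
            remap_to_percent(segment(5.0 * power)),
            5.0 * remap_to_percent(segment(power)),
            rtol=1e-12,
        )

    def test_row_and_grid_methods_agree(self):
        # smooth map: Gaussian bump in both axes
        r = np.arange(24)[:, None]
        c = np.arange(300)[None, :]
        power = np.exp(-((r - 12) ** 2) / 40.0 - ((c - 150) ** 2) / 4000.0)
        a = remap_to_percent(segment(power), method="rows")
        b = remap_to_percent(segment(power), method="grid")
        np.testing.assert_allclose(a, b, atol=1e-6 * power.max())

    def test_too_few_columns_rejected(self):
        with pytest.raises(ValueError):
            remap_to_percent(segment(np.ones((5, 3))))

    def test_output_clipped_nonnegative(self):
        power = np.zeros((4, 50))
        power[:, 25] = 1.0  # spike induces cubic undershoot
        assert np.all(remap_to_percent(segment(power)) >= 0.0)


class TestAverageBlock:
    def test_idempotent_on_identical_maps(self):
        m = np.random.default_rng(3).uniform(size=(6, 401))
        np.testing.assert_allclose(average_block([m] * 10), m, rtol=1e-14)

    def test_two_map_mean(self):
        z, two = np.zeros((4, 5)), np.full((4, 5), 2.0)
        np.testing.assert_array_equal(average_block([z, two]), np.ones((4, 5)))

    def test_bounded_by_pixelwise_max(self):
        rng = np.random.default_rng(4)
        maps = [rng.uniform(size=(7, 9)) for _ in range(10)]
        avg = average_block(maps)
        assert np.all(avg >= 0)
        assert np.all(avg <= np.max(np.stack(maps), axis=0) + 1e-15)

    def test_shape_mismatch_and_empty_rejected(self):
        with pytest.raises(ValueError):
            average_block([np.ones((2, 3)), np.ones((3, 2))])
        with pytest.raises(ValueError):
            average_block([])


class TestRemapAverageCommutation:
    def test_equal_length_cycles_commute(self):
        """remap-then-average equals average-then-remap at constant cadence.

        Segments are smooth (scalogram-like): the cubic overshoot that the zero
        clip removes is negligible there, unlike on white-noise worst cases.
        """
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(5)
        segs = [
            gaussian_filter(rng.uniform(0.1, 1.0, size=(12, 200)), sigma=(0, 3))
            for _ in range(10)
        ]
        path_a = average_block([remap_to_percent(segment(s)) for s in segs])
        path_b = remap_to_percent(segment(average_block(segs)))
        np.testing.assert_allclose(path_a, path_b, rtol=1e-6, atol=1e-9)

    def test_build_cycle_map_matches_per_cycle_path(self):
        scal = toy_scalogram(n_cols=4096)
        cycles = [(i * 0.25, (i + 1) * 0.25) for i in range(6)]
        cmap = build_cycle_map(scal, cycles)
        manual = average_block(
            [remap_to_percent(extract_cycle(scal, t0, t1)) for t0, t1 in cycles]
        )
        assert cmap.n_cycles_averaged == 6
        np.testing.assert_allclose(cmap.power, manual, rtol=1e-6, atol=1e-12)


class TestNormalizeConditions:
    def make_maps(self):
        rng = np.random.default_rng(6)
        return {
            "73": make_cycle_map(rng.uniform(size=(10, 11))),
            "100": make_cycle_map(rng.uniform(size=(10, 11))),
            "133": make_cycle_map(8.0 * np.ones((10, 11)) / 110.0),
        }

    def test_reference_sums_to_unity(self):
        out = normalize_conditions(self.make_maps(), "133")
        assert out["133"].power.sum() == pytest.approx(1.0)
        assert out["73"].normalized_to == "133"

    def test_ratios_preserved(self):
        maps = self.make_maps()
        r = maps["73"].power.sum() / maps["100"].power.sum()
        out = normalize_conditions(maps, "133")
        assert out["73"].power.sum() / out["100"].power.sum() == pytest.approx(r)

    def test_second_pass_is_identity(self):
        out = normalize_conditions(self.make_maps(), "133")
        out2 = normalize_conditions(out, "133")
        np.testing.assert_allclose(out2["73"].power, out["73"].power, rtol=1e-12)

    def test_missing_or_zero_reference_rejected(self):
        maps = self.make_maps()
        with pytest.raises(ValueError):
            normalize_conditions(maps, "166")
        maps["133"].power[:] = 0.0
        with pytest.raises(ValueError):
            normalize_conditions(maps, "133")
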