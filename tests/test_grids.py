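import numpy as np
import pytest

from tumortwin.grids import (
    VoxelGrid,
    adc_to_cellularity,
    block_downsample,
    cellularity_to_adc,
    compute_auc_map,
    compute_carrying_capacity,
    estimate_adc_min,
    summarize,
)


class TestCarryingCapacity:
    def test_hand_value_unit_voxel(self):
        # 1 mm^3 voxel, 10 um cells, packing 1 -> 1 / (pi/6 * 0.01^3)
        theta = compute_carrying_capacity((1, 1, 1), 10.0, 1.0)
        assert theta == pytest.approx(1.90986e6, rel=1e-5)

    def test_volume_scaling(self):
        base = compute_carrying_capacity((1, 1, 1))
        assert compute_carrying_capacity((2, 2, 2)) == pytest.approx(8 * base)

    @pytest.mark.parametrize("bad", [((0, 1, 1), 10, 0.7), ((1, 1, 1), -5, 0.7), ((1, 1, 1), 10, 1.5)])
    def test_invalid_inputs(self, bad):
        with pytest.raises(ValueError):
            compute_carrying_capacity(*bad)


class TestADCConversion:
    theta = 1e6
    adc_w, adc_min = 3.0e-3, 0.8e-3

    def test_linear_endpoints_and_midpoint(self):
        mask = np.ones((2, 2, 1), bool)
        adc = np.full(mask.shape, self.adc_w)
        adc[0, 0, 0] = self.adc_min
        adc[0, 1, 0] = 0.5 * (self.adc_w + self.adc_min)
        n = adc_to_cellularity(adc, mask, self.adc_w, self.adc_min, self.theta)
        assert n[0, 0, 0] == pytest.approx(self.theta)
        assert n[0, 1, 0] == pytest.approx(self.theta / 2)
        assert n[1, 1, 0] == pytest.approx(0.0)

    def test_outside_mask_zero_and_clipping(self):
        mask = np.zeros((2, 1, 1), bool)
        mask[0] = True
        adc = np.array([[[0.1e-3]], [[0.1e-3]]])  # below adc_min -> clipped to theta
        n = adc_to_cellularity(adc, mask, self.adc_w, self.adc_min, self.theta)
        assert n[0, 0, 0] == self.theta
        assert n[1, 0, 0] == 0.0

    def test_monotone_decreasing_in_adc(self, rng):
        mask = np.ones((8, 1, 1), bool)
        adc = np.sort(rng.uniform(self.adc_min, self.adc_w, size=(8, 1, 1)), axis=0)
        n = adc_to_cellularity(adc, mask, self.adc_w, self.adc_min, self.theta)
        assert np.all(np.diff(n.ravel()) <= 1e-12)
        assert np.all((n >= 0) & (n <= self.theta))

    def test_round_trip_on_mask(self, rng):
        mask = rng.random((4, 4, 2)) > 0.4
        cells = rng.uniform(0, self.theta, size=mask.shape) * mask
        adc = cellularity_to_adc(cells, mask, self.adc_w, self.adc_min, self.theta)
        back = adc_to_cellularity(adc, mask, self.adc_w, self.adc_min, self.theta)
        np.testing.assert_allclose(back[mask], cells[mask], rtol=0, atol=self.theta * 1e-12)

    def test_inverse_hand_values(self):
        mask = np.ones((1, 1, 1), bool)
        assert cellularity_to_adc(np.full(mask.shape, self.theta / 2), mask, self.adc_w, self.adc_min, self.theta)[
            0, 0, 0
        ] == pytest.approx(0.5 * (self.adc_w + self.adc_min))
        assert cellularity_to_adc(np.zeros(mask.shape), mask, self.adc_w, self.adc_min, self.theta)[
            0, 0, 0
        ] == pytest.approx(self.adc_w)

    def test_degenerate_adc_window_rejected(self):
        with pytest.raises(ValueError):
            adc_to_cellularity(np.ones((1, 1, 1)), np.ones((1, 1, 1), bool), 1e-3, 1e-3, 1e6)

    def test_estimate_adc_min(self):
        masks = {"V1": np.array([[[True, False]]]), "V2": np.array([[[False, True]]])}
        adcs = {"V1": np.array([[[1.2e-3, 0.1e-3]]]), "V2": np.array([[[0.2e-3, 0.9e-3]]])}
        assert estimate_adc_min(adcs, masks) == pytest.approx(0.9e-3)


class TestAUCMap:
    def test_minmax_normalization_and_hand_value(self):
        mask = np.ones((2, 1, 1), bool)
        times = np.array([0.0, 1.0, 2.0])
        series = np.zeros((2, 1, 1, 3))
        series[0, 0, 0] = [1, 1, 1]  # trapezoid AUC = 2
        series[1, 0, 0] = [3, 3, 3]  # AUC = 6
        auc, ok = compute_auc_map(series, times, mask)
        assert ok
        assert auc[0, 0, 0] == pytest.approx(0.0)
        assert auc[1, 0, 0] == pytest.approx(1.0)

    def test_constant_zero_series_flagged(self):
        mask = np.ones((2, 2, 1), bool)
        auc, ok = compute_auc_map(np.zeros((2, 2, 1, 3)), np.arange(3.0), mask)
        assert not ok
        assert np.all(auc == 0)

    def test_needs_two_timepoints(self):
        with pytest.raises(ValueError):
            compute_auc_map(np.zeros((1, 1, 1, 1)), np.array([0.0]), np.ones((1, 1, 1), bool))


class TestSummarize:
    def test_zero_field(self):
        assert summarize(np.zeros((3, 3, 3)), 1e6, 8.0) == (0.0, 0.0)

    def test_hand_volume_count(self):
        # 10 voxels at capacity on a 2x2x4 mm grid -> 10 * 16 mm^3 = 0.16 mL
        cells = np.zeros((5, 5, 2))
        cells.ravel()[:10] = 1e6
        total, vol = summarize(cells, 1e6, 16.0, volume_fraction_threshold=0.01)
        assert total == pytest.approx(1e7)
        assert vol == pytest.approx(0.16)

    def test_total_invariant_under_permutation(self, rng):
        cells = rng.uniform(0, 1e5, size=(4, 4, 4))
        shuffled = rng.permutation(cells.ravel()).reshape(cells.shape)
        t1, _ = summarize(cells, 1e6, 1.0)
        t2, _ = summarize(shuffled, 1e6, 1.0)
        assert t1 == pytest.approx(t2)

    def test_linearity_of_totals(self, rng):
        a = rng.uniform(0, 1e5, size=(3, 3, 3))
        b = rng.uniform(0, 1e5, size=(3, 3, 3))
        assert summarize(a + b, 1e6, 1.0)[0] == pytest.approx(summarize(a, 1e6, 1.0)[0] + summarize(b, 1e6, 1.0)[0])


class TestVoxelGrid:
    def test_tumor_mask_must_be_inside_breast(self):
        breast = np.zeros((3, 3, 1), bool)
        breast[1, 1, 0] = True
        tumor = np.ones((3, 3, 1), bool)
        with pytest.raises(ValueError):
            VoxelGrid(spacing=(1, 1, 1), breast_mask=breast, tumor_masks={"V1": tumor})

    def test_flatten_unflatten_round_trip(self, rng):
        mask = rng.random((4, 3, 2)) > 0.5
        grid = VoxelGrid(spacing=(1, 1, 1), breast_mask=mask)
        vec = rng.random(grid.n_masked)
        np.testing.assert_array_equal(grid.flatten(grid.unflatten(vec)), vec)

    def test_block_downsample_mean(self):
        v = np.arange(8.0).reshape(2, 2, 2)
        out = block_downsample(v, (2, 2, 2))
        assert out.shape == (1, 1, 1)
        assert out[0, 0, 0] == pytest.approx(v.mean())
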