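"""3D tau-load segmentation: background, threshold, size filters, %tau."""

import numpy as np
import pytest

from taupet.ihc import (
    MicroStack,
    TauMask,
    component_extents_um,
    detect_somata,
    local_background_subtract,
    percentile_threshold,
    quantify_stack,
    remove_small_components,
    tau_volume_load,
)

VOX = (1.0, 0.35, 0.35)  # default anisotropic voxel size (z, y, x)


def stack_of(data, vox=VOX):
    return MicroStack(np.asarray(data), vox)


def mask_of(mask, vox=VOX):
    return TauMask(np.asarray(mask, bool), vox)


class TestBackgroundSubtraction:
    def test_constant_stack_maps_to_zero(self):
        out = local_background_subtract(stack_of(np.full((5, 60, 60), 500.0)), block_um=10)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-9)

    def test_bright_voxel_keeps_contrast(self):
        data = np.full((3, 120, 120), 100.0)
        data[1, 60, 60] = 5100.0
        out = local_background_subtract(stack_of(data), block_um=20)
        assert out.data[1, 60, 60] == pytest.approx(5000.0)
        assert np.abs(out.data[0]).max() == pytest.approx(0.0)

    def test_linear_ramp_residual_bounded_by_block_change(self):
        ny = 200
        ramp = np.tile(np.arange(ny, dtype=float), (1, ny, 1)).reshape(1, ny, ny)
        data = np.swapaxes(ramp, 1, 2) * 2.0  # 2 counts per voxel along y
        block_um = 14.0
        block_vox = block_um / VOX[1]
        out = local_background_subtract(stack_of(data), block_um=block_um)
        assert out.data.max() <= 2.0 * block_vox + 1e-9

    def test_block_too_small_errors(self):
        with pytest.raises(ValueError, match=">= 3 voxels"):
            local_background_subtract(stack_of(np.zeros((2, 50, 50))), block_um=0.5)

    def test_block_larger_than_stack_errors(self):
        with pytest.raises(ValueError, match="larger than"):
            local_background_subtract(stack_of(np.zeros((2, 10, 10))), block_um=100)


class TestPercentileThreshold:
    def test_distinct_values_select_exact_top_fraction(self):
        rng = np.random.default_rng(0)
        values = np.arange(1.0, 1001.0)
        rng.shuffle(values)
        out = percentile_threshold(stack_of(values.reshape(10, 10, 10)), q=80)
        assert out.mask.sum() == 200
        assert values.reshape(10, 10, 10)[out.mask].min() == 801.0

    def test_tiny_q_selects_everything(self):
        # q -> 0+ limit: the threshold collapses onto the minimum
        data = np.arange(1.0, 28.0).reshape(3, 3, 3)
        out = percentile_threshold(stack_of(data), q=1e-30)
        assert out.mask.all()

    def test_degenerate_constant_stack_flagged(self):
        out = percentile_threshold(stack_of(np.full((3, 3, 3), 7.0)), q=80)
        assert out.provenance["degenerate_constant_stack"]
        assert out.mask.all()

    def test_invalid_q_errors(self):
        with pytest.raises(ValueError):
            percentile_threshold(stack_of(np.zeros((2, 2, 2))), q=100)


class TestRemoveSmallComponents:
    def test_single_voxel_removed(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        assert not remove_small_components(mask_of(m)).mask.any()

    def test_axial_pair_is_subvolume_noise(self):
        # two stacked voxels span 2 um axially but hold ~0.25 um^3
        m = np.zeros((5, 5, 5), bool)
        m[1:3, 2, 2] = True
        assert not remove_small_components(mask_of(m)).mask.any()

    def test_lateral_line_kept(self):
        # 10 lateral voxels: 3.5 um long, volume 1.2 um^3
        m = np.zeros((3, 20, 20), bool)
        m[1, 5, 5:15] = True
        out = remove_small_components(mask_of(m))
        assert out.mask.sum() == 10

    def test_empty_mask_passthrough(self):
        m = np.zeros((3, 3, 3), bool)
        assert not remove_small_components(mask_of(m)).mask.any()

    def test_never_adds_voxels(self):
        rng = np.random.default_rng(0)
        m = rng.random((10, 20, 20)) > 0.7
        out = remove_small_components(mask_of(m))
        assert not np.any(out.mask & ~m)


class TestDetectSomata:
    def sphere_mask(self, diameter_um, shape=(20, 40, 40)):
        zz, yy, xx = np.meshgrid(
            *[(np.arange(n) - n / 2) * v for n, v in zip(shape, VOX)], indexing="ij"
        )
        r = diameter_um / 2.0
        return (zz**2 + yy**2 + xx**2) <= r**2

    def test_four_micron_sphere_is_one_soma(self):
        out = detect_somata(mask_of(self.sphere_mask(4.0)))
        assert out.n_somata == 1
        assert np.all(out.extents_um >= 3.0)

    def test_thin_sheet_is_not_a_soma_but_stays_in_mask(self):
        m = np.zeros((9, 60, 60), bool)
        m[4, 10:39, 10:39] = True  # ~10 x 10 um laterally, 1 um axially
        cleaned = remove_small_components(mask_of(m))
        assert cleaned.mask.sum() == m.sum()  # retained in the tau mask
        assert detect_somata(cleaned).n_somata == 0

    def test_empty_mask_zero_somata(self):
        assert detect_somata(mask_of(np.zeros((3, 3, 3)))).n_somata == 0

    def test_two_micron_sphere_rejected(self):
        out = detect_somata(mask_of(self.sphere_mask(2.4)))
        assert out.n_somata == 0


class TestComponentExtentsOracle:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_voxel_scan(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.random((12, 24, 24)) > 0.82
        labels, extents, volumes = component_extents_um(m, VOX)
        from scipy import ndimage

        assert labels.max() == extents.shape[0]
        for comp in range(1, labels.max() + 1):
            idx = np.argwhere(labels == comp)
            # independent oracle: bounding box from raw voxel coordinates
            span = idx.max(axis=0) - idx.min(axis=0) + 1
            np.testing.assert_allclose(extents[comp - 1], span * np.array(VOX))
            assert volumes[comp - 1] == pytest.approx(len(idx) * np.prod(VOX))
        # labelling itself cross-checked against 26-connected scipy label
        ref, n = ndimage.label(m, structure=np.ones((3, 3, 3)))
        assert n == labels.max()


class TestTauVolumeLoad:
    def test_mask_equals_roi_is_100(self):
        m = np.ones((3, 3, 3), bool)
        assert tau_volume_load(mask_of(m)).percent_tau == 100.0

    def test_half_roi(self):
        m = np.zeros((2, 2, 2), bool)
        m[0] = True
        assert tau_volume_load(mask_of(m)).percent_tau == 50.0

    def test_restricted_roi(self):
        m = np.zeros((2, 2, 2), bool)
        m[0, 0, 0] = True
        roi = np.zeros((2, 2, 2), bool)
        roi[0] = True
        assert tau_volume_load(mask_of(m), roi=roi).percent_tau == pytest.approx(25.0)

    def test_empty_roi_errors(self):
        with pytest.raises(ValueError, match="empty"):
            tau_volume_load(mask_of(np.ones((2, 2, 2))), roi=np.zeros((2, 2, 2), bool))


class TestPipelineInvariants:
    def test_filter_chain_never_adds_tau(self):
        rng = np.random.default_rng(1)
        data = rng.integers(0, 4000, (8, 64, 64)).astype(float)
        stack = stack_of(data)
        corrected = local_background_subtract(stack, block_um=10)
        mask0 = percentile_threshold(corrected)
        mask1 = remove_small_components(mask0)
        assert not np.any(mask1.mask & ~mask0.mask)
        somata = detect_somata(mask1)
        assert not np.any((somata.labels > 0) & ~mask1.mask)
        f0 = tau_volume_load(mask0).percent_tau
        f1 = tau_volume_load(mask1).percent_tau
        assert f1 <= f0

    def test_scale_consistency_of_physical_criteria(self):
        # the same physical object sampled twice as fine keeps its extent
        # classification: a 4 um sphere is a soma at both samplings
        for vox in [(1.0, 0.35, 0.35), (0.5, 0.7, 0.7)]:
            shape = tuple(int(round(12 / v)) for v in vox)
            zz, yy, xx = np.meshgrid(
                *[(np.arange(n) - n / 2) * v for n, v in zip(shape, vox)], indexing="ij"
            )
            sphere = (zz**2 + yy**2 + xx**2) <= 2.0**2
            out = detect_somata(TauMask(sphere, vox))
            assert out.n_somata == 1

    def test_quantify_stack_roundtrip(self):
        rng = np.random.default_rng(5)
        data = rng.integers(100, 300, (6, 64, 64)).astype(np.uint16)
        data[2:5, 20:40, 20:40] += 5000
        load, mask, somata = quantify_stack(stack_of(data), block_um=15)
        assert 0 <= load.percent_tau <= 100
        assert load.params["percentile"] == 80.0
        assert somata.n_somata >= 1
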