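"""Segmentation: thresholding, components, despeckling, ROI exclusion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from fmaquant.geometry import VoxelGeometry
from fmaquant.segment import (
    VesselMask,
    clean_mask,
    exclude_region,
    filter_small_components,
    label_components,
    rasterize_polygon_rois,
    segment_vessels,
)
from fmaquant.stack import ImageStack

GEOM = VoxelGeometry(dx=1, dy=1, dz=1)


def _stack(arr):
    return ImageStack({"green": arr}, GEOM)


class TestSegmentVessels:
    def test_binary_phantom_segments_exactly(self, binary_glom_phantom):
        stack, truth = binary_glom_phantom
        mask = segment_vessels(stack, method="fixed", manual_threshold=0)
        np.testing.assert_array_equal(mask.mask, truth.true_vessel_mask)

    def test_segmentation_idempotent_on_binary(self):
        img = (np.arange(27).reshape(3, 3, 3) % 2 * 200).astype(np.uint8)
        m1 = segment_vessels(_stack(img), method="fixed", manual_threshold=100)
        rendered = (m1.mask * 255).astype(np.uint8)
        m2 = segment_vessels(_stack(rendered), method="fixed", manual_threshold=100)
        np.testing.assert_array_equal(m1.mask, m2.mask)

    def test_all_zero_with_fixed_threshold_gives_empty(self):
        m = segment_vessels(_stack(np.zeros((3, 4, 4), np.uint8)),
                            method="fixed", manual_threshold=10)
        assert m.voxel_count == 0

    def test_otsu_on_constant_image_advises_fixed(self):
        with pytest.raises(ValueError, match="fixed"):
            segment_vessels(_stack(np.full((3, 4, 4), 7, np.uint8)))

    def test_threshold_outside_range_rejected(self):
        with pytest.raises(ValueError, match="dynamic range"):
            segment_vessels(_stack(np.zeros((2, 2, 2), np.uint8)),
                            method="fixed", manual_threshold=300)

    def test_threshold_recorded_in_provenance(self, small_glom_phantom):
        stack, _ = small_glom_phantom
        m = segment_vessels(stack)
        assert m.provenance[0]["method"] == "otsu"
        assert m.provenance[0]["threshold"] > 0


class TestComponents:
    def test_two_disjoint_tubes(self):
        mask = np.zeros((5, 10, 10), bool)
        mask[2, 2, 1:9] = True
        mask[2, 7, 1:9] = True
        lab = label_components(VesselMask(mask, GEOM), 26)
        assert lab.n_components == 2

    def test_corner_touch_depends_on_connectivity(self):
        mask = np.zeros((2, 2, 2), bool)
        mask[0, 0, 0] = True
        mask[1, 1, 1] = True
        assert label_components(VesselMask(mask, GEOM), 26).n_components == 1
        assert label_components(VesselMask(mask, GEOM), 6).n_components == 2

    def test_rendered_tuft_is_single_component(self, small_glom_phantom):
        stack, _ = small_glom_phantom
        cleaned = clean_mask(stack)
        lab = label_components(cleaned, 26)
        assert lab.n_components == 1

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(hnp.arrays(bool, (6, 7, 8), elements=st.booleans()))
    def test_component_counts_sum_to_mask_count(self, mask):
        lab = label_components(VesselMask(mask, GEOM), 26)
        assert lab.voxel_counts.sum() == mask.sum()


class TestFilterSmall:
    def _labelled(self, sizes):
        mask = np.zeros((4, 50, 30), bool)
        col = 0
        for s in sizes:
            n = 0
            for z in range(4):
                for y in range(50):
                    if n == s:
                        break
                    mask[z, y, col] = True
                    n += 1
                if n == s:
                    break
            col += 3  # gap keeps components disjoint
        return label_components(VesselMask(mask, GEOM), 26)

    def test_zero_threshold_is_identity(self):
        lab = self._labelled([5, 9])
        out = filter_small_components(lab, 0)
        assert out.voxel_count == 14

    def test_small_component_removed(self):
        lab = self._labelled([150, 3])
        out = filter_small_components(lab, 10)
        assert out.voxel_count == 150

    def test_everything_removed_warns(self):
        lab = self._labelled([5])
        with pytest.warns(UserWarning, match="every component"):
            out = filter_small_components(lab, 1000)
        assert out.voxel_count == 0


class TestExcludeRegion:
    def test_empty_roi_is_identity(self, rng):
        m = VesselMask(rng.random((4, 5, 5)) > 0.5, GEOM)
        out = exclude_region(m, np.zeros((4, 5, 5), bool))
        np.testing.assert_array_equal(out.mask, m.mask)

    def test_full_roi_empties_mask(self, rng):
        m = VesselMask(rng.random((4, 5, 5)) > 0.5, GEOM)
        assert exclude_region(m, np.ones((4, 5, 5), bool)).voxel_count == 0

    def test_shape_mismatch_rejected(self):
        m = VesselMask(np.zeros((2, 2, 2), bool), GEOM)
        with pytest.raises(ValueError, match="shape"):
            exclude_region(m, np.zeros((2, 3, 2), bool))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(hnp.arrays(bool, (5, 6, 6), elements=st.booleans()),
           hnp.arrays(bool, (5, 6, 6), elements=st.booleans()))
    def test_exclusion_count_arithmetic_exact(self, mask, roi):
        m = VesselMask(mask, GEOM)
        out = exclude_region(m, roi)
        assert out.voxel_count == mask.sum() - (mask & roi).sum()

    def test_cortex_exclusion_exact_on_true_mask(self):
        # glomerular tubes are confined to their ROIs and the plexus is carved
        # out of them, so ROI exclusion recovers the plexus voxels exactly
        from fmaquant.phantom import generate_cortex_phantom, preset_params
        p = preset_params("sham", kind="cortex", scale="coarse", seed=8,
                          n_glomeruli=2)
        _, truth = generate_cortex_phantom(p)
        m = VesselMask(truth.true_vessel_mask, p.geometry)
        roi_union = truth.glomerulus_rois[0] | truth.glomerulus_rois[1]
        remaining = exclude_region(m, roi_union)
        assert remaining.voxel_count * p.geometry.voxel_volume == \
            pytest.approx(truth.plexus_volume, rel=1e-12)

    def test_cortex_exclusion_recovers_plexus_volume(self):
        # full pipeline at native voxel geometry: segment, exclude, compare
        from fmaquant.morphometry import capillary_volume
        from fmaquant.phantom import generate_cortex_phantom, preset_params
        p = preset_params("sham", kind="cortex", scale="full", seed=8,
                          n_glomeruli=2, render_red=False)
        stack, truth = generate_cortex_phantom(p)
        vmask = clean_mask(stack)
        roi_union = truth.glomerulus_rois[0] | truth.glomerulus_rois[1]
        remaining = exclude_region(vmask, roi_union)
        assert capillary_volume(remaining) == pytest.approx(
            truth.plexus_volume, rel=0.05)


class TestPolygonRois:
    def test_square_polygon_rasterized(self):
        polys = [{"z": 1, "vertices": [[1, 1], [5, 1], [5, 5], [1, 5]]}]
        mask = rasterize_polygon_rois(polys, (3, 8, 8))
        assert mask[1].sum() > 0
        assert mask[0].sum() == 0 and mask[2].sum() == 0

    def test_out_of_range_slice_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            rasterize_polygon_rois([{"z": 5, "vertices": [[0, 0], [1, 0], [1, 1]]}],
                                   (3, 8, 8))
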