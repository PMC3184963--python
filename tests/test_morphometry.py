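"""Morphometry: voxel-counting volume, ellipsoid fits, density quotients."""

import numpy as np
import pytest

from fmaquant.geometry import Ellipsoid, VoxelGeometry
from fmaquant.morphometry import (
    MeasureConfig,
    capillary_volume,
    evaluate_glomeruli,
    fit_ellipsoid,
    glomerular_capillary_density,
    hull_ellipsoid,
    peritubular_capillary_density,
)
from fmaquant.segment import VesselMask


def slicewise_volume_oracle(mask, dx, dy, dz):
    """Independent oracle: positive pixel area per optical section times dz."""
    total = 0.0
    for z in range(mask.shape[0]):
        area = float(np.count_nonzero(mask[z])) * dx * dy
        total += area * dz
    return total


def solid_ellipsoid_mask(semi, geometry, rotation=None, pad=4):
    """Rasterize a solid ellipsoid (optionally rotated) into a boolean mask."""
    a = max(semi)
    shape = (int(2 * (a + pad) / geometry.dz), int(2 * (a + pad) / geometry.dy),
             int(2 * (a + pad) / geometry.dx))
    center = tuple((s - 1) * d / 2 for s, d in
                   zip(shape, (geometry.dz, geometry.dy, geometry.dx)))
    zz, yy, xx = np.meshgrid(
        np.arange(shape[0]) * geometry.dz - center[0],
        np.arange(shape[1]) * geometry.dy - center[1],
        np.arange(shape[2]) * geometry.dx - center[2], indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1)
    if rotation is not None:
        pts = pts @ rotation
    u = pts / np.asarray(semi)
    return (u * u).sum(axis=-1) <= 1.0


def rotation_about_z(deg):
    """Rotation by ``deg`` about the stack z-axis, in (z, y, x) coordinates."""
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


class TestCapillaryVolume:
    GEOM = VoxelGeometry()

    def test_direct_product(self):
        mask = np.zeros((10, 10, 10), bool)
        mask.ravel()[:1000] = True
        v = capillary_volume(VesselMask(mask, self.GEOM))
        assert v == pytest.approx(433.8, abs=0.05)

    def test_empty_mask_is_zero(self):
        assert capillary_volume(VesselMask(np.zeros((3, 3, 3), bool),
                                           self.GEOM)) == 0.0

    def test_matches_slicewise_oracle_on_random_masks(self, rng):
        g = VoxelGeometry(dx=0.73, dy=0.73, dz=0.8141)
        for _ in range(10):
            mask = rng.random((32, 32, 32)) > rng.uniform(0.2, 0.9)
            assert capillary_volume(VesselMask(mask, g)) == pytest.approx(
                slicewise_volume_oracle(mask, g.dx, g.dy, g.dz), rel=1e-12)


class TestFitEllipsoid:
    GEOM = VoxelGeometry()

    def test_sphere_radius_recovered(self):
        mask = solid_ellipsoid_mask((30, 30, 30), self.GEOM)
        e = fit_ellipsoid(mask, self.GEOM)
        assert np.allclose(e.semi_axes, 30, rtol=0.03)

    def test_axis_aligned_ellipsoid_recovered(self):
        mask = solid_ellipsoid_mask((20, 30, 40), self.GEOM)
        e = fit_ellipsoid(mask, self.GEOM)
        assert np.allclose(e.semi_axes, [40, 30, 20], rtol=0.05)

    def test_rotation_invariance(self):
        mask = solid_ellipsoid_mask((20, 30, 40), self.GEOM,
                                    rotation=rotation_about_z(30))
        e = fit_ellipsoid(mask, self.GEOM)
        assert np.allclose(e.semi_axes, [40, 30, 20], rtol=0.05)

    def test_degenerate_plane_rejected(self):
        mask = np.zeros((5, 10, 10), bool)
        mask[2] = True
        with pytest.raises(ValueError, match="degenerate|planar"):
            fit_ellipsoid(mask, self.GEOM)

    def test_too_few_points_rejected(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[0, 0, 0] = True
        with pytest.raises(ValueError, match=">= 4"):
            fit_ellipsoid(mask, self.GEOM)

    def test_fit_error_shrinks_with_resolution(self):
        errs = []
        for r_vox in (10, 20, 40):
            g = VoxelGeometry(dx=1, dy=1, dz=1)
            mask = solid_ellipsoid_mask((r_vox,) * 3, g)
            e = fit_ellipsoid(mask, g)
            errs.append(abs(e.a - r_vox) / r_vox)
        assert errs[-1] < errs[0]
        assert errs[-1] < 0.01

    def test_extent_mode_on_solid_ellipsoid(self):
        mask = solid_ellipsoid_mask((20, 30, 40), self.GEOM)
        e = fit_ellipsoid(mask, self.GEOM, mode="extent")
        assert np.allclose(e.semi_axes, [40, 30, 20], rtol=0.06)

    def test_hull_ellipsoid_on_solid_mask(self):
        mask = solid_ellipsoid_mask((20, 30, 40), self.GEOM,
                                    rotation=rotation_about_z(20))
        e = hull_ellipsoid(mask, self.GEOM)
        assert np.allclose(e.semi_axes, [40, 30, 20], rtol=0.05)


class TestDensities:
    def test_quotient_example(self):
        d = glomerular_capillary_density(4.1e5, 1.4e6)
        assert d == pytest.approx(0.293, abs=5e-4)

    def test_zero_capillary_volume(self):
        assert glomerular_capillary_density(0.0, 1e6) == 0.0

    def test_capillary_exceeding_envelope_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            glomerular_capillary_density(2e6, 1e6)

    def test_zero_envelope_rejected(self):
        with pytest.raises(ValueError):
            glomerular_capillary_density(1.0, 0.0)

    def test_density_times_volume_is_consistent(self):
        cap, glom = 3.3e5, 1.2e6
        d = glomerular_capillary_density(cap, glom)
        assert d * glom == pytest.approx(cap, rel=1e-9)

    def test_peritubular_fraction(self, rng):
        g = VoxelGeometry(dx=1, dy=1, dz=1)
        field = np.ones((10, 20, 20), bool)
        mask = np.zeros_like(field)
        mask.ravel()[:200] = True  # 200 / 4000 = 5 %
        d = peritubular_capillary_density(VesselMask(mask, g), field)
        assert d == pytest.approx(0.05, rel=1e-12)

    def test_empty_vessel_mask_gives_zero(self):
        g = VoxelGeometry(dx=1, dy=1, dz=1)
        d = peritubular_capillary_density(
            VesselMask(np.zeros((4, 4, 4), bool), g), np.ones((4, 4, 4), bool))
        assert d == 0.0

    def test_empty_field_rejected(self):
        g = VoxelGeometry(dx=1, dy=1, dz=1)
        with pytest.raises(ValueError, match="field"):
            peritubular_capillary_density(
                VesselMask(np.zeros((4, 4, 4), bool), g),
                np.zeros((4, 4, 4), bool))


class TestEvaluateGlomeruli:
    def test_identical_rois_give_zero_sem(self, small_glom_phantom):
        stack, truth = small_glom_phantom
        rois = [truth.glomerulus_rois[0]] * 6
        m = evaluate_glomeruli(stack, rois)
        assert m.n_glomeruli_evaluated == 6
        assert m.capillary_volume == m.per_glomerulus[0].capillary_volume
        assert m.capillary_volume_sem == 0.0
        assert m.density_sem == pytest.approx(0.0, abs=1e-12)

    def test_empty_roi_excluded_with_warning(self, small_glom_phantom):
        stack, truth = small_glom_phantom
        rois = [truth.glomerulus_rois[0]] * 5 + \
            [np.zeros(stack.shape, bool)]
        with pytest.warns(UserWarning, match="no positive voxels"):
            m = evaluate_glomeruli(stack, rois)
        assert m.n_glomeruli_evaluated == 5

    def test_no_rois_rejected(self, small_glom_phantom):
        stack, _ = small_glom_phantom
        with pytest.raises(ValueError, match="ROI"):
            evaluate_glomeruli(stack, [])

    def test_measured_density_tracks_truth(self, small_glom_phantom):
        stack, truth = small_glom_phantom
        m = evaluate_glomeruli(stack, truth.glomerulus_rois)
        assert m.glomerular_capillary_density == pytest.approx(
            truth.true_density, rel=0.10)
        # density x envelope reproduces measured capillary volume
        g = m.per_glomerulus[0]
        assert g.capillary_density * g.glomerular_volume == pytest.approx(
            g.capillary_volume, rel=1e-9)
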