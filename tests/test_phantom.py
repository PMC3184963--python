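"""Phantom generator: determinism, volume bookkeeping, dropout, imaging model."""

from dataclasses import replace

import numpy as np
import pytest

from fmaquant.phantom import (
    GenerationError,
    PhantomParameterError,
    PhantomParams,
    apply_dropout,
    generate_cortex_phantom,
    generate_glomerular_phantom,
    generate_ihc_section,
    preset_params,
    render_imaging,
)


class TestParams:
    def test_axial_step_default_is_exact(self):
        assert PhantomParams().voxel_z == 0.8141

    @pytest.mark.parametrize("bad", [
        {"dropout_fraction": 1.2}, {"dropout_fraction": -0.1},
        {"tube_radius_mean": 0.0}, {"noise_sd": -1.0}, {"psf_sigma_xy": -0.5},
        {"kind": "medulla"}, {"tuft_semi_axes": (10.0, -5.0, 5.0)},
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(PhantomParameterError):
            PhantomParams(**bad)

    def test_tuft_must_fit_stack(self):
        p = preset_params("sham", scale="coarse", stack_shape=(10, 10, 10))
        with pytest.raises(PhantomParameterError, match="does not fit"):
            generate_glomerular_phantom(p)


class TestGlomerularPhantom:
    def test_determinism_same_seed(self):
        p = preset_params("sham", scale="coarse", seed=42)
        s1, t1 = generate_glomerular_phantom(p)
        s2, t2 = generate_glomerular_phantom(p)
        np.testing.assert_array_equal(s1.channel("green"), s2.channel("green"))
        np.testing.assert_array_equal(t1.true_vessel_mask, t2.true_vessel_mask)
        assert t1.true_capillary_volume == t2.true_capillary_volume

    def test_volume_bookkeeping_exact(self, small_glom_phantom):
        _, truth = small_glom_phantom
        expected = int(truth.true_vessel_mask.sum()) * \
            truth.params.geometry.voxel_volume
        assert truth.true_capillary_volume == expected

    def test_default_volume_in_physiological_band(self, small_glom_phantom):
        # defaults are sized to the 2-5e5 µm³ range reported for rat glomeruli
        _, truth = small_glom_phantom
        assert 2e5 <= truth.true_capillary_volume <= 5e5
        assert truth.true_capillary_volume == pytest.approx(
            truth.requested_capillary_volume, rel=0.10)
        assert 0.0 < truth.true_density <= 1.0

    def test_enlargement_scales_truth_ellipsoid_exactly(self):
        p = preset_params("sham", scale="coarse", seed=5)
        _, t1 = generate_glomerular_phantom(p)
        _, t2 = generate_glomerular_phantom(replace(p, enlargement_factor=1.5))
        assert t2.true_tuft_ellipsoid.volume == pytest.approx(
            1.5**3 * t1.true_tuft_ellipsoid.volume, rel=1e-9)

    def test_fixed_capillary_geometry_under_enlargement(self):
        p = preset_params("sham", scale="coarse", seed=5,
                          loops_follow_enlargement=False)
        _, t1 = generate_glomerular_phantom(p)
        _, t2 = generate_glomerular_phantom(replace(p, enlargement_factor=1.5))
        assert t2.true_capillary_volume == pytest.approx(
            t1.true_capillary_volume, rel=0.02)

    def test_density_unreachable_raises(self):
        p = preset_params("sham", scale="coarse", seed=0,
                          capillary_density_target=0.9, n_loops=2)
        with pytest.raises(GenerationError, match="density"):
            generate_glomerular_phantom(p)


class TestDropout:
    def _phantom(self, frac, seed=3):
        p = preset_params("sham", scale="coarse", seed=seed,
                          dropout_fraction=frac)
        return generate_glomerular_phantom(p)[1]

    def test_zero_is_identity_and_one_annihilates(self, small_glom_phantom):
        from fmaquant.phantom import TubeNetwork, TubeSegment
        seg = TubeSegment(points=np.array([[0., 0., 0.], [10., 0., 0.]]),
                          radius=2.0, loop_id=0)
        net = TubeNetwork((seg,))
        same, f0 = apply_dropout(net, 0.0, 1)
        assert same is net and f0 == 0.0
        empty, f1 = apply_dropout(net, 1.0, 1)
        assert len(empty) == 0 and f1 == 1.0

    @pytest.mark.parametrize("frac,lo,hi", [(0.3, 0.65, 0.75), (0.5, 0.45, 0.55)])
    def test_retained_volume_tracks_fraction(self, frac, lo, hi):
        t0 = self._phantom(0.0)
        td = self._phantom(frac)
        ratio = td.true_capillary_volume / t0.true_capillary_volume
        assert lo <= ratio <= hi

    def test_volume_monotone_in_dropout(self):
        vols = [self._phantom(f).true_capillary_volume
                for f in (0.0, 0.25, 0.5)]
        assert vols[0] > vols[1] > vols[2]

    def test_invalid_fraction_rejected(self):
        from fmaquant.phantom import TubeNetwork
        with pytest.raises(PhantomParameterError):
            apply_dropout(TubeNetwork(()), 1.5, 0)


class TestRenderImaging:
    def test_degenerate_model_reproduces_mask(self, rng):
        p = PhantomParams(psf_sigma_xy=0, psf_sigma_z=0, speckle_amplitude=0,
                          noise_sd=0, stack_shape=(8, 10, 10))
        mask = rng.random((8, 10, 10)) > 0.7
        stack = render_imaging(mask, p, rng=0)
        np.testing.assert_array_equal(
            stack.channel("green"), mask.astype(np.uint8) * int(p.peak_intensity))

    def test_noise_is_seeded(self, rng):
        p = PhantomParams(stack_shape=(6, 12, 12), noise_sd=8.0)
        mask = rng.random((6, 12, 12)) > 0.6
        s1 = render_imaging(mask, p, rng=7)
        s2 = render_imaging(mask, p, rng=7)
        np.testing.assert_array_equal(s1.channel("green"), s2.channel("green"))

    def test_red_channel_covers_parenchyma(self, small_glom_phantom):
        stack, truth = small_glom_phantom
        red = stack.channel("red").astype(float)
        inside = truth.glomerulus_rois[0]
        # autofluorescence should light up tissue outside the tuft only
        assert red[~inside].mean() > 5 * max(red[inside].mean(), 1e-9)


class TestCortexPhantom:
    def test_plexus_density_hits_target(self):
        p = preset_params("sham", kind="cortex", scale="coarse", seed=2,
                          n_glomeruli=0)
        _, truth = generate_cortex_phantom(p)
        assert truth.true_density == pytest.approx(0.05, abs=0.005)

    def test_embedded_rois_disjoint_and_counted(self):
        p = preset_params("sham", kind="cortex", scale="coarse", seed=2,
                          n_glomeruli=2)
        _, truth = generate_cortex_phantom(p)
        assert len(truth.glomerulus_rois) == 2
        assert not (truth.glomerulus_rois[0] & truth.glomerulus_rois[1]).any()

    def test_dropout_reduces_network_volume(self):
        p0 = preset_params("sham", kind="cortex", scale="coarse", seed=4)
        pd = replace(p0, dropout_fraction=0.25)
        _, t0 = generate_cortex_phantom(p0)
        _, td = generate_cortex_phantom(pd)
        assert td.true_capillary_volume / t0.true_capillary_volume == \
            pytest.approx(0.75, abs=0.03)

    def test_determinism(self):
        p = preset_params("snx", kind="cortex", scale="coarse", seed=9,
                          n_glomeruli=1)
        s1, t1 = generate_cortex_phantom(p)
        s2, t2 = generate_cortex_phantom(p)
        np.testing.assert_array_equal(s1.channel("green"), s2.channel("green"))
        np.testing.assert_array_equal(t1.true_vessel_mask, t2.true_vessel_mask)


class TestIhcSection:
    def test_blank_target(self):
        sec = generate_ihc_section(0.0, seed=1)
        assert sec.area_fraction == 0.0
        assert not sec.stain_mask.any()

    def test_target_realised_within_half_point(self):
        sec = generate_ihc_section(0.12, seed=1)
        assert 0.115 <= sec.area_fraction <= 0.125

    def test_determinism(self):
        a = generate_ihc_section(0.2, seed=6)
        b = generate_ihc_section(0.2, seed=6)
        np.testing.assert_array_equal(a.image, b.image)

    def test_unreachable_target_raises(self):
        with pytest.raises(GenerationError):
            generate_ihc_section(0.99, seed=0)
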