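import numpy as np
import pytest
from scipy import ndimage

from gazealter import lowvision_render as lr
from gazealter.gaze_geometry import PixelGazePoint


def shift_margin(field, dx):
    """Crop margin guaranteeing all warp samples stay in-frame after a shift."""
    return int(np.ceil(np.linalg.norm(field, axis=-1).max())) + dx + 2


class TestDeformationField:
    def test_zero_amplitude_gives_zero_field(self, center_gaze):
        p = lr.DeformationParams(source_amplitude_px=0.0)
        f = lr.build_deformation_field((64, 64), center_gaze, p, seed=0)
        np.testing.assert_array_equal(f, 0.0)

    def test_zero_sources_gives_zero_field(self, center_gaze):
        p = lr.DeformationParams(n_sources=0)
        f = lr.build_deformation_field((64, 64), center_gaze, p, seed=0)
        np.testing.assert_array_equal(f, 0.0)

    def test_temporal_periodicity(self, center_gaze):
        p = lr.DeformationParams()
        f0 = lr.build_deformation_field((64, 64), center_gaze, p, t=0.4, seed=1)
        f1 = lr.build_deformation_field((64, 64), center_gaze, p,
                                        t=0.4 + p.modulation_period_s, seed=1)
        np.testing.assert_allclose(f0, f1, atol=1e-9)

    def test_gaze_translation_translates_field(self):
        p = lr.DeformationParams()
        g0 = PixelGazePoint(64, 64)
        g1 = PixelGazePoint(74, 64)
        f0 = lr.build_deformation_field((128, 128), g0, p, seed=2)
        f1 = lr.build_deformation_field((128, 128), g1, p, seed=2)
        np.testing.assert_allclose(f0[:, :-10], f1[:, 10:], atol=1e-12)

    def test_offsets_within_analytic_bound(self, center_gaze):
        p = lr.DeformationParams()
        for t in (0.0, 0.5, 1.3):
            f = lr.build_deformation_field((96, 96), center_gaze, p, t=t, seed=3)
            assert np.linalg.norm(f, axis=-1).max() <= p.max_offset_px + 1e-9


class TestMetamorphopsia:
    def test_zero_field_identity(self, scene_rgb):
        f = np.zeros(scene_rgb.shape[:2] + (2,))
        out = lr.apply_metamorphopsia(scene_rgb, f)
        np.testing.assert_array_equal(out, scene_rgb)

    def test_uniform_field_displaces_edge(self):
        # vertical step edge at column 64; a uniform (dx=5) sampling field
        # moves the rendered edge 5 px to the left
        img = np.zeros((64, 128), dtype=np.uint8)
        img[:, 64:] = 255
        f = np.zeros((64, 128, 2))
        f[..., 1] = 5.0
        out = lr.apply_metamorphopsia(img, f)
        edge_in = int(np.argmax(np.diff(img[32].astype(int)) != 0))
        edge_out = int(np.argmax(np.diff(out[32].astype(int)) != 0))
        assert edge_out == edge_in - 5

    def test_straight_lines_become_wavy(self, center_gaze):
        # grid of straight vertical lines; under a nonzero field the best
        # straight-line fit to each rendered line leaves > 1 px residual
        img = np.zeros((128, 128))
        img[:, 60] = 255.0
        p = lr.DeformationParams(source_amplitude_px=8.0, source_sigma_px=25.0,
                                 ring_radius_px=20.0)
        f = lr.build_deformation_field(img.shape, center_gaze, p, seed=4)
        out = lr.apply_metamorphopsia(img, f)
        cols = np.array([np.argmax(row) for row in out])
        rows = np.arange(128)
        fit = np.polyval(np.polyfit(rows, cols, 1), rows)
        assert np.abs(cols - fit).max() > 1.0

    def test_extent_mismatch_rejected(self, scene_image):
        with pytest.raises(ValueError):
            lr.apply_metamorphopsia(scene_image, np.zeros((4, 4, 2)))


class TestScotoma:
    def test_gaze_center_takes_gray_level(self, scene_rgb, center_gaze):
        cfg = lr.ConditionConfig(condition="B")
        out = lr.apply_scotoma(scene_rgb, center_gaze, cfg)
        np.testing.assert_array_equal(out[64, 64], cfg.scotoma_gray_level)

    def test_far_pixels_untouched(self, scene_rgb, center_gaze):
        cfg = lr.ConditionConfig(condition="B", scotoma_radius_deg=5.0,
                                 scotoma_softness_deg=1.0)
        out = lr.apply_scotoma(scene_rgb, center_gaze, cfg)
        disp = lr.image_display(scene_rgb.shape)
        ys, xs = np.mgrid[0:128, 0:128]
        ecc = np.hypot((xs - 64) * disp.fov_deg[0] / 128,
                       (ys - 64) * disp.fov_deg[1] / 128)
        outside = ecc > 2 * (cfg.scotoma_radius_deg + cfg.scotoma_softness_deg)
        np.testing.assert_array_equal(out[outside], scene_rgb[outside])

    def test_occluded_area_matches_disc(self, center_gaze):
        cfg = lr.ConditionConfig(condition="B", scotoma_radius_deg=10.0,
                                 scotoma_softness_deg=0.01, scotoma_gray_level=0)
        white = np.full((128, 128), 255, np.uint8)
        disp = lr.image_display(white.shape)
        out = lr.apply_scotoma(white, center_gaze, cfg, disp)
        occluded = (out < 128).sum()
        r_px = cfg.scotoma_radius_deg / (disp.fov_deg[0] / 128)
        # anisotropic FOV makes the disc an ellipse in pixels
        ry_px = cfg.scotoma_radius_deg / (disp.fov_deg[1] / 128)
        assert occluded == pytest.approx(np.pi * r_px * ry_px, rel=0.05)


class TestTunnel:
    def test_aperture_interior_bit_identical(self, scene_rgb, center_gaze):
        cfg = lr.ConditionConfig(condition="T")
        disp = lr.image_display(scene_rgb.shape)
        out = lr.apply_tunnel(scene_rgb, center_gaze, cfg, disp)
        ys, xs = np.mgrid[0:128, 0:128]
        ecc = np.hypot((xs - 64) * disp.fov_deg[0] / 128,
                       (ys - 64) * disp.fov_deg[1] / 128)
        inside = ecc <= cfg.aperture_radius_deg
        np.testing.assert_array_equal(out[inside], scene_rgb[inside])

    def test_far_corner_dimmed_to_bound(self, center_gaze):
        cfg = lr.ConditionConfig(condition="T")
        white = np.full((128, 128), 255, np.uint8)
        out = lr.apply_tunnel(white, center_gaze, cfg)
        assert out[0, 0] <= cfg.dim_factor * 255 + 0.5

    def test_clear_region_follows_gaze(self):
        # on a white card only dimming changes pixels, so the fully clear
        # region is exactly the set of full-intensity pixels
        white = np.full((128, 128), 255, np.uint8)
        cfg = lr.ConditionConfig(condition="T", dim_factor=0.0)
        disp = lr.image_display(white.shape)
        out1 = lr.apply_tunnel(white, PixelGazePoint(50, 64), cfg, disp)
        out2 = lr.apply_tunnel(white, PixelGazePoint(80, 64), cfg, disp)
        m1 = out1 == 255
        m2 = out2 == 255
        c1x = np.average(np.arange(128), weights=m1.sum(axis=0))
        c2x = np.average(np.arange(128), weights=m2.sum(axis=0))
        assert c2x - c1x == pytest.approx(30.0, abs=1.0)


class TestHemianopsia:
    def test_intact_side_bit_identical(self, scene_rgb, center_gaze):
        cfg = lr.ConditionConfig(condition="H")  # left side impaired
        disp = lr.image_display(scene_rgb.shape)
        out = lr.apply_hemianopsia(scene_rgb, center_gaze, cfg, disp)
        band_px = cfg.boundary_softness_deg / (disp.fov_deg[0] / 128)
        intact = np.arange(128) > 64 + band_px / 2 + 1
        np.testing.assert_array_equal(out[:, intact], scene_rgb[:, intact])

    def test_impaired_side_loses_gradient_energy(self, center_gaze):
        rng = np.random.default_rng(0)
        checker = (rng.integers(0, 2, size=(128, 128)) * 255).astype(np.uint8)
        cfg = lr.ConditionConfig(condition="H")
        out = lr.apply_hemianopsia(checker, center_gaze, cfg).astype(float)
        gx = np.abs(np.diff(out, axis=1))
        left_energy = gx[:, :50].mean()
        right_energy = gx[:, 70:].mean()
        assert left_energy < 0.5 * right_energy

    def test_boundary_tracks_gaze(self, scene_image):
        cfg = lr.ConditionConfig(condition="H", dim_factor=0.0)
        disp = lr.image_display(scene_image.shape)
        out1 = lr.apply_hemianopsia(scene_image, PixelGazePoint(40, 64), cfg, disp)
        out2 = lr.apply_hemianopsia(scene_image, PixelGazePoint(90, 64), cfg, disp)

        def boundary(out):
            changed = (out != scene_image).any(axis=0)
            return int(np.flatnonzero(~changed)[0])

        assert boundary(out2) - boundary(out1) == pytest.approx(50, abs=2)

    def test_right_side_variant(self, scene_rgb, center_gaze):
        cfg = lr.ConditionConfig(condition="H", hemifield_side="right")
        disp = lr.image_display(scene_rgb.shape)
        out = lr.apply_hemianopsia(scene_rgb, center_gaze, cfg, disp)
        band_px = cfg.boundary_softness_deg / (disp.fov_deg[0] / 128)
        intact = np.arange(128) < 64 - band_px / 2 - 1
        np.testing.assert_array_equal(out[:, intact], scene_rgb[:, intact])


class TestPyramidBlur:
    def test_zero_sigma_identity(self, scene_rgb):
        out = lr.pyramid_blur(scene_rgb, np.zeros(scene_rgb.shape[:2]))
        np.testing.assert_array_equal(out, scene_rgb)

    def test_uniform_sigma_reduces_noise_variance(self):
        rng = np.random.default_rng(1)
        noise = rng.uniform(0, 255, size=(96, 96))
        out = lr.pyramid_blur(noise, np.full((96, 96), 8.0))
        assert out.var() < 0.5 * noise.var()

    @pytest.mark.parametrize("sigma", [2.0, 3.0, 6.0])
    def test_uniform_sigma_matches_direct_gaussian(self, scene_image, sigma):
        img = scene_image.astype(float)
        pb = lr.pyramid_blur(img, np.full(img.shape, sigma))
        direct = ndimage.gaussian_filter(img, sigma)
        assert np.abs(pb - direct).mean() <= 2.0

    def test_negative_sigma_rejected(self, scene_image):
        with pytest.raises(ValueError):
            lr.pyramid_blur(scene_image, np.full(scene_image.shape, -1.0))


class TestRenderCondition:
    def test_healthy_is_identity(self, scene_rgb, center_gaze):
        cfg = lr.ConditionConfig(condition="N")
        out = lr.render_condition(scene_rgb, center_gaze, cfg)
        np.testing.assert_array_equal(out, scene_rgb)

    def test_deterministic(self, scene_rgb, center_gaze):
        cfg = lr.ConditionConfig(condition="B")
        a = lr.render_condition(scene_rgb, center_gaze, cfg, t=0.7, seed=5)
        b = lr.render_condition(scene_rgb, center_gaze, cfg, t=0.7, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_temporal_modulation_confined_to_deformation_support(
            self, scene_rgb, center_gaze):
        cfg = lr.ConditionConfig(condition="B")
        disp = lr.image_display(scene_rgb.shape)
        a = lr.render_condition(scene_rgb, center_gaze, cfg, disp, t=0.0, seed=6)
        b = lr.render_condition(scene_rgb, center_gaze, cfg, disp,
                                t=cfg.deformation.modulation_period_s / 4, seed=6)
        diff = (a.astype(int) != b.astype(int)).any(axis=-1)
        ys, xs = np.where(diff)
        if len(ys):
            sx = disp.fov_deg[0] / 128
            ring = 0.6 * cfg.scotoma_radius_deg / sx
            reach = np.hypot(xs - 64.0, ys - 64.0).max()
            support = (ring + 4 * cfg.deformation.source_sigma_px
                       + cfg.deformation.max_offset_px)
            assert reach <= support

    @pytest.mark.parametrize("cond", ["B", "H", "T"])
    def test_gaze_contingency_shift_property(self, scene_rgb, cond):
        cfg = lr.ConditionConfig(condition=cond)
        disp = lr.image_display(scene_rgb.shape)
        dx = 8
        g = PixelGazePoint(64, 64)
        g_shift = PixelGazePoint(64 + dx, 64)
        shifted = np.roll(scene_rgb, dx, axis=1)
        out1 = lr.render_condition(scene_rgb, g, cfg, disp, t=0.3, seed=7)
        out2 = lr.render_condition(shifted, g_shift, cfg, disp, t=0.3, seed=7)
        if cond == "B":
            sx = disp.fov_deg[0] / 128
            params = cfg.deformation.model_copy(
                update={"ring_radius_px": 0.6 * cfg.scotoma_radius_deg / sx})
            field = lr.build_deformation_field(scene_rgb.shape, g, params,
                                               t=0.3, seed=7)
            m = shift_margin(field, dx)
        else:
            m = int(4 * cfg.blur_max_sigma_px) + dx + 2
        c1 = out1[m:-m, m:-m - dx].astype(int)
        c2 = out2[m:-m, m + dx:-m].astype(int)
        assert np.abs(c1 - c2).max() <= 1  # integer rounding only

    def test_unknown_condition_rejected(self, scene_rgb, center_gaze):
        cfg = lr.ConditionConfig(condition="N")
        object.__setattr__(cfg, "condition", "Z") if False else None
        with pytest.raises(Exception):
            lr.ConditionConfig(condition="Z")
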