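"""Ground-truth construction, rendering physics, and determinism of scenes."""

import numpy as np
import pytest
from scipy.signal import find_peaks

from metalloscope import synthetic_scene as ss
from metalloscope import xrf_quant as xq
from metalloscope.registration import AffineTransform2D, fit_affine_from_fiducials


class TestSceneConstruction:
    def test_same_seed_bit_identical_different_seed_differs(self):
        cfg = ss.SceneConfig(seed=5)
        a = ss.generate_scene(cfg)
        b = ss.generate_scene(ss.SceneConfig(seed=5))
        assert np.array_equal(a.tubulin, b.tubulin)
        assert np.array_equal(a.elements["Zn"], b.elements["Zn"])
        c = ss.generate_scene(ss.SceneConfig(seed=6))
        assert not np.array_equal(a.tubulin, c.tubulin)

    def test_empty_scene_without_dendrites(self):
        sc = ss.generate_scene(ss.SceneConfig(n_dendrites=0, seed=0))
        assert sc.tubulin.sum() == 0
        assert sc.elements["Zn"].sum() == 0
        assert sc.elements["Cu"].sum() == 0
        # any sulfur left is the diffuse cell background only
        off_cell = sc.elements["S"][~sc.masks["cell"]]
        assert np.all(off_cell == 0)

    def test_pure_filament_s_to_zn_ratio_is_exact(self, default_scene):
        fil = default_scene.masks["dendrite"]
        cfg = default_scene.config
        ratio = default_scene.elements["S"][fil].sum() / default_scene.elements["Zn"][fil].sum()
        assert ratio == pytest.approx(cfg.s_per_dimer / cfg.zn_per_dimer, rel=1e-12)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ss.SceneConfig(field_size_nm=(0.0, 1000.0))
        with pytest.raises(ValueError):
            ss.SceneConfig(pixel_size_nm=-40.0)
        with pytest.raises(ValueError):
            ss.SceneConfig(zn_per_dimer=-1.0)


class TestElementRendering:
    def test_noise_off_is_exact_unit_conversion_plus_blank(self, default_scene):
        maps = ss.render_element_maps(default_scene, noise=False)
        cfg = default_scene.config
        zn = maps["Zn"]
        truth_blurred = ss._beam_blur(default_scene.elements["Zn"], cfg)
        expected = xq.atoms_to_areal_density(truth_blurred, "Zn") + cfg.blank_level_ng_mm2["Zn"]
        assert np.allclose(zn.data, expected, rtol=1e-12)

    def test_total_sulfur_conserved_after_unit_round_trip(self, default_scene):
        maps = ss.render_element_maps(default_scene, noise=False)
        cfg = default_scene.config
        atoms = xq.areal_density_to_atoms(maps["S"]) - float(
            xq.areal_density_to_atoms(cfg.blank_level_ng_mm2["S"], "S")
        )
        assert atoms.sum() == pytest.approx(default_scene.elements["S"].sum(), rel=1e-9)

    def test_high_sensitivity_converges_to_noise_free(self):
        cfg = ss.SceneConfig(seed=2, counts_per_atom=1e4)
        sc = ss.generate_scene(cfg)
        clean = ss.render_element_maps(sc, noise=False)["S"].data
        noisy = ss.render_element_maps(sc, noise=True)["S"].data
        fil = sc.masks["dendrite"]
        rel = np.abs(noisy[fil] - clean[fil]) / clean[fil]
        assert rel.mean() < 0.01

    def test_poisson_mean_matches_truth_plus_blank(self):
        # 500 replicate pixels at a fixed truth level: Monte-Carlo mean within 3 SE
        cfg = ss.SceneConfig(seed=3)
        atoms_true = 0.2  # atoms/nm²
        px = cfg.pixel_size_nm
        lam = cfg.counts_per_atom * atoms_true * px**2
        rng = np.random.default_rng(99)
        counts = rng.poisson(lam, size=500)
        est = counts.mean() / (cfg.counts_per_atom * px**2)
        se = np.sqrt(lam) / (cfg.counts_per_atom * px**2) / np.sqrt(500)
        assert abs(est - atoms_true) < 3 * se

    def test_noise_requires_positive_sensitivity(self, default_scene):
        default_scene.config.counts_per_atom = 0.0
        try:
            with pytest.raises(ValueError):
                ss.render_element_maps(default_scene, noise=True)
        finally:
            default_scene.config.counts_per_atom = 1.0


class TestProteinImaging:
    @pytest.mark.parametrize(
        "modality, expect_two_peaks", [("sted", True), ("confocal", False)]
    )
    def test_160nm_pair_resolved_only_by_sted(self, modality, expect_two_peaks):
        sc = ss.two_parallel_filaments(160.0)
        img, px = ss.render_protein_image(sc, "tubulin", modality)
        profile = img[:, img.shape[1] // 2]
        peaks, _ = find_peaks(profile, prominence=0.05 * profile.max())
        assert (len(peaks) == 2) == expect_two_peaks
        if not expect_two_peaks:
            assert len(peaks) <= 1

    def test_zero_density_gives_zero_image(self):
        sc = ss.generate_scene(ss.SceneConfig(n_dendrites=0, include_soma=False, seed=0))
        img, _ = ss.render_protein_image(sc, "tubulin", "sted")
        assert np.all(img == 0)

    def test_fwhm_zero_is_proportional_to_density(self, default_scene):
        cfg = default_scene.config
        old = cfg.psf_fwhm_sted_nm, cfg.sted_pixel_nm
        cfg.psf_fwhm_sted_nm, cfg.sted_pixel_nm = 0.0, cfg.pixel_size_nm
        try:
            img, _ = ss.render_protein_image(default_scene, "tubulin", "sted", gain=2.0)
            assert np.allclose(img, 2.0 * default_scene.tubulin)
        finally:
            cfg.psf_fwhm_sted_nm, cfg.sted_pixel_nm = old


class TestMisalignment:
    def test_identity_transform_keeps_fiducials(self, default_scene):
        fr = ss.make_misaligned_frame(
            default_scene, transform=AffineTransform2D.identity(), maps={}
        )
        assert np.allclose(fr.src_fiducials.as_array(), fr.dst_fiducials.as_array())

    def test_pure_translation_offsets_each_fiducial(self, default_scene):
        t = AffineTransform2D.translation(100.0, -50.0)
        fr = ss.make_misaligned_frame(default_scene, transform=t, maps={})
        delta = fr.dst_fiducials.as_array() - fr.src_fiducials.as_array()
        assert np.allclose(delta, [100.0, -50.0])

    def test_rotation_plus_mirror_recovered_below_nanometre(self, default_scene):
        t = AffineTransform2D.similarity(
            rotation_deg=30.0, mirror=True, center=(5120.0, 5120.0)
        )
        fr = ss.make_misaligned_frame(default_scene, transform=t, maps={})
        fitted = fit_affine_from_fiducials(fr.src_fiducials, fr.dst_fiducials)
        residual = np.abs(
            fitted.apply(fr.src_fiducials.as_array()) - fr.dst_fiducials.as_array()
        ).max()
        assert residual < 1e-6
        assert fitted.is_mirror

    def test_warped_maps_carry_missing_mask(self, default_scene):
        maps = ss.render_element_maps(default_scene, noise=False, elements=["Zn"])
        fr = ss.make_misaligned_frame(default_scene, maps=maps, mirror=True, seed=11)
        zn = fr.maps["Zn"]
        assert zn.missing is not None
        assert zn.missing.sum() > 0  # corners leave the field after rotation


class TestGroupGeneration:
    def test_zero_effect_means_background_only_images(self):
        imgs = ss.generate_group_images(
            3, {"control": 1.0, "treated": 0.0}, seed=4, shape=(48, 48)
        )
        treated = [im for im in imgs if im.group == "treated"]
        control = [im for im in imgs if im.group == "control"]
        assert max(im.image.max() for im in treated) < min(im.image.max() for im in control)
        assert all(im.true_mean_intensity == 0 for im in treated)

    def test_reproducible_and_effect_scales_median(self):
        a = ss.generate_group_intensities(200, {"control": 1.0, "treated": 0.5}, seed=8)
        b = ss.generate_group_intensities(200, {"control": 1.0, "treated": 0.5}, seed=8)
        assert np.array_equal(a["treated"], b["treated"])
        ratio = np.median(a["treated"]) / np.median(a["control"])
        assert ratio == pytest.approx(0.5, rel=0.15)

    def test_empty_groups_rejected(self):
        with pytest.raises(ValueError):
            ss.generate_group_intensities(1, {"control": 1.0, "treated": 0.7})


def test_blank_measurements_sit_below_detection_limit(default_scene):
    blanks = ss.simulate_blank_measurements(default_scene.config, n=12, seed=5)
    from metalloscope.xrf_quant import lod_report

    table = lod_report(blanks, k=3, pixel_size_nm=40)
    # blanks were set to LOD/3, so measured blank means stay below the LOD
    assert (table["blank_mean_ng_mm2"] < table["lod_ng_mm2"] + 1e-12).all()
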