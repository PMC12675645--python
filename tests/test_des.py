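"""Weighted log subtraction, bone cancellation, augmentation and the grid."""

import numpy as np
import pytest

from fluorosynth.des import (
    GridConfig,
    PairSimulator,
    TrainingPair,
    augment_pair,
    bone_cancel_weight,
    bone_cancellation_residual,
    des_subtract,
    enumerate_training_grid,
    generate_dataset,
    simulate_training_set,
)
from fluorosynth.phantom import EnergySpec, Material, default_energy_specs
from fluorosynth.projection import AcquisitionAngles, RadiographImage


def img(arr, spacing=(1.0, 1.0), **meta):
    return RadiographImage(np.asarray(arr, dtype=float), spacing, dict(meta))


class TestDesSubtract:
    def test_omega_zero_returns_he(self, rng):
        he = img(rng.random((8, 8)) + 0.1)
        le = img(rng.random((8, 8)) + 0.1)
        out = des_subtract(he, le, omega=0.0)
        assert np.allclose(out.pixels, he.pixels, rtol=1e-12)

    def test_equal_uniform_images_cancel_at_omega_one(self):
        he = img(np.ones((4, 4)))
        out = des_subtract(he, img(np.ones((4, 4))), omega=1.0)
        assert np.allclose(out.meta["log_pixels"], 0.0)

    def test_single_ray_bone_algebra(self):
        # bone exponent 0.3 / 0.6, soft 0.2 / 0.3; omega = 0.5 leaves only
        # the soft-tissue term 0.2 - 0.5 * 0.3 = 0.05
        he = img([[np.exp(-(0.3 + 0.2))]])
        le = img([[np.exp(-(0.6 + 0.3))]])
        out = des_subtract(he, le, omega=0.5)
        assert out.meta["log_pixels"][0, 0] == pytest.approx(-0.05, abs=1e-12)

    def test_shape_mismatch_and_negative_pixels_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            des_subtract(img(np.ones((4, 4))), img(np.ones((4, 5))))
        with pytest.raises(ValueError, match="negative"):
            des_subtract(img(-np.ones((4, 4))), img(np.ones((4, 4))))


class TestBoneCancelWeight:
    @pytest.mark.parametrize(
        "rib_he,rib_le,expected", [(0.30, 0.60, 0.5), (0.4, 0.4, 1.0), (0.2, 0.8, 0.25)]
    )
    def test_ratio(self, rib_he, rib_le, expected):
        mk = lambda name, v: EnergySpec(name, {Material.AIR: 0.0, Material.RIB: v})
        assert bone_cancel_weight(mk("HE", rib_he), mk("LE", rib_le)) == pytest.approx(expected)

    def test_defaults_give_paper_weight(self):
        assert bone_cancel_weight(*default_energy_specs()) == 0.5

    def test_zero_le_bone_rejected(self):
        mk = lambda name, v: EnergySpec(name, {Material.AIR: 0.0, Material.RIB: v})
        with pytest.raises(ValueError):
            bone_cancel_weight(mk("HE", 0.1), mk("LE", 0.0))


class TestBoneCancellation:
    def test_des_identical_with_and_without_bone(self, tiny_config, tiny_detector):
        # the module's central oracle: at omega* the DES image is pixel-wise
        # independent of the bone pathlength
        res = bone_cancellation_residual(tiny_config, detector=tiny_detector)
        assert res < 1e-6

    def test_tumor_contrast_preserved_across_omega(self, tiny_config, tiny_detector):
        from dataclasses import replace

        from fluorosynth.phantom import tumor_center_mm
        from fluorosynth.projection import project_point, rotation_matrix

        he, le = default_energy_specs()
        mu = dict(le.mu)
        mu[Material.RIB] = mu[Material.SPINE] = 0.55  # omega* = 0.3/0.55
        specs = (he, EnergySpec("LE", mu))
        cfg = replace(tiny_config, energy_specs=specs)
        omega_star = bone_cancel_weight(*specs)

        def contrast(omega):
            sim = PairSimulator(cfg, tiny_detector, omega)
            pair = sim.pair(1, AcquisitionAngles(0, 0, 0))
            log_des = pair.des.meta["log_pixels"]
            r = rotation_matrix(AcquisitionAngles(0, 0, 0))
            c = tumor_center_mm(cfg, 1) / np.asarray(cfg.spacing) - 0.5
            pos = project_point(c, cfg.shape, r, tiny_detector)
            yy, xx = np.mgrid[: log_des.shape[0], : log_des.shape[1]]
            d = np.sqrt((yy - pos[0]) ** 2 + (xx - pos[1]) ** 2)
            disc = log_des[d <= 1.5].mean()
            annulus = log_des[(d > 2.5) & (d <= 4.5)].mean()
            return disc - annulus

        c_def, c_star = contrast(0.5), contrast(omega_star)
        assert c_def != 0
        assert abs(c_def - c_star) <= 0.6 * abs(c_star)


class TestAugmentation:
    def _pair(self, rng):
        se = img(rng.random((16, 16)) + 0.5)
        des = img(rng.random((16, 16)) + 0.5)
        return TrainingPair(se=se, des=des, provenance={"phase": 1})

    def test_identity_transform_via_forced_params(self, rng):
        pair = self._pair(rng)
        out = augment_pair(pair, seed=7, scale=1.0, crop_fraction=1.0)
        assert np.array_equal(out.se.pixels, pair.se.pixels)
        assert np.array_equal(out.des.pixels, pair.des.pixels)

    def test_seeded_determinism(self, rng):
        pair = self._pair(rng)
        a = augment_pair(pair, seed=3)
        b = augment_pair(pair, seed=3)
        assert np.array_equal(a.se.pixels, b.se.pixels)
        assert np.array_equal(a.des.pixels, b.des.pixels)
        assert a.provenance["augmentation"] == b.provenance["augmentation"]

    def test_half_crop_zeroes_border_frame(self, rng):
        pair = self._pair(rng)
        out = augment_pair(pair, seed=11, scale=1.0, crop_fraction=0.5)
        assert out.se.shape == pair.se.shape
        r0, c0, h, w = out.provenance["augmentation"].crop_box
        frame = np.ones_like(out.se.pixels, dtype=bool)
        frame[r0 : r0 + h, c0 : c0 + w] = False
        border = out.se.pixels[frame]
        assert np.mean(border == 0.0) >= 0.75

    def test_same_transform_on_both_members(self, rng):
        pair = self._pair(rng)
        out = augment_pair(pair, seed=5)
        rec = out.provenance["augmentation"]
        r0, c0, h, w = rec.crop_box
        frame = np.ones_like(out.se.pixels, dtype=bool)
        frame[r0 : r0 + h, c0 : c0 + w] = False
        assert np.all(out.se.pixels[frame] == 0.0)
        assert np.all(out.des.pixels[frame] == 0.0)
        assert out.se.shape == out.des.shape == pair.se.shape


class TestTrainingGrid:
    def test_default_grid_has_36000_entries(self):
        entries = enumerate_training_grid()
        assert len(entries) == 36000

    def test_reduced_grid_count_and_order(self):
        grid = GridConfig(
            gantry_start_deg=3.6, gantry_stop_deg=7.2, gantry_step_deg=3.6, couch_pairs=((0, 0),)
        )
        entries = enumerate_training_grid(grid)
        assert len(entries) == 20  # 2 gantry x 1 couch x 10 phases
        phases = [p for p, _ in entries]
        assert phases == sorted(phases)  # phase-major ordering

    def test_couch_angles_always_equal(self):
        for _, a in enumerate_training_grid()[::997]:
            assert a.theta == a.phi

    def test_gantry_range(self):
        g = GridConfig().gantry_angles()
        assert len(g) == 100
        assert g[0] == pytest.approx(3.6)
        assert g[-1] == pytest.approx(360.0)


class TestGenerateDataset:
    def test_writes_pairs_and_manifest(self, tiny_config, tiny_detector, tmp_path):
        grid = GridConfig(gantry_stop_deg=7.2, couch_pairs=((0, 0),), phases=(1, 2))
        out = generate_dataset(
            tiny_config, grid, tmp_path / "ds", master_seed=0, detector=tiny_detector
        )
        assert len(list((out / "pairs").glob("*_se.tif"))) == 4
        assert len(list((out / "pairs").glob("*_des.tif"))) == 4
        assert (out / "manifest.csv").exists()

    def test_emitted_pair_regenerates_from_manifest(self, tiny_config, tiny_detector):
        from fluorosynth.des import des_subtract

        grid = GridConfig(gantry_stop_deg=3.6, couch_pairs=((5, 5),), phases=(2,))
        pairs = simulate_training_set(
            tiny_config, grid, master_seed=0, detector=tiny_detector, augment=False
        )
        (pair,) = pairs
        sim = PairSimulator(tiny_config, tiny_detector)
        i_he, i_le = sim.projections(2, AcquisitionAngles(5, 5, 3.6))
        re_des = des_subtract(i_he, i_le, 0.5)
        assert np.allclose(pair.des.pixels, re_des.pixels, atol=1e-12)
        assert np.allclose(pair.se.pixels, i_he.pixels, atol=1e-12)
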