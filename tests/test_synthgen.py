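import numpy as np
import pytest

from stainshift.datamodel import RaterProfile, StudyConfig, MITOTIC_PHASES
from stainshift.synthgen import (PlacementError, default_rater_profiles,
                                 generate_cell_population, generate_study,
                                 make_deformation_field, render_image_pair,
                                 simulate_rater)


def perfect_profile(hindsight=0.0, phh3_sensitivity=1.0, fp=0.0, jitter=0.0,
                    rater_id="r00"):
    return RaterProfile(rater_id=rater_id,
                        sensitivity_by_phase={p: 1.0 for p in MITOTIC_PHASES},
                        phh3_sensitivity=phh3_sensitivity, fp_rate_lookalike=fp,
                        jitter_sd_um=jitter, hindsight_bias=hindsight)


class TestCellPopulation:
    def test_zero_mismatch_means_all_phh3_cells_visible(self):
        cfg = StudyConfig(mismatch_fraction=0.0, rng_seed=1)
        cells = generate_cell_population(cfg, "img_000")
        assert all(c.he_visible for c in cells if c.phh3_positive)

    def test_mismatch_fraction_binomial(self):
        # a large population of early-phase cells: the mismatch fraction is
        # recovered within binomial noise
        cfg = StudyConfig(image_size_px=4096, mismatch_fraction=0.56,
                          phase_mix={"prophase": 0.5, "prometaphase": 0.5,
                                     "metaphase": 0.0, "anaphase": 0.0,
                                     "telophase": 0.0},
                          rng_seed=2)
        cells = generate_cell_population(cfg, "img_000", counts=(1000, 0, 0))
        n_mismatch = sum(c.is_mismatch for c in cells)
        se = np.sqrt(1000 * 0.56 * 0.44)
        assert abs(n_mismatch - 560) <= 3 * se

    def test_determinism(self):
        cfg = StudyConfig(rng_seed=7)
        a = generate_cell_population(cfg, "img_003")
        b = generate_cell_population(cfg, "img_003")
        assert a == b

    def test_minimum_separation_one_nucleus_diameter(self):
        cfg = StudyConfig(rng_seed=3)
        cells = generate_cell_population(cfg, "img_000")
        pos = np.array([(c.x, c.y) for c in cells])
        d = np.hypot(pos[:, None, 0] - pos[None, :, 0],
                     pos[:, None, 1] - pos[None, :, 1])
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 7.5 / cfg.mpp - 1e-9

    def test_placement_error_names_constraint(self):
        cfg = StudyConfig(image_size_px=128, rng_seed=0)
        with pytest.raises(PlacementError, match="separation"):
            generate_cell_population(cfg, "img_000", counts=(200, 0, 0))

    def test_mismatch_conservation(self):
        cfg = StudyConfig(rng_seed=5)
        cells = generate_cell_population(cfg, "img_001")
        n_phh3 = sum(c.phh3_positive for c in cells)
        n_both = sum(c.phh3_positive and c.he_visible for c in cells)
        assert sum(c.is_mismatch for c in cells) == n_phh3 - n_both


class TestRendering:
    def test_mismatch_cell_pixel_identical_to_plain_nucleus(self):
        cfg = StudyConfig(image_size_px=256, deformation_max_px=0.0, rng_seed=0)
        from stainshift.datamodel import CellObject
        mismatch = CellObject("img_x_c0000", 128, 128, "prophase",
                              he_visible=False, phh3_positive=True,
                              phh3_intensity=0.9)
        plain = CellObject("img_x_c0000", 128, 128, "nonmitotic",
                           he_visible=False, phh3_positive=False)
        pair_m = render_image_pair([mismatch], cfg, "img_x")
        pair_p = render_image_pair([plain], cfg, "img_x")
        assert np.array_equal(pair_m.he_image, pair_p.he_image)
        # but the PHH3 rasters differ: the mismatch cell carries the signal
        assert not np.array_equal(pair_m.phh3_image, pair_p.phh3_image)

    def test_zero_deformation_blob_centroid_at_cell(self):
        # background speckle off: the measurement is the centroid of the
        # cell's own signal blob
        cfg = StudyConfig(image_size_px=256, deformation_max_px=0.0,
                          phh3_speckle_per_image=0.0, rng_seed=0)
        from stainshift.datamodel import CellObject
        cell = CellObject("img_y_c0000", 100.0, 140.0, "metaphase",
                          he_visible=True, phh3_positive=True, phh3_intensity=1.0)
        pair = render_image_pair([cell], cfg, "img_y")
        cy, cx = _brown_centroid(pair.phh3_image)
        assert abs(cx - 100.0) < 0.5 and abs(cy - 140.0) < 0.5

    def test_deformation_bounds_blob_displacement(self):
        d = 3.0
        cfg = StudyConfig(image_size_px=256, deformation_max_px=d,
                          phh3_speckle_per_image=0.0, rng_seed=9)
        from stainshift.datamodel import CellObject
        cell = CellObject("img_z_c0000", 120.0, 120.0, "metaphase",
                          he_visible=True, phh3_positive=True, phh3_intensity=1.0)
        pair = render_image_pair([cell], cfg, "img_z")
        cy, cx = _brown_centroid(pair.phh3_image)
        assert np.hypot(cx - 120.0, cy - 120.0) <= d + 0.5

    def test_deformation_field_magnitude_bounded(self, rng):
        f = make_deformation_field((64, 64), 2.5, rng)
        assert np.sqrt(f[0] ** 2 + f[1] ** 2).max() <= 2.5 + 1e-6

    def test_rasters_same_shape_and_bounds_check(self):
        cfg = StudyConfig(image_size_px=128, rng_seed=0)
        from stainshift.datamodel import CellObject
        pair = render_image_pair([], cfg, "img_e")
        assert pair.he_image.shape == pair.phh3_image.shape == (128, 128, 3)
        outside = CellObject("img_e_c0000", 500.0, 10.0, "nonmitotic",
                             he_visible=False, phh3_positive=False)
        with pytest.raises(ValueError, match="bounds"):
            render_image_pair([outside], cfg, "img_e")


def _brown_centroid(phh3_img):
    """Centroid of the brown (R >> B) pixels of a PHH3 raster."""
    img = phh3_img.astype(float)
    mask = (img[:, :, 0] - img[:, :, 2]) > 40
    ys, xs = np.nonzero(mask)
    return ys.mean(), xs.mean()


class TestRaterSimulation:
    def _pair(self, seed=4):
        cfg = StudyConfig(rng_seed=seed)
        from stainshift.synthgen import generate_cell_population
        cells = generate_cell_population(cfg, "img_000")
        return render_image_pair(cells, cfg, "img_000"), cfg

    def test_perfect_rater_p1_hits_exactly_the_visible_mfs(self):
        pair, _ = self._pair()
        anns = simulate_rater(pair, perfect_profile(), "P1",
                              np.random.default_rng(0))
        expected = {(c.x, c.y) for c in pair.cells if c.is_true_mf and c.he_visible}
        assert {(a.x, a.y) for a in anns} == expected
        assert all(a.cls == "MF" for a in anns)

    def test_no_hindsight_means_no_upgraded_mismatch(self):
        pair, _ = self._pair()
        anns = simulate_rater(pair, perfect_profile(hindsight=0.0), "P2",
                              np.random.default_rng(1))
        mismatch_pos = {(c.x, c.y) for c in pair.cells if c.is_mismatch}
        for a in anns:
            if (a.x, a.y) in mismatch_pos:
                assert a.cls == "PHH3_ONLY"

    def test_full_hindsight_upgrades_every_mismatch(self):
        pair, _ = self._pair()
        anns = simulate_rater(pair, perfect_profile(hindsight=1.0), "P2",
                              np.random.default_rng(2))
        mismatch_pos = {(c.x, c.y) for c in pair.cells if c.is_mismatch}
        hit = [a for a in anns if (a.x, a.y) in mismatch_pos]
        assert len(hit) == len(mismatch_pos)
        assert all(a.cls == "HE_AND_PHH3" for a in hit)

    def test_unknown_study_phase_rejected(self):
        pair, _ = self._pair()
        with pytest.raises(ValueError, match="study phase"):
            simulate_rater(pair, perfect_profile(), "P3", np.random.default_rng(0))

    def test_recall_recovery_within_binomial_error(self):
        # one rater with sensitivity 0.8, no jitter/FP, >= 500 metaphase cells
        cfg = StudyConfig(image_size_px=4096,
                          phase_mix={"prophase": 0.0, "prometaphase": 0.0,
                                     "metaphase": 1.0, "anaphase": 0.0,
                                     "telophase": 0.0},
                          mismatch_fraction=0.0, rng_seed=6)
        cells = generate_cell_population(cfg, "img_000", counts=(600, 0, 0))
        pair = render_image_pair(cells, cfg, "img_000")
        prof = RaterProfile("r00", {p: 0.8 for p in MITOTIC_PHASES},
                            phh3_sensitivity=0.8, fp_rate_lookalike=0.0,
                            jitter_sd_um=0.0, hindsight_bias=0.0)
        anns = simulate_rater(pair, prof, "P1", np.random.default_rng(3))
        recall = len(anns) / len(cells)
        se = np.sqrt(0.8 * 0.2 / len(cells))
        assert abs(recall - 0.8) <= 3 * se


class TestStudy:
    def test_structure_13_raters_two_phases(self):
        cfg = StudyConfig(n_images=4, n_raters=13, rng_seed=1)
        study = generate_study(cfg, render=False)
        raters = {a.rater_id for a in study.annotations}
        assert len(raters) == 13
        assert {a.study_phase for a in study.annotations} == {"P1", "P2"}
        assert len(study.images) == 4

    def test_determinism_same_seed(self):
        cfg = StudyConfig(n_images=3, rng_seed=2)
        a = generate_study(cfg, render=False)
        b = generate_study(cfg, render=False)
        assert a.annotations == b.annotations
        assert all(x.cells == y.cells for x, y in zip(a.images, b.images))

    def test_profile_count_must_match(self):
        cfg = StudyConfig(n_images=2, n_raters=13, rng_seed=0)
        with pytest.raises(ValueError, match="n_raters"):
            generate_study(cfg, profiles=default_rater_profiles(5), render=False)

    def test_perfect_raters_full_hindsight_double_consensus(self):
        # every visible MF reaches the P1 consensus; P2 adds every mismatch
        # cell, so the consensus grows by exactly the mismatch count
        from stainshift.consensus import derive_label_sets
        cfg = StudyConfig(n_images=4, mismatch_fraction=0.5, rng_seed=8)
        profiles = [perfect_profile(hindsight=1.0, rater_id=f"r{i:02d}")
                    for i in range(cfg.n_raters)]
        study = generate_study(cfg, profiles=profiles, render=False)
        ls = derive_label_sets(study)
        n_visible = sum(c.is_true_mf and c.he_visible
                        for im in study.images for c in im.cells)
        n_mismatch = sum(c.is_mismatch for im in study.images for c in im.cells)
        assert ls["he_only_labels"].count() == n_visible
        assert ls["phh3_assisted_labels"].count() == n_visible + n_mismatch
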