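import math

import numpy as np
import pytest

from stainshift.consensus import (build_consensus, clean_label_set,
                                  cluster_annotations, consensus_for_images,
                                  derive_label_sets, leave_one_out_consensus,
                                  newly_found_points)
from stainshift.datamodel import LabelSet, PointAnnotation, StudyConfig
from stainshift.synthgen import generate_study

from oracles import brute_force_clusters

MPP = 0.25
RADIUS_PX = 7.5 / MPP  # 30 px


def ann(rater, x, y, image="img_000", phase="P1", cls="MF"):
    return PointAnnotation(image, rater, phase, x, y, cls)


def random_annotations(rng, n, n_raters=13, scale=120.0, image="img_000"):
    return [ann(f"r{int(rng.integers(n_raters)):02d}",
                float(np.round(rng.uniform(0, scale), 3)),
                float(np.round(rng.uniform(0, scale), 3)), image)
            for _ in range(n)]


class TestClustering:
    def test_thirteen_identical_points_one_cluster(self):
        anns = [ann(f"r{i:02d}", 50.0, 50.0) for i in range(13)]
        clusters = cluster_annotations(anns, mpp=MPP)
        assert len(clusters) == 1
        assert clusters[0].support == 13
        assert clusters[0].centroid == (50.0, 50.0)

    def test_points_beyond_nucleus_diameter_stay_separate(self):
        # 7.6 um at 0.25 um/px = 30.4 px > the 30 px radius
        anns = [ann("r00", 10.0, 10.0), ann("r01", 10.0 + 7.6 / MPP, 10.0)]
        assert len(cluster_annotations(anns, mpp=MPP)) == 2
        # while 7.4 um merges
        anns = [ann("r00", 10.0, 10.0), ann("r01", 10.0 + 7.4 / MPP, 10.0)]
        assert len(cluster_annotations(anns, mpp=MPP)) == 1

    def test_same_rater_never_supports_twice(self):
        anns = [ann("r00", 50.0, 50.0), ann("r00", 51.0, 50.0),
                ann("r01", 50.5, 50.0)]
        clusters = cluster_annotations(anns, mpp=MPP)
        for c in clusters:
            raters = [m.rater_id for m in c.members]
            assert len(raters) == len(set(raters))

    def test_matches_brute_force_oracle(self, rng):
        for trial in range(60):
            anns = random_annotations(rng, int(rng.integers(2, 26)))
            clusters = cluster_annotations(anns, mpp=MPP)
            got = {frozenset(anns.index(m) for m in c.members) for c in clusters}
            expected = set(brute_force_clusters(anns, RADIUS_PX))
            assert got == expected

    def test_radius_scaling_invariance(self, rng):
        anns = random_annotations(rng, 20)
        halved = [ann(a.rater_id, a.x / 2, a.y / 2) for a in anns]
        c1 = cluster_annotations(anns, mpp=MPP)
        c2 = cluster_annotations(halved, mpp=2 * MPP)
        m1 = [sorted((m.rater_id, m.x) for m in c.members) for c in c1]
        m2 = [sorted((m.rater_id, m.x * 2) for m in c.members) for c in c2]
        assert m1 == m2

    def test_rejects_mixed_images_and_bad_mpp(self):
        with pytest.raises(ValueError, match="one image"):
            cluster_annotations([ann("r00", 1, 1), ann("r01", 1, 1, image="img_001")])
        with pytest.raises(ValueError, match="mpp"):
            cluster_annotations([ann("r00", 1, 1)], mpp=0)


class TestConsensusThresholds:
    def _clusters(self, n_supporters):
        return cluster_annotations([ann(f"r{i:02d}", 40.0, 40.0)
                                    for i in range(n_supporters)], mpp=MPP)

    def test_six_of_thirteen_retained(self):
        cons = build_consensus({"img_000": self._clusters(6)}, min_support=6)
        assert cons.count() == 1

    def test_five_of_thirteen_dropped(self):
        cons = build_consensus({"img_000": self._clusters(5)}, min_support=6)
        assert cons.count() == 0

    def test_min_support_one_keeps_everything(self, rng):
        anns = random_annotations(rng, 25)
        clusters = cluster_annotations(anns, mpp=MPP)
        cons = build_consensus({"img_000": clusters}, min_support=1)
        assert cons.count() == len(clusters)

    def test_monotonic_in_min_support(self, rng):
        anns = random_annotations(rng, 40, scale=60.0)
        clusters = cluster_annotations(anns, mpp=MPP)
        counts = [build_consensus({"img_000": clusters}, min_support=k).count()
                  for k in range(1, 14)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestLeaveOneOut:
    def test_thirteen_raters_threshold_six(self):
        anns = [ann(f"r{i:02d}", 20.0, 20.0) for i in range(13)]
        cons = leave_one_out_consensus(anns, "r00", mpp=MPP)
        assert cons.min_support == 6
        assert cons.count() == 1

    def test_three_raters_fraction_half_threshold_one(self):
        anns = [ann(f"r{i}", 20.0, 20.0) for i in range(3)]
        cons = leave_one_out_consensus(anns, "r0", mpp=MPP)
        assert cons.min_support == math.ceil(0.5 * 2) == 1

    def test_excluded_rater_never_contributes(self, rng):
        anns = random_annotations(rng, 50, scale=80.0)
        anns.append(ann("r99", 40.0, 40.0))
        cons_with = leave_one_out_consensus(anns, "r99", mpp=MPP)
        cons_without = leave_one_out_consensus(
            [a for a in anns if a.rater_id != "r99"] + [ann("r99", 999.0, 999.0)],
            "r99", mpp=MPP)
        assert cons_with.points == cons_without.points

    def test_errors(self):
        anns = [ann("r00", 1.0, 1.0)]
        with pytest.raises(ValueError, match="not present"):
            leave_one_out_consensus(anns, "r42", mpp=MPP)
        with pytest.raises(ValueError, match="2 raters"):
            leave_one_out_consensus(anns, "r00", mpp=MPP)


class TestLabelSets:
    def _study(self, **kw):
        cfg = StudyConfig(n_images=3, rng_seed=4, **kw)
        return generate_study(cfg, render=False), cfg

    def test_phh3_only_annotations_never_contribute(self):
        study, cfg = self._study()
        ls = derive_label_sets(study)
        # rebuild after dropping all PHH3_ONLY clicks: identical result
        filtered = [a for a in study.annotations if a.cls != "PHH3_ONLY"]
        study.annotations = filtered
        ls2 = derive_label_sets(study)
        assert ls["phh3_assisted_labels"].points == ls2["phh3_assisted_labels"].points

    def test_identical_phases_give_identical_sets(self):
        study, cfg = self._study()
        # replace P2 with a copy of P1 under the pooled classes
        p1 = study.annotations_for(study_phase="P1")
        mirrored = [PointAnnotation(a.image_id, a.rater_id, "P2", a.x, a.y,
                                    "HE_AND_PHH3") for a in p1]
        study.annotations = p1 + mirrored
        ls = derive_label_sets(study)
        assert ls["he_only_labels"].points == ls["phh3_assisted_labels"].points


class TestCleaning:
    def _sets(self):
        he = LabelSet("he_only_labels", {"img_000": [(10.0, 10.0, 8)]})
        phh3 = LabelSet("phh3_assisted_labels",
                        {"img_000": [(10.0, 10.0, 13), (200.0, 200.0, 7),
                                     (300.0, 300.0, 9)]})
        return he, phh3

    def test_all_recognizable_keeps_everything(self):
        he, phh3 = self._sets()
        dec = {("img_000", 1): ["recognizable"] * 3,
               ("img_000", 2): ["recognizable"] * 3}
        cleaned = clean_label_set(phh3, dec, he_only=he, mpp=MPP)
        assert cleaned.points == phh3.points

    def test_two_of_three_majority_removes(self):
        he, phh3 = self._sets()
        dec = {("img_000", 1): ["not_recognizable", "not_recognizable",
                                "recognizable"],
               ("img_000", 2): ["recognizable"] * 3}
        cleaned = clean_label_set(phh3, dec, he_only=he, mpp=MPP)
        assert cleaned.points["img_000"] == [(10.0, 10.0, 13), (300.0, 300.0, 9)]

    def test_points_in_he_only_are_protected(self):
        he, phh3 = self._sets()
        # no verdict needed for index 0 (present in the H&E-only set), and a
        # hostile verdict would not remove it either
        dec = {("img_000", 1): ["recognizable"] * 3,
               ("img_000", 2): ["recognizable"] * 3}
        cleaned = clean_label_set(phh3, dec, he_only=he, mpp=MPP)
        assert (10.0, 10.0, 13) in cleaned.points["img_000"]

    def test_missing_decision_is_an_error(self):
        he, phh3 = self._sets()
        with pytest.raises(ValueError, match="missing post-hoc"):
            clean_label_set(phh3, {("img_000", 1): ["recognizable"] * 3},
                            he_only=he, mpp=MPP)

    def test_truthful_oracle_recovers_visible_subset(self):
        from stainshift.experiments import cleaned_label_set_for
        cfg = StudyConfig(n_images=4, rng_seed=9)
        study = generate_study(cfg, render=False)
        ls = derive_label_sets(study)
        cleaned = cleaned_label_set_for(study, ls)
        # every removed point sits on a mismatch cell; every kept newly-found
        # point sits on an H&E-visible cell
        by_id = {im.image_id: im for im in study.images}
        new = newly_found_points(ls["he_only_labels"], ls["phh3_assisted_labels"],
                                 mpp=cfg.mpp)
        for img, idxs in new.items():
            cells = by_id[img].cells
            for i in idxs:
                x, y, s = ls["phh3_assisted_labels"].points[img][i]
                j = int(np.argmin([np.hypot(c.x - x, c.y - y) for c in cells]))
                kept = (x, y, s) in cleaned.points[img]
                assert kept == cells[j].he_visible
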