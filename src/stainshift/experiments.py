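"""Desk-scale experiment drivers: the full synthetic rater study and the
train-label x eval-label detector grid, wired together end to end.

These functions are the package's reference experiments; the test suite and
the reproduction script call them with fixed seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .agreement import (icc_avg_fixed_raters, mitotic_count_matrix,
                        paired_metric_test, rater_prf_table)
from .consensus import clean_label_set, derive_label_sets, newly_found_points
from .datamodel import LabelSet, StudyConfig, StudyDataset
from .detector import DetectorConfig, train_detector
from .evaluation import ResultGrid, evaluate_on_images
from .io import monte_carlo_splits
from .synthgen import generate_study

__all__ = ["desk_detector_config", "StudyReport", "run_rater_study",
           "truthful_posthoc_decisions", "cleaned_label_set_for",
           "run_detector_grid"]

P2_CLASSES = ("HE_AND_PHH3", "HE_ONLY")


def desk_detector_config(mode: str, seed: int = 0) -> DetectorConfig:
    """The desk-scale training configuration: tiny backbone, 128-px patches,
    nucleus-scale boxes, and a learning rate raised to 2e-3 so the small
    from-scratch network converges within a few hundred AdamW steps."""
    return DetectorConfig(mode=mode, backbone="tiny", patch_size=128,
                          box_size_px=32, lr=2e-3, iters_per_epoch=30,
                          max_epochs=8, patience=3, val_patches=12, seed=seed)


# ---------------------------------------------------------------------------
# rater-study statistics


@dataclass
class StudyReport:
    """Agreement statistics of one simulated two-phase study."""

    f1_p1: float
    f1_p2: float
    precision_p1: float
    precision_p2: float
    recall_p1: float
    recall_p2: float
    icc_p1: float
    icc_p2: float
    consensus_count_p1: int
    consensus_count_p2: int
    newly_found: int
    f1_test: object = None
    per_rater_p1: dict = field(default_factory=dict)
    per_rater_p2: dict = field(default_factory=dict)


def run_rater_study(config: StudyConfig, study: StudyDataset | None = None
                    ) -> tuple[StudyReport, StudyDataset, dict[str, LabelSet]]:
    """Simulate (or take) a study and compute all panel statistics: per-rater
    leave-one-out P/R/F1 for both phases, count ICC, consensus counts, the
    number of newly found consensus MFs, and the paired F1 test."""
    if study is None:
        study = generate_study(config, render=False)
    label_sets = derive_label_sets(study)
    p1 = study.annotations_for(study_phase="P1")
    p2 = study.annotations_for(study_phase="P2", classes=P2_CLASSES)
    t1 = rater_prf_table(p1, mpp=config.mpp)
    t2 = rater_prf_table(p2, mpp=config.mpp)
    raters = sorted(set(t1) & set(t2))
    f1_1 = [t1[r][2] for r in raters]
    f1_2 = [t2[r][2] for r in raters]
    m1 = mitotic_count_matrix(p1, study.image_ids, raters)
    m2 = mitotic_count_matrix(p2, study.image_ids, raters)
    new = newly_found_points(label_sets["he_only_labels"],
                             label_sets["phh3_assisted_labels"], mpp=config.mpp)
    report = StudyReport(
        f1_p1=float(np.mean(f1_1)), f1_p2=float(np.mean(f1_2)),
        precision_p1=float(np.mean([t1[r][0] for r in raters])),
        precision_p2=float(np.mean([t2[r][0] for r in raters])),
        recall_p1=float(np.mean([t1[r][1] for r in raters])),
        recall_p2=float(np.mean([t2[r][1] for r in raters])),
        icc_p1=icc_avg_fixed_raters(m1).icc_k,
        icc_p2=icc_avg_fixed_raters(m2).icc_k,
        consensus_count_p1=label_sets["he_only_labels"].count(),
        consensus_count_p2=label_sets["phh3_assisted_labels"].count(),
        newly_found=sum(len(v) for v in new.values()),
        f1_test=paired_metric_test(f1_1, f1_2, n_tests=3),
        per_rater_p1=t1, per_rater_p2=t2)
    return report, study, label_sets


# ---------------------------------------------------------------------------
# cleaned label set from a truthful post-hoc panel


def truthful_posthoc_decisions(study: StudyDataset, phh3_labels: LabelSet,
                               he_labels: LabelSet, n_experts: int = 3
                               ) -> dict[tuple[str, int], list[str]]:
    """Simulated post-hoc review with a truthful verdict oracle: a newly
    found consensus point is 'recognizable' iff its nearest ground-truth cell
    is H&E-visible.  All ``n_experts`` verdicts agree (the panel disagreement
    itself is exercised separately via Fleiss' kappa)."""
    by_id = {im.image_id: im for im in study.images}
    new = newly_found_points(he_labels, phh3_labels, mpp=study.config.mpp)
    decisions = {}
    for img, indices in new.items():
        cells = by_id[img].cells
        cx = np.array([c.x for c in cells])
        cy = np.array([c.y for c in cells])
        for i in indices:
            x, y, _s = phh3_labels.points[img][i]
            j = int(np.argmin(np.hypot(cx - x, cy - y)))
            verdict = "recognizable" if cells[j].he_visible else "not_recognizable"
            decisions[(img, i)] = [verdict] * n_experts
    return decisions


def cleaned_label_set_for(study: StudyDataset, label_sets: dict[str, LabelSet]
                          ) -> LabelSet:
    decisions = truthful_posthoc_decisions(study, label_sets["phh3_assisted_labels"],
                                           label_sets["he_only_labels"])
    return clean_label_set(label_sets["phh3_assisted_labels"], decisions,
                           he_only=label_sets["he_only_labels"],
                           mpp=study.config.mpp)


# ---------------------------------------------------------------------------
# the 2x2 detector grid


def run_detector_grid(seed: int, n_images: int = 200, n_splits: int = 2,
                      modes: tuple[str, ...] = ("single", "dual"),
                      train_label_names: tuple[str, ...] = (
                          "he_only_labels", "phh3_assisted_labels"),
                      image_size_px: int = 512,
                      verbose: bool = False) -> ResultGrid:
    """One seed of the desk-scale 2x2 experiment.

    Generates a rendered study of ``n_images``, derives the three label sets
    (H&E-only, PHH3-assisted, cleaned), builds ``n_splits`` Monte-Carlo
    splits, trains every (mode x training label set) detector on every split
    and evaluates it on the split's test images under all three label sets,
    sharing one inference pass per trained model.
    """
    config = StudyConfig(n_images=n_images, image_size_px=image_size_px,
                         rng_seed=seed)
    study = generate_study(config, render=True)
    label_sets = derive_label_sets(study)
    label_sets["cleaned_labels"] = cleaned_label_set_for(study, label_sets)
    splits = monte_carlo_splits(study.image_ids, n_splits=n_splits, seed=seed)
    by_id = {im.image_id: im for im in study.images}
    grid = ResultGrid()
    from .evaluation import operating_threshold

    for mode in modes:
        for train_name in train_label_names:
            for split in splits:
                cfg = desk_detector_config(mode,
                                           seed=seed * 1009 + split.split_index)
                model, _ = train_detector(cfg, split, label_sets[train_name],
                                          study.images)
                # desk-scale networks are miscalibrated near zero score, so
                # AP is computed over the detections the deployed model would
                # emit: those above its validation-selected operating point
                thr = operating_threshold(model,
                                          [by_id[i] for i in split.val[:8]],
                                          label_sets[train_name],
                                          tile=128, overlap=25)
                test_imgs = [by_id[i] for i in split.test]
                cache: dict = {}
                for eval_name in ("he_only_labels", "phh3_assisted_labels",
                                  "cleaned_labels"):
                    res = evaluate_on_images(model, test_imgs,
                                             label_sets[eval_name],
                                             tile=128, overlap=25,
                                             detections_cache=cache,
                                             score_threshold=thr)
                    grid.add(mode, train_name, eval_name, res.ap)
                    if verbose:
                        print(f"seed {seed} split {split.split_index} {mode} "
                              f"train={train_name} eval={eval_name}: "
                              f"AP {res.ap:.3f}")
    return grid


def merge_grids(grids: list[ResultGrid]) -> ResultGrid:
    out = ResultGrid()
    for g in grids:
        for key, aps in g.cells.items():
            out.cells.setdefault(key, []).extend(aps)
    return out


# ---------------------------------------------------------------------------
# latent decision-boundary shift


def run_latent_shift(seed: int, n_images: int = 16, n_cv_models: int = 3,
                     n_total: int = 600, feature_width: int = 64,
                     umap_seed: int | None = None) -> dict:
    """Decision-boundary shift between training-label conditions, per phase
    group.

    Trains ``n_cv_models`` single-stain detectors per training condition
    (H&E-only vs PHH3-assisted labels) on a rendered study, flags each
    mitotic figure as TP/FN by majority vote of the condition's models,
    embeds all mitotic figures with the mapping network + test-time
    augmentation, projects once with UMAP (one shared layout for both
    conditions), and measures how far the false-negative three-quartile
    region centroid moves between the conditions for each phase group.
    """
    from .evaluation import tiled_inference
    from .latent import (MappingConfig, embed_with_tta, extract_cell_patches,
                         phase_group, region_centroid, tpfn_flags,
                         train_mapping_network, umap_project)

    config = StudyConfig(n_images=n_images, rng_seed=seed)
    study = generate_study(config, render=True)
    label_sets = derive_label_sets(study)
    splits = monte_carlo_splits(study.image_ids, n_splits=n_cv_models, seed=seed)

    # per-condition cross-validation detections over all study images; each
    # model runs at its own validation-selected operating threshold
    from .evaluation import operating_threshold

    by_id = {im.image_id: im for im in study.images}
    per_condition: dict[str, list[dict]] = {}
    for train_name in ("he_only_labels", "phh3_assisted_labels"):
        models_dets = []
        for split in splits:
            cfg = desk_detector_config("single",
                                       seed=seed * 1009 + split.split_index)
            cfg.iters_per_epoch = 25
            cfg.max_epochs = 6
            cfg.patience = 2
            model, _ = train_detector(cfg, split, label_sets[train_name],
                                      study.images)
            thr = operating_threshold(model, [by_id[i] for i in split.val],
                                      label_sets[train_name],
                                      tile=128, overlap=25)
            dets = {im.image_id: tiled_inference(model, im, tile=128, overlap=25,
                                                 score_threshold=thr)
                    for im in study.images}
            models_dets.append(dets)
        per_condition[train_name] = models_dets

    cells = [c for im in study.images for c in im.cells if c.is_true_mf]
    patches = extract_cell_patches(study.images, cells, patch_size=32)

    # mapping network: strong-morphology mitoses vs plain nuclei
    strong = [c for im in study.images for c in im.cells
              if c.is_true_mf and c.he_visible]
    plain = [c for im in study.images for c in im.cells
             if c.phase == "nonmitotic"][:len(strong)]
    train_patches = extract_cell_patches(study.images, strong + plain, 32)
    train_labels = np.array([1] * len(strong) + [0] * len(plain))
    net = train_mapping_network(train_patches, train_labels,
                                MappingConfig(feature_width=feature_width,
                                              max_epochs=10, patience=3,
                                              seed=seed))

    es = embed_with_tta(cells, patches, net, n_total=max(n_total, len(cells)),
                        rng=np.random.default_rng([seed, 0x7E7]))
    es.projections = umap_project(es.embeddings,
                                  seed=seed if umap_seed is None else umap_seed)
    for name, models_dets in per_condition.items():
        es.tp_flags[name] = tpfn_flags(cells, models_dets, mpp=config.mpp)

    groups = np.array(es.representation_groups())
    shifts = {}
    for grp in ("pro/prometaphase", "metaphase", "ana/telophase"):
        centroids = {}
        for name in per_condition:
            fn_mask = (~es.tp_flags[name])[es.source_index] & (groups == grp)
            if fn_mask.sum() < 3:
                centroids[name] = None
            else:
                centroids[name] = region_centroid(es.projections[fn_mask])
        a = centroids["he_only_labels"]
        b = centroids["phh3_assisted_labels"]
        shifts[grp] = 0.0 if a is None or b is None \
            else float(np.hypot(*(a - b)))
    return {"shifts": shifts, "embedding_set": es, "study": study,
            "per_condition_flags": {k: v.copy() for k, v in es.tp_flags.items()}}
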