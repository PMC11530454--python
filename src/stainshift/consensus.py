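"""Distance-based consensus of multi-rater point annotations.

An annotation joins a cluster if it lies within one nucleus diameter
(7.5 µm) of the cluster centre, clusters are support-thresholded (at least
six of thirteen experts for the full panel; at least half of the remaining
experts for leave-one-out scoring), and label sets are derived by pooling
the PHH3-assisted annotation classes that imply H&E-recognisable morphology.

The clustering is greedy and incremental with a deterministic processing
order: annotations sorted by (rater_id, x, y); each annotation joins the
nearest existing cluster whose *current running-mean centroid* is within the
radius and which holds no annotation from the same rater yet (ties broken by
lowest cluster index), otherwise it founds a new cluster.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np

from .datamodel import (Cluster, ConsensusSet, LabelSet, PointAnnotation,
                        StudyDataset, NUCLEUS_DIAMETER_UM)

__all__ = ["cluster_annotations", "build_consensus", "leave_one_out_consensus",
           "derive_label_sets", "clean_label_set", "consensus_for_images"]


def cluster_annotations(annotations: list[PointAnnotation],
                        radius_um: float = NUCLEUS_DIAMETER_UM,
                        mpp: float = 0.25) -> list[Cluster]:
    """Greedy incremental clustering of one image's annotations."""
    if mpp <= 0:
        raise ValueError("mpp must be positive")
    image_ids = {a.image_id for a in annotations}
    if len(image_ids) > 1:
        raise ValueError("cluster_annotations expects annotations from one image")
    radius_px = radius_um / mpp

    ordered = sorted(annotations, key=lambda a: (a.rater_id, a.x, a.y))
    clusters: list[Cluster] = []
    centroids = np.empty((0, 2), dtype=float)
    sizes: list[int] = []
    rater_sets: list[set[str]] = []

    for ann in ordered:
        best = -1
        if len(clusters):
            d = np.hypot(centroids[:, 0] - ann.x, centroids[:, 1] - ann.y)
            order = np.argsort(d, kind="stable")  # nearest first, ties by index
            for j in order:
                if d[j] > radius_px:
                    break
                if ann.rater_id not in rater_sets[j]:
                    best = int(j)
                    break
        if best >= 0:
            clusters[best].members.append(ann)
            n = sizes[best] + 1
            centroids[best] = centroids[best] + (np.array([ann.x, ann.y])
                                                 - centroids[best]) / n
            sizes[best] = n
            rater_sets[best].add(ann.rater_id)
            clusters[best].centroid = (float(centroids[best, 0]),
                                       float(centroids[best, 1]))
        else:
            clusters.append(Cluster(centroid=(ann.x, ann.y), members=[ann]))
            centroids = np.vstack([centroids, [ann.x, ann.y]])
            sizes.append(1)
            rater_sets.append({ann.rater_id})
    return clusters


def build_consensus(clusters_by_image: dict[str, list[Cluster]] | list[Cluster],
                    min_support: int, radius_um: float = NUCLEUS_DIAMETER_UM
                    ) -> ConsensusSet:
    """Retain cluster centroids supported by at least ``min_support`` raters."""
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if isinstance(clusters_by_image, list):
        by_image: dict[str, list[Cluster]] = defaultdict(list)
        for c in clusters_by_image:
            img = c.members[0].image_id if c.members else ""
            by_image[img].append(c)
        clusters_by_image = dict(by_image)
    points = {}
    for img, clusters in clusters_by_image.items():
        points[img] = [(c.centroid[0], c.centroid[1], c.support)
                       for c in clusters if c.support >= min_support]
    return ConsensusSet(points=points, min_support=min_support, radius_um=radius_um)


def consensus_for_images(annotations: list[PointAnnotation], min_support: int,
                         radius_um: float = NUCLEUS_DIAMETER_UM,
                         mpp: float = 0.25) -> ConsensusSet:
    """Cluster per image, then support-threshold: the full-panel consensus."""
    by_image: dict[str, list[PointAnnotation]] = defaultdict(list)
    for a in annotations:
        by_image[a.image_id].append(a)
    clusters = {img: cluster_annotations(anns, radius_um=radius_um, mpp=mpp)
                for img, anns in by_image.items()}
    return build_consensus(clusters, min_support=min_support, radius_um=radius_um)


def leave_one_out_consensus(annotations: list[PointAnnotation], excluded_rater: str,
                            radius_um: float = NUCLEUS_DIAMETER_UM,
                            mpp: float = 0.25, support_fraction: float = 0.5
                            ) -> ConsensusSet:
    """Consensus of all raters except one; threshold = ceil(f * (k - 1)).

    For a 13-expert panel this is 6: at least half of the remaining experts.
    """
    raters = {a.rater_id for a in annotations}
    if excluded_rater not in raters:
        raise ValueError(f"rater {excluded_rater!r} not present in annotations")
    if len(raters) < 2:
        raise ValueError("leave-one-out consensus needs at least 2 raters")
    remaining = [a for a in annotations if a.rater_id != excluded_rater]
    min_support = math.ceil(support_fraction * (len(raters) - 1))
    return consensus_for_images(remaining, min_support=min_support,
                                radius_um=radius_um, mpp=mpp)


def derive_label_sets(study: StudyDataset, min_support: int | None = None,
                      radius_um: float = NUCLEUS_DIAMETER_UM
                      ) -> dict[str, LabelSet]:
    """Build the two ground-truth definitions of the two study phases.

    ``he_only_labels``: full-panel consensus of the first-phase annotations.
    ``phh3_assisted_labels``: full-panel consensus of the second-phase
    annotations of the classes implying H&E-recognisable morphology
    (``HE_AND_PHH3`` and ``HE_ONLY``), pooled before clustering;
    ``PHH3_ONLY`` clicks never contribute support.
    """
    if min_support is None:
        # half of the *remaining* experts, the same threshold the one-vs-all
        # scoring uses: 6 for a 13-expert panel
        min_support = max(math.ceil((study.config.n_raters - 1) / 2.0), 1)
    mpp = study.config.mpp
    p1 = study.annotations_for(study_phase="P1")
    p2 = study.annotations_for(study_phase="P2", classes=("HE_AND_PHH3", "HE_ONLY"))
    he_cons = consensus_for_images(p1, min_support=min_support,
                                   radius_um=radius_um, mpp=mpp)
    phh3_cons = consensus_for_images(p2, min_support=min_support,
                                     radius_um=radius_um, mpp=mpp)
    # images with no retained points still appear with empty lists
    for img in study.image_ids:
        he_cons.points.setdefault(img, [])
        phh3_cons.points.setdefault(img, [])
    return {"he_only_labels": LabelSet("he_only_labels", he_cons.points),
            "phh3_assisted_labels": LabelSet("phh3_assisted_labels",
                                             phh3_cons.points)}


def newly_found_points(he_only: LabelSet, phh3_assisted: LabelSet,
                       radius_um: float = NUCLEUS_DIAMETER_UM, mpp: float = 0.25
                       ) -> dict[str, list[int]]:
    """Indices of PHH3-assisted consensus points absent from the H&E-only set."""
    radius_px = radius_um / mpp
    out: dict[str, list[int]] = {}
    for img, pts in phh3_assisted.points.items():
        ref = np.array([(x, y) for x, y, _ in he_only.points.get(img, [])],
                       dtype=float).reshape(-1, 2)
        new = []
        for i, (x, y, _) in enumerate(pts):
            if ref.shape[0] == 0 or np.hypot(ref[:, 0] - x,
                                             ref[:, 1] - y).min() > radius_px:
                new.append(i)
        out[img] = new
    return out


def clean_label_set(phh3_assisted: LabelSet,
                    posthoc_decisions: dict[tuple[str, int], list[str]],
                    he_only: LabelSet | None = None,
                    radius_um: float = NUCLEUS_DIAMETER_UM, mpp: float = 0.25
                    ) -> LabelSet:
    """Remove newly-found points a post-hoc expert majority judged
    non-recognisable in H&E.

    ``posthoc_decisions`` maps (image_id, point_index in the PHH3-assisted
    set) to at least three verdicts from {"recognizable", "not_recognizable"};
    a point is removed when a majority (e.g. 2 of 3) says not recognisable.
    Points that already exist in the H&E-only label set are never removed and
    need no verdict.
    """
    protected: dict[str, set[int]] = {}
    if he_only is not None:
        new = newly_found_points(he_only, phh3_assisted, radius_um=radius_um, mpp=mpp)
        protected = {img: set(range(len(pts))) - set(new.get(img, []))
                     for img, pts in phh3_assisted.points.items()}
    points = {}
    for img, pts in phh3_assisted.points.items():
        kept = []
        for i, pt in enumerate(pts):
            if img in protected and i in protected[img]:
                kept.append(pt)
                continue
            verdicts = posthoc_decisions.get((img, i))
            if verdicts is None or len(verdicts) < 3:
                raise ValueError(
                    f"missing post-hoc decision for newly-found point {i} of "
                    f"image {img!r} (need >= 3 verdicts)")
            n_not = sum(v == "not_recognizable" for v in verdicts)
            if n_not <= len(verdicts) / 2:
                kept.append(pt)
        points[img] = kept
    return LabelSet("cleaned_labels", points)
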