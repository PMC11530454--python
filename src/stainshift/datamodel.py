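"""Canonical domain types shared by all stainshift modules.

Coordinate convention: all positions are 0-based pixel centres in the H&E
frame, x growing rightwards and y growing downwards.  Physical quantities
(the clustering radius, annotation jitter) are specified in microns and
converted with the image's microns-per-pixel (mpp) at the point of use;
micron and pixel units are never mixed inside a stored structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

MITOTIC_PHASES = ("prophase", "prometaphase", "metaphase", "anaphase", "telophase")
ALL_PHASES = MITOTIC_PHASES + ("lookalike", "nonmitotic")

ANNOTATION_CLASSES = ("MF", "HE_AND_PHH3", "HE_ONLY", "PHH3_ONLY")
STUDY_PHASES = ("P1", "P2")

#: nucleus diameter used throughout as the clustering / matching radius
NUCLEUS_DIAMETER_UM = 7.5


@dataclass(frozen=True)
class CellObject:
    """A ground-truth cell in a synthetic image pair.

    ``he_visible`` says whether the cell is rendered with distinct mitotic
    morphology in the H&E raster; ``phh3_positive`` whether it carries an
    IHC signal in the PHH3 raster.  A *mismatch cell* is PHH3-positive but
    not H&E-visible: the information that drives the interpretation shift.
    """

    id: str
    x: float
    y: float
    phase: str
    he_visible: bool
    phh3_positive: bool
    phh3_intensity: float = 0.0

    def __post_init__(self):
        if self.phase not in ALL_PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.phase in ("lookalike", "nonmitotic") and self.phh3_positive:
            raise ValueError("lookalike/nonmitotic cells cannot be PHH3-positive")
        if self.phase == "lookalike" and not self.he_visible:
            raise ValueError("lookalikes mimic MF morphology and must be he_visible")
        if self.is_mismatch and self.phase not in ("prophase", "prometaphase"):
            raise ValueError("only prophase/prometaphase cells may be mismatch cells")
        if not 0.0 <= self.phh3_intensity <= 1.0:
            raise ValueError("phh3_intensity must lie in [0, 1]")

    @property
    def is_true_mf(self) -> bool:
        return self.phase in MITOTIC_PHASES

    @property
    def is_mismatch(self) -> bool:
        return self.phh3_positive and not self.he_visible


@dataclass
class ImagePair:
    """Co-registered H&E and PHH3 rasters with shared ground truth.

    ``deformation`` is a smooth per-pixel displacement field (2, H, W) in
    pixels applied when rendering the PHH3 raster, emulating residual
    registration error between the two scans.
    """

    image_id: str
    he_image: np.ndarray
    phh3_image: np.ndarray
    mpp: float
    cells: list[CellObject]
    deformation: np.ndarray | None = None

    def __post_init__(self):
        if self.he_image.shape != self.phh3_image.shape:
            raise ValueError("H&E and PHH3 rasters must have identical dimensions")
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")


@dataclass(frozen=True)
class RaterProfile:
    """Per-rater behaviour: detection cutoffs, noise, and hindsight bias.

    ``sensitivity_by_phase`` gives the probability of annotating an
    H&E-visible mitotic figure of each phase when viewing H&E only;
    ``phh3_sensitivity`` applies to PHH3-positive cells once the IHC overlay
    is available; ``hindsight_bias`` is the probability that a rater calls a
    morphology-free (mismatch) cell H&E-identifiable after seeing its PHH3
    signal.
    """

    rater_id: str
    sensitivity_by_phase: dict[str, float]
    phh3_sensitivity: float
    fp_rate_lookalike: float
    jitter_sd_um: float
    hindsight_bias: float

    def __post_init__(self):
        probs = list(self.sensitivity_by_phase.values()) + [
            self.phh3_sensitivity, self.fp_rate_lookalike, self.hindsight_bias]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.jitter_sd_um < 0:
            raise ValueError("jitter_sd_um must be >= 0")


@dataclass
class StudyConfig:
    """Generative configuration of a synthetic annotation study."""

    n_images: int = 20
    image_size_px: int = 512
    mpp: float = 0.25
    mf_per_image: float = 20.0          # Poisson mean of true mitotic figures
    lookalike_per_image: float = 10.0   # Poisson mean of MF lookalikes
    nonmitotic_per_image: float = 70.0  # Poisson mean of plain nuclei
    phase_mix: dict[str, float] = field(default_factory=lambda: {
        "prophase": 0.24, "prometaphase": 0.24, "metaphase": 0.37,
        "anaphase": 0.075, "telophase": 0.075})
    mismatch_fraction: float = 172.0 / 308.0
    telophase_phh3_rate: float = 0.7
    deformation_max_px: float = 3.0
    phh3_speckle_per_image: float = 40.0  # nonspecific DAB background blobs
    n_raters: int = 13
    rng_seed: int = 0

    def __post_init__(self):
        total = sum(self.phase_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("phase_mix must sum to 1")
        for f in (self.mismatch_fraction, self.telophase_phh3_rate):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


@dataclass(frozen=True)
class PointAnnotation:
    """One rater's click on one image in one study phase."""

    image_id: str
    rater_id: str
    study_phase: str
    x: float
    y: float
    cls: str

    def __post_init__(self):
        if self.study_phase not in STUDY_PHASES:
            raise ValueError(f"unknown study phase {self.study_phase!r}")
        if self.cls not in ANNOTATION_CLASSES:
            raise ValueError(f"unknown annotation class {self.cls!r}")
        if self.study_phase == "P1" and self.cls != "MF":
            raise ValueError("P1 annotations must have cls=MF")
        if self.study_phase == "P2" and self.cls == "MF":
            raise ValueError("P2 annotations must use the three-way class labels")


@dataclass
class Cluster:
    """A consensus cluster of point annotations from distinct raters."""

    centroid: tuple[float, float]
    members: list[PointAnnotation] = field(default_factory=list)

    @property
    def supporting_raters(self) -> set[str]:
        return {m.rater_id for m in self.members}

    @property
    def support(self) -> int:
        return len(self.supporting_raters)


@dataclass
class ConsensusSet:
    """Support-thresholded cluster centroids per image."""

    points: dict[str, list[tuple[float, float, int]]]
    min_support: int
    radius_um: float

    def count(self, image_id: str | None = None) -> int:
        if image_id is not None:
            return len(self.points.get(image_id, []))
        return sum(len(v) for v in self.points.values())


@dataclass
class LabelSet:
    """A named ground-truth definition: consensus points per image."""

    name: str
    points: dict[str, list[tuple[float, float, int]]]

    def count(self) -> int:
        return sum(len(v) for v in self.points.values())


@dataclass(frozen=True)
class Split:
    """One Monte-Carlo train/validation/test partition of image ids."""

    split_index: int
    train: tuple[str, ...]
    val: tuple[str, ...]
    test: tuple[str, ...]


@dataclass(frozen=True)
class Detection:
    """Detector output in global image coordinates."""

    x: float
    y: float
    box: tuple[float, float, float, float]
    score: float

    def __post_init__(self):
        x0, y0, x1, y1 = self.box
        if not (x0 < x1 and y0 < y1):
            raise ValueError("degenerate detection box")
        if not np.isfinite(self.score):
            raise ValueError("non-finite detection score")


@dataclass
class Matching:
    """One-to-one point matching between predictions and references."""

    pairs: list[tuple[int, int]]
    unmatched_predictions: list[int]
    unmatched_references: list[int]


@dataclass
class StudyDataset:
    """Everything one synthetic study produces."""

    config: StudyConfig
    images: list[ImagePair]
    annotations: list[PointAnnotation]
    profiles: list[RaterProfile]

    def annotations_for(self, image_id: str | None = None,
                        study_phase: str | None = None,
                        rater_id: str | None = None,
                        classes: Iterable[str] | None = None) -> list[PointAnnotation]:
        cls_set = set(classes) if classes is not None else None
        out = []
        for a in self.annotations:
            if image_id is not None and a.image_id != image_id:
                continue
            if study_phase is not None and a.study_phase != study_phase:
                continue
            if rater_id is not None and a.rater_id != rater_id:
                continue
            if cls_set is not None and a.cls not in cls_set:
                continue
            out.append(a)
        return out

    @property
    def image_ids(self) -> list[str]:
        return [im.image_id for im in self.images]


__all__ = [
    "ALL_PHASES", "ANNOTATION_CLASSES", "MITOTIC_PHASES", "NUCLEUS_DIAMETER_UM",
    "STUDY_PHASES", "CellObject", "Cluster", "ConsensusSet", "Detection",
    "ImagePair", "LabelSet", "Matching", "PointAnnotation", "RaterProfile",
    "Split", "StudyConfig", "StudyDataset", "replace",
]
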