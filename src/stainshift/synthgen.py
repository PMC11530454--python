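"""Synthetic co-registered H&E/PHH3 image pairs and multi-expert annotations.

The generator reproduces the *information structure* of a dual-stain
mitotic-figure annotation study rather than its visual appearance:

* true mitotic figures of five phases, a configurable fraction of the
  prophase/prometaphase population being *mismatch cells* — PHH3-positive
  but without any mitotic morphology in H&E (rendered pixel-identically to
  plain non-mitotic nuclei);
* telophases that may lack a PHH3 signal despite clear H&E morphology;
* mitotic-figure lookalikes that mimic MF morphology but are not mitoses;
* a panel of raters, each with per-phase sensitivities, a lookalike
  false-positive rate, localisation jitter, PHH3 sensitivity and a
  hindsight-bias probability, annotating in two phases (H&E only, then
  PHH3-assisted) with independent random streams per phase (washout);
* a smooth residual deformation field displacing the PHH3 rendering, as
  left over by slide re-staining and registration.

Rendering is stylised (flat background, disc nuclei, glyph morphology); the
contract that matters is that mismatch cells are indistinguishable from
non-mitotic nuclei in the H&E raster.
"""

from __future__ import annotations

import zlib

import numpy as np
from scipy import ndimage

from .datamodel import (MITOTIC_PHASES, CellObject, ImagePair, PointAnnotation,
                        RaterProfile, StudyConfig, StudyDataset,
                        NUCLEUS_DIAMETER_UM)

__all__ = ["PlacementError", "default_rater_profiles", "generate_cell_population",
           "render_image_pair", "simulate_rater", "generate_study"]


class PlacementError(RuntimeError):
    """Image too small to place the requested cells at minimum separation."""


#: In the PHH3-assisted phase, a rater facing an IHC-negative lookalike mostly
#: trusts the missing signal; the lookalike false-positive rate is scaled by
#: this factor in P2.
P2_LOOKALIKE_SUPPRESSION = 0.3


def _image_rng(config: StudyConfig, image_id: str, salt: int = 0) -> np.random.Generator:
    """Deterministic per-image random stream derived from the study seed."""
    return np.random.default_rng([config.rng_seed, zlib.crc32(image_id.encode()), salt])


# ---------------------------------------------------------------------------
# cell population


def generate_cell_population(config: StudyConfig, image_id: str,
                             rng: np.random.Generator | None = None,
                             counts: tuple[int, int, int] | None = None
                             ) -> list[CellObject]:
    """Draw and place the cells of one image.

    Counts are Poisson draws around the configured means (or fixed via
    ``counts`` = (n_mf, n_lookalike, n_nonmitotic)).  Positions are uniform
    with a minimum pairwise separation of one nucleus diameter (7.5 µm) so
    that distance clustering can never merge two distinct cells.
    """
    rng = rng if rng is not None else _image_rng(config, image_id)
    if counts is None:
        n_mf = int(rng.poisson(config.mf_per_image))
        n_look = int(rng.poisson(config.lookalike_per_image))
        n_non = int(rng.poisson(config.nonmitotic_per_image))
    else:
        n_mf, n_look, n_non = counts

    phases = list(config.phase_mix.keys())
    pvec = np.array([config.phase_mix[p] for p in phases], dtype=float)
    pvec = pvec / pvec.sum()

    size = config.image_size_px
    sep_px = NUCLEUS_DIAMETER_UM / config.mpp
    margin = sep_px / 2.0
    if size <= 2 * margin:
        raise PlacementError(
            f"image of {size}px cannot hold cells at minimum separation "
            f"{sep_px:.1f}px (one nucleus diameter, {NUCLEUS_DIAMETER_UM} µm)")

    total = n_mf + n_look + n_non
    positions = _place_points(total, size, sep_px, margin, rng)

    cells: list[CellObject] = []
    idx = 0
    for i in range(n_mf):
        phase = phases[rng.choice(len(phases), p=pvec)]
        x, y = positions[idx]; idx += 1
        he_visible = True
        if phase in ("prophase", "prometaphase"):
            he_visible = rng.random() >= config.mismatch_fraction
        phh3_positive = True
        if phase == "telophase":
            phh3_positive = rng.random() < config.telophase_phh3_rate
        if not he_visible and not phh3_positive:
            he_visible = True  # a cell invisible in both stains cannot occur
        intensity = float(rng.uniform(0.6, 1.0)) if phh3_positive else 0.0
        cells.append(CellObject(id=f"{image_id}_c{len(cells):04d}", x=x, y=y,
                                phase=phase, he_visible=he_visible,
                                phh3_positive=phh3_positive,
                                phh3_intensity=intensity))
    for i in range(n_look):
        x, y = positions[idx]; idx += 1
        cells.append(CellObject(id=f"{image_id}_c{len(cells):04d}", x=x, y=y,
                                phase="lookalike", he_visible=True,
                                phh3_positive=False))
    for i in range(n_non):
        x, y = positions[idx]; idx += 1
        cells.append(CellObject(id=f"{image_id}_c{len(cells):04d}", x=x, y=y,
                                phase="nonmitotic", he_visible=False,
                                phh3_positive=False))
    return cells


def _place_points(n: int, size: int, sep: float, margin: float,
                  rng: np.random.Generator, max_attempts_per_point: int = 500
                  ) -> np.ndarray:
    """Dart-throwing placement with minimum pairwise separation."""
    pts = np.empty((n, 2), dtype=float)
    sep2 = sep * sep
    for i in range(n):
        for attempt in range(max_attempts_per_point):
            x = rng.uniform(margin, size - 1 - margin)
            y = rng.uniform(margin, size - 1 - margin)
            if i == 0:
                break
            d2 = (pts[:i, 0] - x) ** 2 + (pts[:i, 1] - y) ** 2
            if d2.min() >= sep2:
                break
        else:
            raise PlacementError(
                f"could not place cell {i + 1}/{n} in a {size}px image at "
                f"minimum separation {sep:.1f}px after {max_attempts_per_point} "
                "attempts")
        pts[i] = (x, y)
    return pts


# ---------------------------------------------------------------------------
# rendering

_HE_BACKGROUND = np.array([236, 214, 223], dtype=np.float32)   # eosin-pink
_HE_NUCLEUS = np.array([112, 90, 168], dtype=np.float32)       # hematoxylin
_HE_MF = np.array([52, 34, 92], dtype=np.float32)              # condensed chromatin
_HE_MF_FAINT = np.array([86, 66, 136], dtype=np.float32)       # early-phase subtle
_HE_MF_CORE = np.array([50, 34, 96], dtype=np.float32)
_PHH3_BACKGROUND = np.array([246, 242, 236], dtype=np.float32)
_PHH3_NUCLEUS = np.array([206, 202, 226], dtype=np.float32)    # faint counterstain
_PHH3_BROWN = np.array([130, 74, 28], dtype=np.float32)        # DAB signal


def _disc_mask(shape: tuple[int, int], cx: float, cy: float, r: float) -> np.ndarray:
    h, w = shape
    x0, x1 = max(int(cx - r) - 1, 0), min(int(cx + r) + 2, w)
    y0, y1 = max(int(cy - r) - 1, 0), min(int(cy + r) + 2, h)
    if x0 >= x1 or y0 >= y1:
        return np.zeros((0, 0), dtype=bool), (0, 0)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    return ((xx - cx) ** 2 + (yy - cy) ** 2) <= r * r, (y0, x0)


def _stamp_disc(img: np.ndarray, cx: float, cy: float, r: float,
                color: np.ndarray) -> None:
    mask, (y0, x0) = _disc_mask(img.shape[:2], cx, cy, r)
    if mask.size:
        sub = img[y0:y0 + mask.shape[0], x0:x0 + mask.shape[1]]
        sub[mask] = color


def _stamp_ellipse(img: np.ndarray, cx: float, cy: float, a: float, b: float,
                   angle: float, color: np.ndarray) -> None:
    h, w = img.shape[:2]
    r = max(a, b)
    x0, x1 = max(int(cx - r) - 1, 0), min(int(cx + r) + 2, w)
    y0, y1 = max(int(cy - r) - 1, 0), min(int(cy + r) + 2, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = (xx - cx) * ca + (yy - cy) * sa
    v = -(xx - cx) * sa + (yy - cy) * ca
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    sub = img[y0:y1, x0:x1]
    sub[mask] = color


def _stamp_nucleus(img: np.ndarray, cx: float, cy: float, r: float) -> None:
    """Plain (non-mitotic) nucleus: the SAME code path renders mismatch
    cells, which makes them pixel-identical to ordinary nuclei in H&E."""
    _stamp_disc(img, cx, cy, r, _HE_NUCLEUS)


def _stamp_mf_glyph(img: np.ndarray, cell: CellObject, r: float,
                    angle: float, color: np.ndarray) -> None:
    """Distinct mitotic-figure morphology, varying with phase.

    Early phases (prophase/prometaphase) get a deliberately subtle glyph —
    a slightly condensed disc with a small dark core — mirroring the fact
    that the same cells are the ones human raters most often miss.
    """
    if cell.phase in ("prophase", "prometaphase"):
        _stamp_disc(img, cell.x, cell.y, 0.80 * r, _HE_MF_FAINT)
        _stamp_disc(img, cell.x, cell.y, 0.52 * r, _HE_MF_CORE)
    elif cell.phase in ("metaphase", "lookalike"):
        _stamp_ellipse(img, cell.x, cell.y, 1.1 * r, 0.45 * r, angle, color)
    else:  # anaphase / telophase: two separating lobes
        dx, dy = 0.62 * r * np.cos(angle), 0.62 * r * np.sin(angle)
        _stamp_disc(img, cell.x - dx, cell.y - dy, 0.55 * r, color)
        _stamp_disc(img, cell.x + dx, cell.y + dy, 0.55 * r, color)


def make_deformation_field(shape: tuple[int, int], max_px: float,
                           rng: np.random.Generator, grid: int = 4) -> np.ndarray:
    """Smooth random displacement field with magnitude bounded by ``max_px``."""
    h, w = shape
    field = np.zeros((2, h, w), dtype=np.float32)
    if max_px <= 0:
        return field
    coarse = rng.normal(size=(2, grid, grid))
    for c in range(2):
        field[c] = ndimage.zoom(coarse[c], (h / grid, w / grid), order=3,
                                mode="nearest", grid_mode=True)
    mag = np.sqrt(field[0] ** 2 + field[1] ** 2)
    peak = float(mag.max())
    if peak > 0:
        field *= max_px / peak
    return field


def render_image_pair(cells: list[CellObject], config: StudyConfig,
                      image_id: str = "img") -> ImagePair:
    """Render the H&E and PHH3 rasters for one cell population.

    H&E: flat eosin background, hematoxylin discs for every cell, and an MF
    glyph only where ``he_visible`` (lookalikes get a paler glyph).  PHH3:
    faint counterstained nuclei plus brown blobs of the configured intensity
    where ``phh3_positive``, displaced by the residual deformation field.
    """
    size = config.image_size_px
    for c in cells:
        if not (0 <= c.x < size and 0 <= c.y < size):
            raise ValueError(f"cell {c.id} outside image bounds")
    rng = _image_rng(config, image_id, salt=1)
    r = 0.5 * NUCLEUS_DIAMETER_UM / config.mpp

    he = np.empty((size, size, 3), dtype=np.float32)
    he[...] = _HE_BACKGROUND
    phh3 = np.empty((size, size, 3), dtype=np.float32)
    phh3[...] = _PHH3_BACKGROUND

    deform = make_deformation_field((size, size), config.deformation_max_px,
                                    rng=_image_rng(config, image_id, salt=2))

    # nonspecific DAB background: small brown speckles not tied to any cell,
    # as ubiquitous in real IHC; a detector cannot treat "brown signal" alone
    # as proof of mitosis
    n_speckles = rng.poisson(config.phh3_speckle_per_image)
    for _ in range(n_speckles):
        sx, sy = rng.uniform(0, size - 1, 2)
        sr = rng.uniform(2.0, 6.0)
        inten = rng.uniform(0.4, 0.9)
        color = (1 - inten) * _PHH3_BACKGROUND + inten * _PHH3_BROWN
        _stamp_disc(phh3, sx, sy, sr, color)

    angles = {c.id: float(rng.uniform(0, np.pi)) for c in cells}
    for c in cells:
        if c.he_visible:
            # lookalikes share the metaphase glyph exactly: in H&E alone they
            # are indistinguishable from true mitoses, only the missing PHH3
            # signal tells them apart
            _stamp_nucleus(he, c.x, c.y, r)
            _stamp_mf_glyph(he, c, r, angles[c.id], _HE_MF)
        else:
            # mismatch cells and plain nuclei share one rendering path
            _stamp_nucleus(he, c.x, c.y, r)

        # PHH3 raster at deformation-displaced position
        iy, ix = int(np.clip(c.y, 0, size - 1)), int(np.clip(c.x, 0, size - 1))
        px = c.x + float(deform[0, iy, ix])
        py = c.y + float(deform[1, iy, ix])
        _stamp_disc(phh3, px, py, r, _PHH3_NUCLEUS)
        if c.phh3_positive:
            i = c.phh3_intensity
            color = (1 - i) * _PHH3_NUCLEUS + i * _PHH3_BROWN
            _stamp_disc(phh3, px, py, 0.9 * r, color)

    return ImagePair(image_id=image_id,
                     he_image=he.astype(np.uint8),
                     phh3_image=phh3.astype(np.uint8),
                     mpp=config.mpp, cells=cells, deformation=deform)


# ---------------------------------------------------------------------------
# rater simulation


def default_rater_profiles(n: int = 13, seed: int = 0) -> list[RaterProfile]:
    """A heterogeneous expert panel.

    Base H&E sensitivities are morphology-driven (metaphase and the late
    phases clear, early phases harder); the PHH3 sensitivity is high and
    narrow (the IHC signal is a strong criterion); each rater carries an
    individual skill offset, localisation jitter around 1 µm and a moderate
    hindsight bias.
    """
    rng = np.random.default_rng([seed, 0x5274])
    base = {"prophase": 0.55, "prometaphase": 0.65, "metaphase": 0.85,
            "anaphase": 0.80, "telophase": 0.80}
    profiles = []
    for i in range(n):
        skill = rng.normal(0.0, 0.12)
        sens = {ph: float(np.clip(v + skill + rng.normal(0, 0.06), 0.05, 0.95))
                for ph, v in base.items()}
        profiles.append(RaterProfile(
            rater_id=f"r{i:02d}",
            sensitivity_by_phase=sens,
            phh3_sensitivity=float(np.clip(0.95 + rng.normal(0, 0.02), 0.85, 0.995)),
            fp_rate_lookalike=float(np.clip(0.25 + rng.normal(0, 0.08), 0.01, 0.50)),
            jitter_sd_um=float(np.clip(abs(rng.normal(1.25, 0.4)), 0.2, 2.5)),
            hindsight_bias=float(np.clip(0.55 + rng.normal(0, 0.10), 0.0, 0.90))))
    return profiles


def simulate_rater(image_pair: ImagePair, profile: RaterProfile, study_phase: str,
                   rng: np.random.Generator) -> list[PointAnnotation]:
    """Simulate one rater's clicks on one image in one study phase.

    Phase P1 (H&E only): each H&E-visible true MF is annotated with the
    rater's per-phase sensitivity, each lookalike with the rater's
    false-positive rate; class is always ``MF``.

    Phase P2 (PHH3-assisted): cells visible in both stains are annotated
    with the larger of the two sensitivities (class ``HE_AND_PHH3``);
    H&E-visible, PHH3-negative MFs with the per-phase sensitivity (class
    ``HE_ONLY``); mismatch cells with the PHH3 sensitivity as ``PHH3_ONLY``
    unless the hindsight bias upgrades them to ``HE_AND_PHH3``.  Lookalikes
    remain a false-positive source (class ``HE_ONLY``: morphology without an
    IHC signal).  All positions get isotropic Gaussian jitter and are always
    reported in H&E coordinates.
    """
    if study_phase not in ("P1", "P2"):
        raise ValueError(f"unknown study phase {study_phase!r}")
    jitter_px = profile.jitter_sd_um / image_pair.mpp
    # placeholder rasters (unrendered studies) carry no usable bounds
    size = image_pair.he_image.shape[0]
    if size <= 1:
        size = None
    out: list[PointAnnotation] = []

    def emit(cell: CellObject, cls: str):
        x = cell.x + rng.normal(0, jitter_px)
        y = cell.y + rng.normal(0, jitter_px)
        if size:
            x = float(np.clip(x, 0, size - 1))
            y = float(np.clip(y, 0, size - 1))
        out.append(PointAnnotation(image_id=image_pair.image_id,
                                   rater_id=profile.rater_id,
                                   study_phase=study_phase, x=x, y=y, cls=cls))

    for cell in image_pair.cells:
        if study_phase == "P1":
            if cell.is_true_mf and cell.he_visible:
                if rng.random() < profile.sensitivity_by_phase[cell.phase]:
                    emit(cell, "MF")
            elif cell.phase == "lookalike":
                if rng.random() < profile.fp_rate_lookalike:
                    emit(cell, "MF")
        else:
            if cell.is_true_mf and cell.he_visible and cell.phh3_positive:
                p = max(profile.sensitivity_by_phase[cell.phase],
                        profile.phh3_sensitivity)
                if rng.random() < p:
                    emit(cell, "HE_AND_PHH3")
            elif cell.is_true_mf and cell.he_visible and not cell.phh3_positive:
                if rng.random() < profile.sensitivity_by_phase[cell.phase]:
                    emit(cell, "HE_ONLY")
            elif cell.is_mismatch:
                if rng.random() < profile.phh3_sensitivity:
                    cls = "HE_AND_PHH3" if rng.random() < profile.hindsight_bias \
                        else "PHH3_ONLY"
                    emit(cell, cls)
            elif cell.phase == "lookalike":
                if rng.random() < profile.fp_rate_lookalike * P2_LOOKALIKE_SUPPRESSION:
                    emit(cell, "HE_ONLY")
    return out


# ---------------------------------------------------------------------------
# full study


def generate_study(config: StudyConfig, profiles: list[RaterProfile] | None = None,
                   render: bool = True) -> StudyDataset:
    """Generate the full two-phase study: images, ground truth, annotations.

    The washout period between the phases is modelled as independent random
    substreams per (study phase, rater): a rater retains no memory of their
    first-phase clicks.  With ``render=False`` the rasters are skipped
    (1-px placeholders) — sufficient for all annotation-level statistics.
    """
    if profiles is None:
        profiles = default_rater_profiles(config.n_raters, seed=config.rng_seed)
    if len(profiles) != config.n_raters:
        raise ValueError(
            f"profile count {len(profiles)} != config.n_raters {config.n_raters}")

    images: list[ImagePair] = []
    for i in range(config.n_images):
        image_id = f"img_{i:03d}"
        cells = generate_cell_population(config, image_id)
        if render:
            images.append(render_image_pair(cells, config, image_id))
        else:
            placeholder = np.zeros((1, 1, 3), dtype=np.uint8)
            images.append(ImagePair(image_id=image_id, he_image=placeholder,
                                    phh3_image=placeholder.copy(), mpp=config.mpp,
                                    cells=cells, deformation=None))

    annotations: list[PointAnnotation] = []
    for phase_idx, study_phase in enumerate(("P1", "P2")):
        for rater_idx, profile in enumerate(profiles):
            rng = np.random.default_rng(
                [config.rng_seed, 7000 + phase_idx, rater_idx])
            for pair in images:
                annotations.extend(simulate_rater(pair, profile, study_phase, rng))
    return StudyDataset(config=config, images=images, annotations=annotations,
                        profiles=profiles)
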