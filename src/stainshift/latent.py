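"""Latent-space decision-boundary analysis.

A small convolutional classifier is trained to separate mitotic-figure
patches from other cell patches; with its classification layer removed it
serves as a *mapping network* that embeds cell patches into a fixed-width
feature space.  Cells of interest are embedded with test-time augmentation
(round-robin allocation of augmented copies up to a fixed total), projected
to 2-D with UMAP, and coloured by whether the majority of the
cross-validation detectors found them (true positive) or not (false
negative).  For each phase group the region holding three quartiles of the
TP and FN distributions is marked via a highest-density region of a 2-D
kernel density estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .datamodel import CellObject, Detection, ImagePair, NUCLEUS_DIAMETER_UM
from .detector import DetectorConfig, augment
from .nn.autograd import AdamW, Tensor
from .nn.layers import ConvBlock, Linear, Module
from .nn.autograd import global_avg_pool

__all__ = ["MappingConfig", "MappingNetwork", "EmbeddingSet", "phase_group",
           "extract_cell_patches", "train_mapping_network", "embed_with_tta",
           "umap_project", "tpfn_flags", "quartile_region", "region_centroid"]

PHASE_GROUPS = ("pro/prometaphase", "metaphase", "ana/telophase")


def phase_group(phase: str) -> str:
    if phase in ("prophase", "prometaphase"):
        return "pro/prometaphase"
    if phase == "metaphase":
        return "metaphase"
    if phase in ("anaphase", "telophase"):
        return "ana/telophase"
    raise ValueError(f"{phase!r} is not a mitotic phase")


@dataclass
class MappingConfig:
    patch_size: int = 32
    feature_width: int = 512      # embedding length; desk-scale tests shrink it
    channels: tuple = (16, 24, 32)
    lr: float = 1e-3
    batch_size: int = 16
    iters_per_epoch: int = 30
    max_epochs: int = 15
    patience: int = 3
    val_fraction: float = 0.2
    seed: int = 0


class MappingNetwork(Module):
    """Conv stem -> global average pool -> feature layer -> classifier.

    ``embed`` returns the post-feature-layer activations; ``logit`` applies
    the final classification layer (removed conceptually after training).
    """

    def __init__(self, config: MappingConfig, rng=None):
        rng = rng or np.random.default_rng(config.seed)
        c1, c2, c3 = config.channels
        self.config = config
        self.b1 = ConvBlock(3, c1, 2, rng)
        self.b2 = ConvBlock(c1, c2, 2, rng)
        self.b3 = ConvBlock(c2, c3, 2, rng)
        self.feat = Linear(c3, config.feature_width, rng)
        self.cls = Linear(config.feature_width, 1, rng)

    def _features(self, x: Tensor) -> Tensor:
        h = self.b3(self.b2(self.b1(x)))
        return self.feat(global_avg_pool(h)).relu()

    def embed(self, patches: np.ndarray) -> np.ndarray:
        """Patches (N, H, W, 3) uint8/float -> embeddings (N, feature_width)."""
        x = Tensor(_to_float(patches).transpose(0, 3, 1, 2))
        return self._features(x).data.copy()

    def logit(self, x: Tensor) -> Tensor:
        return self.cls(self._features(x))


def _to_float(patches: np.ndarray) -> np.ndarray:
    arr = np.asarray(patches, dtype=np.float32)
    if arr.max() > 1.5:
        arr = arr / 255.0
    return arr


def extract_cell_patches(images: list[ImagePair], cells: list[CellObject],
                         patch_size: int = 32) -> np.ndarray:
    """Crop a patch around each cell centre (edge-padded at image borders)."""
    by_id = {im.image_id: im for im in images}
    half = patch_size // 2
    out = np.empty((len(cells), patch_size, patch_size, 3), dtype=np.uint8)
    for i, c in enumerate(cells):
        img_id = c.id.rsplit("_c", 1)[0]
        he = by_id[img_id].he_image
        h, w = he.shape[:2]
        pad = np.pad(he, ((half, half), (half, half), (0, 0)), mode="edge")
        cy, cx = int(round(c.y)) + half, int(round(c.x)) + half
        out[i] = pad[cy - half:cy + half, cx - half:cx + half]
    return out


def train_mapping_network(patches: np.ndarray, binary_labels: np.ndarray,
                          config: MappingConfig | None = None,
                          verbose: bool = False) -> MappingNetwork:
    """Train the MF-vs-other patch classifier; the feature stem (with the
    classification layer detached) is the mapping network.

    Uses the same augmentation pipeline as detector training and early
    stopping on validation loss.
    """
    config = config or MappingConfig()
    labels = np.asarray(binary_labels, dtype=np.float32)
    if patches.shape[0] != labels.shape[0] or patches.shape[0] < 4:
        raise ValueError("need matching patches/labels, at least 4 samples")
    rng = np.random.default_rng([config.seed, 0xE3B])
    n = patches.shape[0]
    perm = rng.permutation(n)
    n_val = max(int(config.val_fraction * n), 1)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    aug_cfg = DetectorConfig(patch_size=config.patch_size)

    model = MappingNetwork(config, rng=np.random.default_rng([config.seed, 0x31]))
    opt = AdamW(model.parameters(), lr=config.lr)
    best_loss, best_state, since_best = np.inf, None, 0
    val_x = Tensor(_to_float(patches[val_idx]).transpose(0, 3, 1, 2))
    val_y = labels[val_idx]

    for epoch in range(config.max_epochs):
        for _ in range(config.iters_per_epoch):
            idx = train_idx[rng.integers(0, len(train_idx), config.batch_size)]
            batch = np.stack([augment(patches[i], rng, config=aug_cfg)
                              for i in idx])
            x = Tensor(_to_float(batch).transpose(0, 3, 1, 2))
            logits = model.logit(x)
            loss = _bce(logits, labels[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
        vl = float(_bce(model.logit(val_x), val_y).data)
        if verbose:
            print(f"epoch {epoch}: val loss {vl:.4f}")
        if vl < best_loss:
            best_loss, best_state, since_best = vl, model.state_dict(), 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    return model


def _bce(logits: Tensor, targets: np.ndarray) -> Tensor:
    p = logits.sigmoid()
    t = Tensor(targets.reshape(logits.data.shape).astype(np.float32))
    one = Tensor(np.float32(1.0))
    return -((p.log() * t) + ((one - p).log() * (one - t))).mean()


# ---------------------------------------------------------------------------
# embeddings with test-time augmentation


@dataclass
class EmbeddingSet:
    cell_ids: list[str]
    source_index: np.ndarray          # representation -> cell index
    phase_groups: list[str]           # per cell
    embeddings: np.ndarray            # (n_total, feature_width)
    projections: np.ndarray | None = None   # (n_total, 2)
    tp_flags: dict[str, np.ndarray] = field(default_factory=dict)  # per cell

    def representation_groups(self) -> list[str]:
        return [self.phase_groups[i] for i in self.source_index]


def embed_with_tta(cells: list[CellObject], patches: np.ndarray,
                   embedder: MappingNetwork, n_total: int = 2000,
                   rng: np.random.Generator | None = None,
                   identity_only: bool = False) -> EmbeddingSet:
    """Embed each cell several times under test-time augmentation.

    Augmented copies are allocated round-robin across cells until exactly
    ``n_total`` representations exist, so every cell receives either
    floor(n_total / n_cells) or one more.  The first copy of each cell is
    the unaugmented patch.
    """
    if len(cells) == 0:
        raise ValueError("no cells to embed")
    if n_total < len(cells):
        raise ValueError("n_total must be at least the number of cells")
    rng = rng or np.random.default_rng(0)
    n_cells = len(cells)
    counts = np.full(n_cells, n_total // n_cells, dtype=int)
    counts[:n_total % n_cells] += 1
    aug_cfg = DetectorConfig(patch_size=patches.shape[1])
    reps = []
    source = []
    for i in range(n_cells):
        for k in range(counts[i]):
            if k == 0 or identity_only:
                reps.append(patches[i].astype(np.float32))
            else:
                reps.append(augment(patches[i], rng, config=aug_cfg))
            source.append(i)
    reps = np.stack(reps)
    # embed in chunks to bound memory
    embs = np.concatenate([embedder.embed(reps[i:i + 256])
                           for i in range(0, len(reps), 256)])
    return EmbeddingSet(cell_ids=[c.id for c in cells],
                        source_index=np.array(source),
                        phase_groups=[phase_group(c.phase) if c.is_true_mf
                                      else "other" for c in cells],
                        embeddings=embs)


def umap_project(embeddings: np.ndarray, seed: int = 0, n_neighbors: int = 15,
                 min_dist: float = 0.1) -> np.ndarray:
    """Deterministic 2-D UMAP layout of the embedding matrix."""
    import umap

    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                        min_dist=min_dist, random_state=seed)
    return np.asarray(reducer.fit_transform(embeddings), dtype=float)


def tpfn_flags(cells: list[CellObject],
               per_model_detections: list[dict[str, list[Detection]]],
               radius_um: float = NUCLEUS_DIAMETER_UM,
               mpp: float = 0.25) -> np.ndarray:
    """True-positive flag per cell: detected by more than half of the
    cross-validation models (a detection centre within the matching radius)."""
    if not per_model_detections:
        raise ValueError("need at least one model's detections")
    radius_px = radius_um / mpp
    hits = np.zeros(len(cells), dtype=int)
    for model_dets in per_model_detections:
        for i, c in enumerate(cells):
            img_id = c.id.rsplit("_c", 1)[0]
            dets = model_dets.get(img_id, [])
            if any(np.hypot(d.x - c.x, d.y - c.y) <= radius_px for d in dets):
                hits[i] += 1
    return hits > len(per_model_detections) / 2.0


# ---------------------------------------------------------------------------
# three-quartile density regions


def quartile_region(points: np.ndarray, mass: float = 0.75, grid_n: int = 120,
                    method: str = "kde"):
    """Highest-density region of a 2-D KDE containing ``mass`` of the points.

    Returns (contours, threshold, inside_mask): contour polygons in data
    coordinates (may be several), the density threshold, and which input
    points fall inside the region.  Degenerate inputs (fewer than 3 distinct
    points, or a singular covariance) collapse to a point/segment region.

    ``method="hull"`` is the simpler alternative: the convex hull of the
    ``mass`` fraction of points closest to the centroid (threshold is a
    distance, not a density, in that case).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if method not in ("kde", "hull"):
        raise ValueError(f"unknown region method {method!r}")
    if method == "hull":
        return _hull_region(pts, mass)
    distinct = np.unique(pts, axis=0)
    if len(distinct) < 3 or np.linalg.matrix_rank(np.cov(pts.T)) < 2:
        centroid = pts.mean(axis=0)
        return [np.array([centroid])], np.inf, np.ones(len(pts), dtype=bool)
    kde = sstats.gaussian_kde(pts.T)  # Scott's rule bandwidth
    dens = kde(pts.T)
    thr = float(np.quantile(dens, 1.0 - mass))
    inside = dens >= thr

    from skimage import measure

    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    pad = 0.15 * (hi - lo + 1e-9)
    xs = np.linspace(lo[0] - pad[0], hi[0] + pad[0], grid_n)
    ys = np.linspace(lo[1] - pad[1], hi[1] + pad[1], grid_n)
    gx, gy = np.meshgrid(xs, ys)
    gz = kde(np.vstack([gx.ravel(), gy.ravel()])).reshape(grid_n, grid_n)
    contours = []
    for poly in measure.find_contours(gz, thr):
        # grid indices -> data coordinates (rows are y)
        cx = np.interp(poly[:, 1], np.arange(grid_n), xs)
        cy = np.interp(poly[:, 0], np.arange(grid_n), ys)
        contours.append(np.column_stack([cx, cy]))
    return contours, thr, inside


def _hull_region(pts: np.ndarray, mass: float):
    centroid = pts.mean(axis=0)
    d = np.hypot(pts[:, 0] - centroid[0], pts[:, 1] - centroid[1])
    thr = float(np.quantile(d, mass))
    inside = d <= thr
    core = pts[inside]
    if len(np.unique(core, axis=0)) < 3:
        return [np.array([centroid])], thr, inside
    from scipy.spatial import ConvexHull

    hull = ConvexHull(core)
    poly = core[hull.vertices]
    return [np.vstack([poly, poly[:1]])], thr, inside


def region_centroid(points: np.ndarray, mass: float = 0.75) -> np.ndarray:
    """Centroid of the points inside the three-quartile density region."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        return pts.mean(axis=0)
    _, _, inside = quartile_region(pts, mass=mass)
    return pts[inside].mean(axis=0)


def plot_embedding_set(es: EmbeddingSet, path, condition: str | None = None,
                       mass: float = 0.75) -> None:
    """One row of projection scatter plots, one panel per phase group.

    Points are coloured by the TP/FN flag of the chosen condition (first
    stored condition by default) and each panel overlays the three-quartile
    region contours of the TP and FN point sets.  Written as PNG or SVG
    depending on the file suffix.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if es.projections is None:
        raise ValueError("embedding set has no projections; run umap_project")
    if condition is None:
        condition = next(iter(es.tp_flags))
    flags = es.tp_flags[condition][es.source_index]
    groups = np.array(es.representation_groups())
    panel_groups = [g for g in PHASE_GROUPS if (groups == g).any()]
    fig, axes = plt.subplots(1, max(len(panel_groups), 1),
                             figsize=(4 * max(len(panel_groups), 1), 4),
                             squeeze=False)
    for ax, grp in zip(axes[0], panel_groups):
        sel = groups == grp
        for flag_value, color, label in ((True, "tab:orange", "TP"),
                                         (False, "tab:blue", "FN")):
            mask = sel & (flags == flag_value)
            pts = es.projections[mask]
            ax.scatter(pts[:, 0], pts[:, 1], s=4, alpha=0.4, color=color,
                       label=label)
            if mask.sum() >= 3:
                contours, _, _ = quartile_region(pts, mass=mass)
                for poly in contours:
                    if len(poly) > 1:
                        ax.plot(poly[:, 0], poly[:, 1], color=color, lw=1.5)
        ax.set_title(grp)
        ax.legend(loc="best", fontsize=8)
    fig.suptitle(f"latent projections — {condition}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def embedding_table(es: EmbeddingSet):
    """Projections, phase groups and flags as a tidy DataFrame."""
    import pandas as pd

    data = {"cell_id": [es.cell_ids[i] for i in es.source_index],
            "phase_group": es.representation_groups()}
    if es.projections is not None:
        data["umap_x"] = es.projections[:, 0]
        data["umap_y"] = es.projections[:, 1]
    for name, flags in es.tp_flags.items():
        data[f"tp_{name}"] = flags[es.source_index]
    return pd.DataFrame(data)
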