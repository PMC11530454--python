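"""Anchor-free mitosis detectors: single-stain FCOS-style and the dual-input
variant with per-level mid-fusion of the H&E and PHH3 feature maps.

The dual-input model runs one backbone per stain and merges the per-level
feature maps H and P with an independent merging network per pyramid level:

    F = ReLU(Conv1x1(LayerNorm(Cat(H, P))))

where Cat concatenates along the channel axis (2C channels) and the 1x1
convolution halves the channel count back to C.  The rest of the network is
a standard anchor-free design: a three-level feature pyramid over backbone
stages 2-4 and shared heads emitting a per-location foreground score,
centerness, and distances to the four box sides.

Training follows a fixed protocol: AdamW at learning rate 1e-4, patch
sampling with at least half the patches containing a labelled mitotic
figure, a four-operation augmentation pipeline (color jitter, Gaussian blur,
pixel drop, rotation), and early stopping on validation average precision
with a patience of 5.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .datamodel import Detection, ImagePair, LabelSet, Split
from .nn.autograd import (Tensor, concat_channels, crop_like, layernorm_channels,
                          layernorm_full, minimum, upsample2x, AdamW)
from .nn.layers import Conv2d, Module, count_parameters, make_backbone

__all__ = ["DetectorConfig", "FCOSModel", "FusionBlock", "points_to_boxes",
           "sample_training_patches", "augment", "augment_pair", "train_detector",
           "centerness_target", "model_summary"]


@dataclass
class DetectorConfig:
    mode: str = "single"                 # "single" (H&E) or "dual" (H&E + PHH3)
    backbone: str = "tiny"               # "tiny", "resnet18", "resnet101"
    pretrained: bool = False             # no weight download at desk scale
    lr: float = 1e-4
    patience: int = 5
    patch_size: int = 128
    mf_patch_fraction: float = 0.5
    box_size_px: int = 50
    score_threshold: float = 0.30
    nms_threshold: float = 0.30
    layernorm_mode: str = "per_position"  # or "per_level"
    tiny_channels: tuple = (12, 16, 24, 32)
    fpn_channels: int = 24
    batch_size: int = 4
    iters_per_epoch: int = 40
    max_epochs: int = 20
    val_patches: int = 16
    aug_color_p: float = 0.5
    aug_blur_p: float = 0.25
    aug_drop_p: float = 0.25
    aug_drop_rate: float = 0.05
    aug_rot_p: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("single", "dual"):
            raise ValueError(f"unknown mode {self.mode!r}")
        stride = 16 if self.backbone == "tiny" else 32
        if self.patch_size % stride != 0:
            raise ValueError(
                f"patch_size {self.patch_size} must be divisible by the total "
                f"backbone stride {stride}")


class FusionBlock(Module):
    """Per-level merging network: Cat -> LayerNorm -> 1x1 conv (2C->C) -> ReLU."""

    def __init__(self, channels: int, rng, layernorm_mode: str = "per_position"):
        self.gain = Tensor(np.ones(2 * channels), requires_grad=True)
        self.bias = Tensor(np.zeros(2 * channels), requires_grad=True)
        self.conv = Conv2d(2 * channels, channels, 1, rng=rng)
        self.layernorm_mode = layernorm_mode

    def __call__(self, he: Tensor, phh3: Tensor) -> Tensor:
        if he.shape != phh3.shape:
            raise ValueError(f"stain branch shapes differ: {he.shape} vs {phh3.shape}")
        cat = concat_channels(he, phh3)
        if self.layernorm_mode == "per_level":
            normed = layernorm_full(cat, self.gain, self.bias)
        else:
            normed = layernorm_channels(cat, self.gain, self.bias)
        return self.conv(normed).relu()


def fuse_features(fusion_blocks: list[FusionBlock], he_maps: list[Tensor],
                  phh3_maps: list[Tensor]) -> list[Tensor]:
    """Apply one independent merging network per feature-pyramid level."""
    if len(he_maps) != len(phh3_maps):
        raise ValueError("branch level counts differ")
    return [fb(h, p) for fb, h, p in zip(fusion_blocks, he_maps, phh3_maps)]


class FCOSModel(Module):
    """Three-level anchor-free detector with optional dual-stain mid-fusion."""

    def __init__(self, config: DetectorConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(config.seed)
        if config.pretrained:
            raise ValueError("no pretrained backbone weights are bundled with "
                             "this build; construct with pretrained=False and "
                             "load weights via load_state_dict if available")
        self.config = config
        self.backbone_he = make_backbone(config.backbone, rng=rng,
                                         tiny_channels=config.tiny_channels)
        self.strides = tuple(self.backbone_he.strides)
        chans = self.backbone_he.out_channels
        if config.mode == "dual":
            self.backbone_phh3 = make_backbone(config.backbone, rng=rng,
                                               tiny_channels=config.tiny_channels)
            self.fusion = [FusionBlock(c, rng, config.layernorm_mode) for c in chans]
        f = config.fpn_channels
        self.lateral = [Conv2d(c, f, 1, rng=rng) for c in chans]
        self.smooth = [Conv2d(f, f, 3, pad=1, rng=rng) for _ in chans]
        self.cls_tower = Conv2d(f, f, 3, pad=1, rng=rng)
        self.reg_tower = Conv2d(f, f, 3, pad=1, rng=rng)
        self.cls_head = Conv2d(f, 1, 1, rng=rng)
        self.ctr_head = Conv2d(f, 1, 1, rng=rng)
        self.reg_head = Conv2d(f, 4, 1, rng=rng)
        # start with a low foreground prior so the focal loss is stable early
        self.cls_head.bias.data[...] = -3.0
        # level ranges on max(l, t, r, b): locations are assigned to the level
        # whose scale bracket contains their largest side distance
        self.level_ranges = []
        lo = 0.0
        for s in self.strides[:-1]:
            self.level_ranges.append((lo, 8.0 * s))
            lo = 8.0 * s
        self.level_ranges.append((lo, np.inf))

    # -- forward -------------------------------------------------------------

    def backbone_forward(self, image: Tensor, stain: str = "he") -> list[Tensor]:
        stride = self.strides[-1]
        h, w = image.shape[2], image.shape[3]
        if h % stride or w % stride:
            raise ValueError(
                f"input size {h}x{w} must be divisible by the total backbone "
                f"stride {stride}")
        bb = self.backbone_he if stain == "he" else self.backbone_phh3
        return bb(image)

    def forward(self, he: Tensor, phh3: Tensor | None = None) -> list[dict]:
        maps = self.backbone_forward(he, "he")
        if self.config.mode == "dual":
            if phh3 is None:
                raise ValueError("dual-mode model requires the PHH3 input")
            pmaps = self.backbone_forward(phh3, "phh3")
            maps = fuse_features(self.fusion, maps, pmaps)
        pyramid = self._fpn(maps)
        out = []
        for lvl, feat in enumerate(pyramid):
            c = self.cls_tower(feat).relu()
            r = self.reg_tower(feat).relu()
            out.append({"cls": self.cls_head(c), "ctr": self.ctr_head(r),
                        "reg": self.reg_head(r), "stride": self.strides[lvl]})
        return out

    def _fpn(self, maps: list[Tensor]) -> list[Tensor]:
        lat = [self.lateral[i](m) for i, m in enumerate(maps)]
        outs = [None] * len(lat)
        prev = lat[-1]
        outs[-1] = self.smooth[-1](prev)
        for i in range(len(lat) - 2, -1, -1):
            up = upsample2x(prev)
            up = crop_like(up, lat[i].shape[2], lat[i].shape[3])
            prev = lat[i] + up
            outs[i] = self.smooth[i](prev)
        return outs

    # -- inference -----------------------------------------------------------

    def predict_patch(self, he: np.ndarray, phh3: np.ndarray | None = None,
                      score_threshold: float | None = None) -> list[Detection]:
        """Decode raw detections (no NMS) from one patch; coordinates local."""
        batch = self.predict_batch(he[None], None if phh3 is None else phh3[None],
                                   score_threshold=score_threshold)
        return batch[0]

    def predict_batch(self, he: np.ndarray, phh3: np.ndarray | None = None,
                      score_threshold: float | None = None,
                      pre_nms_topk: int = 200) -> list[list[Detection]]:
        """Decode raw detections for a batch of patches (NHWC uint8/float).

        Only the ``pre_nms_topk`` highest-scoring locations per patch are
        materialised (the usual pre-NMS cap of one-stage detectors).
        """
        thr = self.config.score_threshold if score_threshold is None \
            else score_threshold
        n = he.shape[0]
        levels = self.forward(_batch_tensor(list(he)),
                              None if phh3 is None else _batch_tensor(list(phh3)))
        cols = []  # (batch, score, x0, y0, x1, y1) rows across levels
        for lv in levels:
            s = lv["stride"]
            p_cls = _sigmoid(lv["cls"].data[:, 0])
            p_ctr = _sigmoid(lv["ctr"].data[:, 0])
            score = np.sqrt(p_cls * p_ctr)
            bs, ys, xs = np.nonzero(score >= thr)
            if len(ys) == 0:
                continue
            # advanced indexing yields shape (n_locations, 4)
            dist = np.exp(np.clip(lv["reg"].data[bs, :, ys, xs], -10, 10)) * s
            cx = xs * s + s / 2.0
            cy = ys * s + s / 2.0
            cols.append(np.column_stack([bs, score[bs, ys, xs],
                                         cx - dist[:, 0], cy - dist[:, 1],
                                         cx + dist[:, 2], cy + dist[:, 3]]))
        dets: list[list[Detection]] = [[] for _ in range(n)]
        if not cols:
            return dets
        rows = np.concatenate(cols)
        rows = rows[(rows[:, 4] > rows[:, 2]) & (rows[:, 5] > rows[:, 3])]
        for b in range(n):
            sub = rows[rows[:, 0] == b]
            if sub.shape[0] > pre_nms_topk:
                sub = sub[np.argsort(-sub[:, 1], kind="stable")[:pre_nms_topk]]
            for _, sv, a0, b0, a1, b1 in sub:
                dets[b].append(Detection(x=float((a0 + a1) / 2),
                                         y=float((b0 + b1) / 2),
                                         box=(float(a0), float(b0),
                                              float(a1), float(b1)),
                                         score=float(sv)))
        return dets

    # -- loss ----------------------------------------------------------------

    def loss(self, he: Tensor, boxes_per_image: list[np.ndarray],
             phh3: Tensor | None = None) -> Tensor:
        """Focal classification loss + IoU box loss + centerness BCE."""
        levels = self.forward(he, phh3)
        n = he.shape[0]
        cls_logits, ctr_logits, reg_maps = [], [], []
        cls_t, ctr_t, reg_t = [], [], []
        for lv in levels:
            s = lv["stride"]
            _, _, hh, ww = lv["cls"].shape
            rng_lo, rng_hi = self.level_ranges[self.strides.index(s)]
            t_cls, t_ctr, t_reg = _fcos_targets(boxes_per_image, hh, ww, s,
                                                rng_lo, rng_hi)
            cls_logits.append(lv["cls"].reshape(n * hh * ww, 1))
            ctr_logits.append(lv["ctr"].reshape(n * hh * ww, 1))
            reg_maps.append(lv["reg"].transpose((0, 2, 3, 1)).reshape(n * hh * ww, 4))
            cls_t.append(t_cls.reshape(-1, 1))
            ctr_t.append(t_ctr.reshape(-1, 1))
            reg_t.append(t_reg.reshape(-1, 4))
        cls_all = _vconcat(cls_logits)
        ctr_all = _vconcat(ctr_logits)
        reg_all = _vconcat(reg_maps)
        tc = np.concatenate(cls_t)
        tt = np.concatenate(ctr_t)
        tr = np.concatenate(reg_t)
        pos = np.nonzero(tc[:, 0] > 0.5)[0]
        npos = max(len(pos), 1)

        loss = _focal_loss(cls_all, tc) * Tensor(np.float32(1.0 / npos))
        if len(pos):
            reg_pos = reg_all.gather_rows(pos)
            pred = reg_pos.exp()  # distances in stride units
            strides_per_loc = np.concatenate(
                [np.full(t.shape[0], lv["stride"], dtype=np.float32)
                 for t, lv in zip(cls_t, levels)])[pos]
            pred = pred * Tensor(strides_per_loc[:, None])
            target = Tensor(tr[pos])
            loss = loss + _iou_loss(pred, target) * Tensor(np.float32(1.0 / npos))
            ctr_pos = ctr_all.gather_rows(pos)
            loss = loss + _bce_with_logits(ctr_pos, tt[pos]) * Tensor(
                np.float32(1.0 / npos))
        return loss


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def _vconcat(tensors: list[Tensor]) -> Tensor:
    """Concatenate 2-D tensors along axis 0 (autodiff-aware)."""
    datas = [t.data for t in tensors]
    rg = any(t.requires_grad for t in tensors)
    data = np.concatenate(datas, axis=0)
    offsets = np.cumsum([0] + [d.shape[0] for d in datas])

    def backward():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                t._accum(out.grad[lo:hi])

    out = Tensor._make(data, tuple(tensors), backward, rg)
    return out


def centerness_target(left, top, right, bottom) -> float:
    """The standard anchor-free centerness: sqrt(min/max(l,r) * min/max(t,b))."""
    lr = min(left, right) / max(left, right) if max(left, right) > 0 else 0.0
    tb = min(top, bottom) / max(top, bottom) if max(top, bottom) > 0 else 0.0
    return float(np.sqrt(lr * tb))


def _fcos_targets(boxes_per_image, hh, ww, stride, rng_lo, rng_hi):
    """Per-location targets for one pyramid level.

    A location is positive if it falls inside a ground-truth box and its
    largest side distance lies within the level's scale bracket; among
    several admissible boxes the smallest-area one wins.
    """
    n = len(boxes_per_image)
    t_cls = np.zeros((n, hh, ww), dtype=np.float32)
    t_ctr = np.zeros((n, hh, ww), dtype=np.float32)
    t_reg = np.zeros((n, hh, ww, 4), dtype=np.float32)
    ys, xs = np.mgrid[0:hh, 0:ww]
    cx = xs * stride + stride / 2.0
    cy = ys * stride + stride / 2.0
    for i, boxes in enumerate(boxes_per_image):
        if boxes is None or len(boxes) == 0:
            continue
        best_area = np.full((hh, ww), np.inf, dtype=np.float32)
        for (x0, y0, x1, y1) in boxes:
            left = cx - x0
            top = cy - y0
            right = x1 - cx
            bottom = y1 - cy
            dist = np.stack([left, top, right, bottom])
            inside = dist.min(axis=0) > 0
            maxd = dist.max(axis=0)
            ok = inside & (maxd >= rng_lo) & (maxd < rng_hi)
            area = (x1 - x0) * (y1 - y0)
            take = ok & (area < best_area)
            if not take.any():
                continue
            best_area[take] = area
            t_cls[i][take] = 1.0
            lr = np.minimum(left, right) / np.maximum(left, right)
            tb = np.minimum(top, bottom) / np.maximum(top, bottom)
            ctr = np.sqrt(np.clip(lr * tb, 0, None))
            t_ctr[i][take] = ctr[take]
            for k, d in enumerate((left, top, right, bottom)):
                t_reg[i, :, :, k][take] = d[take]
    return t_cls, t_ctr, t_reg


def _focal_loss(logits: Tensor, targets: np.ndarray, alpha: float = 0.25,
                gamma: float = 2.0) -> Tensor:
    p = logits.sigmoid()
    t = Tensor(targets)
    one = Tensor(np.float32(1.0))
    pt_pos = p.log() * t
    pt_neg = (one - p).log() * (one - t)
    w_pos = (one - p).pow_const(gamma) * Tensor(np.float32(alpha))
    w_neg = p.pow_const(gamma) * Tensor(np.float32(1.0 - alpha))
    loss = -(w_pos * pt_pos + w_neg * pt_neg)
    return loss.sum()


def _iou_loss(pred: Tensor, target: Tensor) -> Tensor:
    """-log(IoU) between predicted and target (l, t, r, b) distances."""
    pl, pt_, pr, pb = (_col(pred, j) for j in range(4))
    tl, tt, tr, tb = (_col(target, j) for j in range(4))
    area_p = (pl + pr) * (pt_ + pb)
    area_t = (tl + tr) * (tt + tb)
    iw = minimum(pl, tl) + minimum(pr, tr)
    ih = minimum(pt_, tt) + minimum(pb, tb)
    inter = iw * ih
    union = area_p + area_t - inter
    iou = inter * union.pow_const(-1.0)
    eps = Tensor(np.float32(1e-6))
    return -((iou + eps).log()).sum()


def _col(t: Tensor, j: int) -> Tensor:
    """Column slice of a 2-D tensor as an (n,) tensor."""
    def backward():
        if t.requires_grad:
            g = np.zeros_like(t.data)
            g[:, j] = out.grad
            t._accum(g)

    out = Tensor._make(t.data[:, j], (t,), backward, t.requires_grad)
    return out


def _bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    p = logits.sigmoid()
    t = Tensor(targets.reshape(logits.data.shape))
    one = Tensor(np.float32(1.0))
    return -((p.log() * t) + ((one - p).log() * (one - t))).sum()


# ---------------------------------------------------------------------------
# labels, patches, augmentation


def points_to_boxes(points: list[tuple], box_size_px: float,
                    image_size: tuple[int, int] | None = None) -> np.ndarray:
    """Square boxes of the given side centred on label points, clipped to the
    image; a clipped box never collapses to zero area."""
    half = box_size_px / 2.0
    boxes = []
    for pt in points:
        x, y = pt[0], pt[1]
        x0, y0, x1, y1 = x - half, y - half, x + half, y + half
        if image_size is not None:
            w, h = image_size
            x0, x1 = np.clip([x0, x1], 0, w)
            y0, y1 = np.clip([y0, y1], 0, h)
            if x1 - x0 < 2:
                x0, x1 = (0.0, 2.0) if x0 < 1 else (w - 2.0, float(w))
            if y1 - y0 < 2:
                y0, y1 = (0.0, 2.0) if y0 < 1 else (h - 2.0, float(h))
        boxes.append((x0, y0, x1, y1))
    return np.array(boxes, dtype=np.float32).reshape(-1, 4)


def sample_training_patches(images: list[ImagePair], label_set: LabelSet,
                            config: DetectorConfig, rng: np.random.Generator,
                            n_patches: int | None = None):
    """Random training patches; at least ``mf_patch_fraction`` of them contain
    a labelled MF centre strictly inside.  Yields dicts with he/phh3 patches
    and label points in patch coordinates."""
    ps = config.patch_size
    positives = [(im, (x, y)) for im in images
                 for (x, y, _s) in label_set.points.get(im.image_id, [])]
    count = 0
    while n_patches is None or count < n_patches:
        want_positive = rng.random() < config.mf_patch_fraction
        if want_positive and positives:
            im, (px, py) = positives[rng.integers(len(positives))]
            h, w = im.he_image.shape[:2]
            x0 = int(np.clip(px - rng.integers(1, ps - 1), 0, w - ps))
            y0 = int(np.clip(py - rng.integers(1, ps - 1), 0, h - ps))
        else:
            im = images[rng.integers(len(images))]
            h, w = im.he_image.shape[:2]
            x0 = int(rng.integers(0, max(w - ps, 0) + 1))
            y0 = int(rng.integers(0, max(h - ps, 0) + 1))
        pts = [(x - x0, y - y0) for (x, y, _s) in label_set.points.get(im.image_id, [])
               if x0 < x < x0 + ps - 1 and y0 < y < y0 + ps - 1]
        if want_positive and positives and not pts:
            continue
        yield {"he": im.he_image[y0:y0 + ps, x0:x0 + ps],
               "phh3": im.phh3_image[y0:y0 + ps, x0:x0 + ps],
               "points": pts, "image_id": im.image_id, "origin": (x0, y0)}
        count += 1


def _color_jitter(img: np.ndarray, rng) -> np.ndarray:
    out = img.astype(np.float32)
    out = out * rng.uniform(0.85, 1.15) + rng.uniform(-12, 12)
    mean = out.mean(axis=2, keepdims=True)
    out = mean + (out - mean) * rng.uniform(0.85, 1.15)  # saturation
    return np.clip(out, 0, 255)


def augment(patch: np.ndarray, rng: np.random.Generator,
            points: list[tuple] | None = None, config: DetectorConfig | None = None,
            k_rot: int | None = None):
    """Four-operation augmentation of a single patch (+ its label points).

    Color jitter, Gaussian blur and pixel drop fire with their configured
    probabilities; rotation is by a multiple of 90 degrees.  Returns
    (patch, points) when points are given, else the patch.
    """
    cfg = config or DetectorConfig()
    out = patch.astype(np.float32)
    if rng.random() < cfg.aug_color_p:
        out = _color_jitter(out, rng)
    if rng.random() < cfg.aug_blur_p:
        out = ndimage.gaussian_filter(out, sigma=(rng.uniform(0.4, 1.0),) * 2 + (0,))
    if rng.random() < cfg.aug_drop_p:
        mask = rng.random(out.shape[:2]) < cfg.aug_drop_rate
        out[mask] = 0.0
    if k_rot is None:
        k_rot = int(rng.integers(0, 4)) if rng.random() < cfg.aug_rot_p else 0
    k = k_rot
    out = np.rot90(out, k=k, axes=(0, 1)).copy()
    if points is None:
        return out
    return out, rotate_points(points, k, patch.shape[0])


def rotate_points(points: list[tuple], k: int, size: int) -> list[tuple]:
    """Rotate label points by k*90 degrees counter-clockwise, matching
    ``np.rot90`` of the image content."""
    pts = points
    for _ in range(k % 4):
        pts = [(y, size - 1 - x) for (x, y) in pts]
    return pts


def augment_pair(he: np.ndarray, phh3: np.ndarray | None, points: list[tuple],
                 rng: np.random.Generator, config: DetectorConfig):
    """Dual-stain augmentation: spatial transforms identical for both stains,
    color transforms independent per stain."""
    k = (int(rng.integers(0, 4)) if rng.random() < config.aug_rot_p else 0)
    he_a, pts = augment(he, rng, points=points, config=config, k_rot=k)
    if phh3 is None:
        return he_a, None, pts
    phh3_a = augment(phh3, rng, points=None, config=config, k_rot=k)
    return he_a, phh3_a, pts


# ---------------------------------------------------------------------------
# training


class EarlyStopper:
    """Patience-based early stopping on a to-be-maximised score.

    ``update`` returns True once the score has not strictly improved for
    ``patience`` consecutive evaluations; with a monotonically worsening
    score the rule stops after exactly patience + 1 evaluations.
    """

    def __init__(self, patience: int):
        self.patience = patience
        self.best = -np.inf
        self.since_best = 0
        self.n_evals = 0

    def update(self, score: float) -> bool:
        self.n_evals += 1
        if score > self.best:
            self.best = score
            self.since_best = 0
            return False
        self.since_best += 1
        return self.since_best >= self.patience


def _batch_tensor(patches: list[np.ndarray]) -> Tensor:
    arr = np.stack([p.astype(np.float32) / 255.0 if p.max() > 1.5
                    else p.astype(np.float32) for p in patches])
    return Tensor(arr.transpose(0, 3, 1, 2))


def train_detector(config: DetectorConfig, split: Split, label_set: LabelSet,
                   images: list[ImagePair], verbose: bool = False):
    """Train a detector on one split's training images and label set.

    Per epoch: ``iters_per_epoch`` AdamW steps on augmented sampled patches,
    then average precision on a fixed set of validation patches; training
    stops once validation AP has not improved for ``patience`` consecutive
    evaluations, and the best-AP checkpoint is returned along with the
    history of validation APs.
    """
    from .evaluation import average_precision, nms as _nms  # no import cycle

    by_id = {im.image_id: im for im in images}
    train_imgs = [by_id[i] for i in split.train if i in by_id]
    val_imgs = [by_id[i] for i in split.val if i in by_id]
    n_train_labels = sum(len(label_set.points.get(im.image_id, []))
                         for im in train_imgs)
    if n_train_labels == 0:
        raise ValueError("empty training labels: refusing to train a detector "
                         "with no positive examples")

    rng = np.random.default_rng([config.seed, 0xDE7])
    model = FCOSModel(config, rng=np.random.default_rng([config.seed, 0x11]))
    opt = AdamW(model.parameters(), lr=config.lr)
    sampler = sample_training_patches(train_imgs, label_set, config, rng)

    # fixed validation patch set (biased to label-bearing patches so AP is
    # defined); frozen once per run
    val_rng = np.random.default_rng([config.seed, 0x7A1])
    val_cfg_fraction = 0.75
    val_sampler = sample_training_patches(
        val_imgs, label_set,
        _with(config, mf_patch_fraction=val_cfg_fraction), val_rng)
    val_patches = [next(val_sampler) for _ in range(config.val_patches)]

    history: list[float] = []
    best_state = None
    stopper = EarlyStopper(config.patience)
    mpp = images[0].mpp if images else 0.25

    for epoch in range(config.max_epochs):
        for _ in range(config.iters_per_epoch):
            hes, phh3s, boxes = [], [], []
            for _ in range(config.batch_size):
                sample = next(sampler)
                he, phh3, pts = augment_pair(
                    sample["he"], sample["phh3"] if config.mode == "dual" else None,
                    sample["points"], rng, config)
                hes.append(he)
                if config.mode == "dual":
                    phh3s.append(phh3)
                boxes.append(points_to_boxes(pts, config.box_size_px,
                                             (config.patch_size, config.patch_size)))
            he_t = _batch_tensor(hes)
            phh3_t = _batch_tensor(phh3s) if config.mode == "dual" else None
            loss = model.loss(he_t, boxes, phh3_t)
            opt.zero_grad()
            loss.backward()
            opt.step()

        ap = _val_ap(model, val_patches, config, mpp, average_precision, _nms)
        history.append(ap)
        if verbose:
            print(f"epoch {epoch}: val AP {ap:.3f}")
        if ap > stopper.best:
            best_state = model.state_dict()
        if stopper.update(ap):
            break
    if best_state is not None:
        model.load_state_dict(best_state)
    model.best_val_ap = stopper.best if history else None
    return model, history


def _with(config: DetectorConfig, **kw) -> DetectorConfig:
    d = copy.copy(config)
    for k, v in kw.items():
        setattr(d, k, v)
    return d


def _val_ap(model, val_patches, config, mpp, average_precision, nms) -> float:
    """Pooled AP over the validation patches: each patch is offset into its
    own region of a virtual plane so detections and labels never collide."""
    dets, gts = [], []
    offset = 0.0
    step = 4.0 * config.patch_size
    for vp in val_patches:
        d = model.predict_patch(vp["he"],
                                vp["phh3"] if config.mode == "dual" else None,
                                score_threshold=0.05)
        d = nms(d, config.nms_threshold)
        for det in d:
            dets.append(Detection(x=det.x + offset, y=det.y,
                                  box=(det.box[0] + offset, det.box[1],
                                       det.box[2] + offset, det.box[3]),
                                  score=det.score))
        gts.extend((x + offset, y) for (x, y) in vp["points"])
        offset += step
    if not gts:
        return 0.0
    return average_precision(dets, gts, radius_um=7.5, mpp=mpp).ap


def model_summary(model: FCOSModel) -> dict:
    """Parameter accounting per component."""
    total = count_parameters(model)
    parts = {"backbone_he": count_parameters(model.backbone_he)}
    if model.config.mode == "dual":
        parts["backbone_phh3"] = count_parameters(model.backbone_phh3)
        parts["fusion"] = sum(count_parameters(f) for f in model.fusion)
    parts["pyramid_and_heads"] = total - sum(parts.values())
    return {"total": total, "parts": parts, "mode": model.config.mode,
            "backbone": model.config.backbone}
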