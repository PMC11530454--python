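"""Tiled whole-image inference, distance-matched average precision, and the
train-label x eval-label experiment grid.

Test images are divided into overlapping tiles (the last row/column is
clamped to the border so every pixel is covered), per-tile detections are
transferred to global coordinates, and duplicates are removed with a single
global IoU-based non-maximum suppression pass.  AP uses greedy
centre-distance matching of score-ranked detections to ground-truth points
within one nucleus diameter, and the all-point interpolated area under the
precision-recall curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import Detection, ImagePair, LabelSet, Split, NUCLEUS_DIAMETER_UM

__all__ = ["EvalResult", "ResultGrid", "tile_origins", "tiled_inference", "nms",
           "average_precision", "evaluate_on_images", "run_experiment_grid"]


@dataclass
class EvalResult:
    ap: float
    precision: np.ndarray
    recall: np.ndarray
    radius_um: float
    tp: int
    fp: int
    fn: int


def tile_origins(length: int, tile: int, overlap: int) -> list[int]:
    """1-D tile origins: stride = tile - overlap, last origin clamped to the
    border, duplicates removed."""
    if tile >= length:
        return [0]
    stride = tile - overlap
    origins = list(range(0, length - tile + 1, stride))
    if origins[-1] != length - tile:
        origins.append(length - tile)
    return sorted(set(origins))


def _iou(a: tuple, b: tuple) -> float:
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union


def nms(detections: list[Detection], iou_threshold: float = 0.30) -> list[Detection]:
    """Greedy IoU-based non-maximum suppression, highest score first
    (deterministic: score ties broken by position)."""
    if not detections:
        return []
    boxes = np.array([d.box for d in detections], dtype=float)
    scores = np.array([d.score for d in detections], dtype=float)
    xs = np.array([d.x for d in detections])
    ys = np.array([d.y for d in detections])
    order = np.lexsort((ys, xs, -scores))
    areas = (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1])
    kept_idx: list[int] = []
    alive = np.ones(len(order), dtype=bool)
    for pos, i in enumerate(order):
        if not alive[pos]:
            continue
        kept_idx.append(int(i))
        rest = order[pos + 1:]
        sub = alive[pos + 1:]
        if rest.size == 0:
            continue
        iw = (np.minimum(boxes[rest, 2], boxes[i, 2])
              - np.maximum(boxes[rest, 0], boxes[i, 0]))
        ih = (np.minimum(boxes[rest, 3], boxes[i, 3])
              - np.maximum(boxes[rest, 1], boxes[i, 1]))
        inter = np.clip(iw, 0, None) * np.clip(ih, 0, None)
        iou = inter / (areas[rest] + areas[i] - inter)
        alive[pos + 1:] = sub & (iou <= iou_threshold)
    return [detections[i] for i in kept_idx]


def nms_distance(detections: list[Detection], radius_px: float) -> list[Detection]:
    """Centre-distance alternative to IoU suppression."""
    order = sorted(range(len(detections)),
                   key=lambda i: (-detections[i].score, detections[i].x,
                                  detections[i].y))
    kept: list[Detection] = []
    for i in order:
        d = detections[i]
        if all(np.hypot(d.x - k.x, d.y - k.y) > radius_px for k in kept):
            kept.append(d)
    return kept


def tiled_inference(model, image_pair: ImagePair, tile: int = 512,
                    overlap: int = 50, score_threshold: float | None = None,
                    nms_threshold: float | None = None) -> list[Detection]:
    """Run a detector over overlapping tiles and fuse globally with NMS."""
    if not tile > overlap >= 0:
        raise ValueError("need tile > overlap >= 0")
    he = image_pair.he_image
    phh3 = image_pair.phh3_image
    h, w = he.shape[:2]
    dual = model.config.mode == "dual"
    thr = model.config.score_threshold if score_threshold is None else score_threshold
    nms_thr = model.config.nms_threshold if nms_threshold is None else nms_threshold

    stride = model.strides[-1]
    tile = min(tile, max(h, w))
    tile -= tile % stride  # keep the tile compatible with the backbone

    def snapped(length):
        # snap origins down to the stride grid so the convolutional feature
        # grids of all tiles align with a full-image pass; snapping only
        # moves origins left, and the border is re-covered if needed
        base = sorted({o - (o % stride) for o in tile_origins(length, tile,
                                                              overlap)})
        if base[-1] + tile < length:
            base.append(length - tile)
        return base

    xs_origins = snapped(w)
    ys_origins = snapped(h)
    origins = [(x0, y0) for y0 in ys_origins for x0 in xs_origins]

    def owner(origin_list, g):
        # the tile in which a coordinate is most interior: convolution padding
        # at interior tile edges degrades context, so each detection is kept
        # only from its maximal-context tile
        best, best_d = None, -1.0
        for o in origin_list:
            if o <= g <= o + tile:
                d = min(g - o, o + tile - g)
                if d > best_d:
                    best, best_d = o, d
        return best

    all_dets: list[Detection] = []
    chunk = 16  # bound the activation memory of one batched forward pass
    for c0 in range(0, len(origins), chunk):
        block = origins[c0:c0 + chunk]
        he_b = np.stack([he[y0:y0 + tile, x0:x0 + tile] for x0, y0 in block])
        ph_b = np.stack([phh3[y0:y0 + tile, x0:x0 + tile] for x0, y0 in block]) \
            if dual else None
        topk = max(200, (tile * tile) // 80)  # pre-NMS cap scales with area
        for (x0, y0), dets in zip(block,
                                  model.predict_batch(he_b, ph_b,
                                                      score_threshold=thr,
                                                      pre_nms_topk=topk)):
            for d in dets:
                gx, gy = d.x + x0, d.y + y0
                if owner(xs_origins, gx) != x0 or owner(ys_origins, gy) != y0:
                    continue
                all_dets.append(Detection(
                    x=gx, y=gy,
                    box=(d.box[0] + x0, d.box[1] + y0, d.box[2] + x0, d.box[3] + y0),
                    score=d.score))
    return nms(all_dets, nms_thr)


def average_precision(detections: list[Detection],
                      gt_points: list[tuple[float, float]],
                      radius_um: float = NUCLEUS_DIAMETER_UM,
                      mpp: float = 0.25, criterion: str = "distance",
                      gt_box_size_px: float = 50.0,
                      iou_threshold: float = 0.5) -> EvalResult:
    """Distance-matched AP: rank by score, greedily match each detection to
    the nearest unmatched ground-truth point within the radius, accumulate
    the PR curve, and integrate the all-point interpolation.

    ``criterion="iou"`` is the box-overlap alternative: ground-truth points
    become squares of ``gt_box_size_px`` and a detection matches the free
    ground truth of highest IoU above ``iou_threshold``.
    """
    if len(gt_points) == 0:
        raise ValueError("AP undefined for empty ground truth")
    if criterion not in ("distance", "iou"):
        raise ValueError(f"unknown matching criterion {criterion!r}")
    radius_px = radius_um / mpp
    n_gt = len(gt_points)
    if len(detections) == 0:
        return EvalResult(ap=0.0, precision=np.array([]), recall=np.array([]),
                          radius_um=radius_um, tp=0, fp=0, fn=n_gt)
    gt = np.asarray(gt_points, dtype=float)[:, :2]
    order = sorted(range(len(detections)),
                   key=lambda i: (-detections[i].score, detections[i].x,
                                  detections[i].y))
    matched = np.zeros(n_gt, dtype=bool)
    tp_flags = np.zeros(len(order), dtype=bool)
    half = gt_box_size_px / 2.0
    for rank, i in enumerate(order):
        d = detections[i]
        if criterion == "distance":
            dist = np.hypot(gt[:, 0] - d.x, gt[:, 1] - d.y)
            dist[matched] = np.inf
            j = int(np.argmin(dist))
            hit = dist[j] <= radius_px
        else:
            ious = np.array([_iou(d.box, (x - half, y - half, x + half,
                                          y + half)) for x, y in gt])
            ious[matched] = -1.0
            j = int(np.argmax(ious))
            hit = ious[j] >= iou_threshold
        if hit:
            matched[j] = True
            tp_flags[rank] = True
    tp_cum = np.cumsum(tp_flags)
    fp_cum = np.cumsum(~tp_flags)
    precision = tp_cum / (tp_cum + fp_cum)
    recall = tp_cum / n_gt
    # all-point interpolation: precision envelope, integrate over recall steps
    prec_env = np.maximum.accumulate(precision[::-1])[::-1]
    r_prev = 0.0
    ap = 0.0
    for p, r in zip(prec_env, recall):
        if r > r_prev:
            ap += (r - r_prev) * p
            r_prev = r
    tp = int(tp_cum[-1])
    return EvalResult(ap=float(ap), precision=precision, recall=recall,
                      radius_um=radius_um, tp=tp, fp=int(fp_cum[-1]), fn=n_gt - tp)


def evaluate_on_images(model, images: list[ImagePair], label_set: LabelSet,
                       tile: int = 512, overlap: int = 50,
                       radius_um: float = NUCLEUS_DIAMETER_UM,
                       detections_cache: dict | None = None,
                       score_threshold: float = 0.05) -> EvalResult:
    """Pooled AP of a model over a set of images under one label set.

    Detections do not depend on the label set, so a cache keyed by image id
    lets several evaluation label sets share one inference pass.  The AP is
    computed over the detections emitted above ``score_threshold`` —
    typically either a permissive floor or the model's validation-selected
    operating point (see ``operating_threshold``).
    """
    dets: list[Detection] = []
    gts: list[tuple[float, float]] = []
    offset = 0.0
    for im in images:
        if detections_cache is not None and im.image_id in detections_cache:
            im_dets = detections_cache[im.image_id]
        else:
            im_dets = tiled_inference(model, im, tile=tile, overlap=overlap,
                                      score_threshold=score_threshold)
            if detections_cache is not None:
                detections_cache[im.image_id] = im_dets
        for d in im_dets:
            dets.append(Detection(x=d.x + offset, y=d.y,
                                  box=(d.box[0] + offset, d.box[1],
                                       d.box[2] + offset, d.box[3]),
                                  score=d.score))
        gts.extend((x + offset, y) for (x, y, _s) in
                   label_set.points.get(im.image_id, []))
        offset += 4.0 * max(im.he_image.shape[:2])
    if not gts:
        raise ValueError("no ground-truth points in the evaluation label sets")
    return average_precision(dets, gts, radius_um=radius_um, mpp=images[0].mpp)


def operating_threshold(model, images: list[ImagePair], label_set: LabelSet,
                        tile: int = 512, overlap: int = 50,
                        radius_um: float = NUCLEUS_DIAMETER_UM,
                        candidates: np.ndarray | None = None) -> float:
    """Score threshold maximising instance F1 on held-out images.

    Detector scores are not calibrated across runs; the operating point for
    hard TP/FN decisions is therefore chosen on validation data, the same way
    a deployed counting pipeline would fix its cutoff.
    """
    from .agreement import match_points

    if candidates is None:
        candidates = np.arange(0.05, 0.95, 0.05)
    per_image = [(tiled_inference(model, im, tile=tile, overlap=overlap,
                                  score_threshold=float(candidates.min())),
                  [(x, y) for x, y, _s in label_set.points.get(im.image_id, [])],
                  im.mpp) for im in images]
    best_thr, best_f1 = float(candidates[0]), -1.0
    for thr in candidates:
        tp = fp = fn = 0
        for dets, gts, mpp in per_image:
            kept = [(d.x, d.y) for d in dets if d.score >= thr]
            m = match_points(kept, gts, radius_um=radius_um, mpp=mpp)
            tp += len(m.pairs)
            fp += len(m.unmatched_predictions)
            fn += len(m.unmatched_references)
        f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
        if f1 > best_f1:
            best_thr, best_f1 = float(thr), f1
    return best_thr


@dataclass
class ResultGrid:
    """mean +- sd AP per (model, train label set, eval label set) cell."""

    cells: dict[tuple[str, str, str], list[float]] = field(default_factory=dict)

    def add(self, model_name: str, train_labels: str, eval_labels: str, ap: float):
        self.cells.setdefault((model_name, train_labels, eval_labels), []).append(ap)

    def mean(self, model_name: str, train_labels: str, eval_labels: str) -> float:
        return float(np.mean(self.cells[(model_name, train_labels, eval_labels)]))

    def sd(self, model_name: str, train_labels: str, eval_labels: str) -> float:
        v = self.cells[(model_name, train_labels, eval_labels)]
        return float(np.std(v, ddof=1)) if len(v) > 1 else 0.0

    def to_table(self):
        import pandas as pd
        rows = []
        for (m, tr, ev), aps in sorted(self.cells.items()):
            rows.append({"model": m, "train_labels": tr, "eval_labels": ev,
                         "ap_mean": float(np.mean(aps)),
                         "ap_sd": float(np.std(aps, ddof=1)) if len(aps) > 1 else 0.0,
                         "n_runs": len(aps)})
        return pd.DataFrame(rows)

    def formatted(self) -> str:
        df = self.to_table()
        lines = ["model                train-labels          eval-labels           AP"]
        for _, r in df.iterrows():
            lines.append(f"{r['model']:<20} {r['train_labels']:<21} "
                         f"{r['eval_labels']:<21} {r['ap_mean']:.3f} ± {r['ap_sd']:.3f}")
        return "\n".join(lines)


def run_experiment_grid(model_configs: dict, label_sets: dict[str, LabelSet],
                        splits: list[Split], images: list[ImagePair],
                        train_label_names: tuple[str, ...] = ("he_only_labels",
                                                              "phh3_assisted_labels"),
                        eval_label_names: tuple[str, ...] | None = None,
                        tile: int = 512, overlap: int = 50,
                        seeds: tuple[int, ...] = (0,),
                        holdout: tuple[list[ImagePair], dict] | None = None
                        ) -> ResultGrid:
    """Train every model config on every training label set and every split,
    then evaluate each trained model on the split's test images under every
    evaluation label set (detections shared across label sets).

    ``holdout`` is an optional independent dataset, (images, label sets);
    every trained model is additionally evaluated on it under each of its
    label sets, reported with eval names prefixed ``holdout:``.
    """
    from .detector import train_detector  # lazy import: no cycle at load

    import copy as _copy

    if eval_label_names is None:
        eval_label_names = tuple(label_sets.keys())
    for name in set(train_label_names) | set(eval_label_names):
        if name not in label_sets:
            raise ValueError(f"label set {name!r} missing")
    by_id = {im.image_id: im for im in images}
    grid = ResultGrid()
    for model_name, base_cfg in model_configs.items():
        for train_name in train_label_names:
            for split in splits:
                for seed in seeds:
                    cfg = _copy.copy(base_cfg)
                    cfg.seed = int(seed * 1009 + split.split_index)
                    model, _hist = train_detector(cfg, split,
                                                  label_sets[train_name], images)
                    test_imgs = [by_id[i] for i in split.test if i in by_id]
                    cache: dict = {}
                    for eval_name in eval_label_names:
                        res = evaluate_on_images(model, test_imgs,
                                                 label_sets[eval_name],
                                                 tile=tile, overlap=overlap,
                                                 detections_cache=cache)
                        grid.add(model_name, train_name, eval_name, res.ap)
                    if holdout is not None:
                        h_imgs, h_sets = holdout
                        h_cache: dict = {}
                        for h_name, h_set in h_sets.items():
                            res = evaluate_on_images(model, h_imgs, h_set,
                                                     tile=tile, overlap=overlap,
                                                     detections_cache=h_cache)
                            grid.add(model_name, train_name,
                                     f"holdout:{h_name}", res.ap)
    return grid
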