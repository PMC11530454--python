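"""Independent reference implementations used to cross-check the package.

These are deliberately written with plain loops and a structure different
from the library code; they implement the same stated rules (ordered greedy
clustering, maximum-cardinality matching, exhaustive PR enumeration, textbook
two-way ANOVA) and serve as oracles in the tests.
"""

from __future__ import annotations

import numpy as np


def brute_force_clusters(annotations, radius_px: float):
    """Ordered greedy clustering, re-coded independently.

    Processing order: sorted by (rater_id, x, y).  Each annotation joins the
    nearest cluster whose running-mean centroid lies within radius_px and
    which has no member of the same rater (ties: lowest cluster index);
    otherwise it opens a new cluster.  Returns member index sets in the
    processing order.
    """
    order = sorted(range(len(annotations)),
                   key=lambda i: (annotations[i].rater_id, annotations[i].x,
                                  annotations[i].y))
    clusters = []  # each: {"members": [ann indices], "sum": [sx, sy]}
    for idx in order:
        a = annotations[idx]
        best_j, best_d = -1, None
        for j, cl in enumerate(clusters):
            n = len(cl["members"])
            cx, cy = cl["sum"][0] / n, cl["sum"][1] / n
            d = ((cx - a.x) ** 2 + (cy - a.y) ** 2) ** 0.5
            if d <= radius_px:
                raters = {annotations[m].rater_id for m in cl["members"]}
                if a.rater_id not in raters:
                    if best_d is None or d < best_d:
                        best_j, best_d = j, d
        if best_j >= 0:
            clusters[best_j]["members"].append(idx)
            clusters[best_j]["sum"][0] += a.x
            clusters[best_j]["sum"][1] += a.y
        else:
            clusters.append({"members": [idx], "sum": [a.x, a.y]})
    return [frozenset(cl["members"]) for cl in clusters]


def max_matching_size(predictions, references, radius_px: float) -> int:
    """Maximum-cardinality matching size on the within-radius bipartite graph."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import maximum_bipartite_matching

    if not predictions or not references:
        return 0
    p = np.asarray(predictions, dtype=float)
    r = np.asarray(references, dtype=float)
    d = np.hypot(p[:, None, 0] - r[None, :, 0], p[:, None, 1] - r[None, :, 1])
    graph = csr_matrix((d <= radius_px).astype(int))
    match = maximum_bipartite_matching(graph, perm_type="column")
    return int((match >= 0).sum())


def brute_force_ap(det_points, det_scores, gt_points, radius_px: float) -> float:
    """AP by explicit enumeration: rank detections by score (ties by x, y),
    greedily match each to its nearest free ground-truth point, build the PR
    sequence, take the running maximum of precision from the right, and sum
    precision-weighted recall increments."""
    n = len(det_points)
    if n == 0:
        return 0.0
    order = sorted(range(n), key=lambda i: (-det_scores[i], det_points[i][0],
                                            det_points[i][1]))
    free = [True] * len(gt_points)
    is_tp = []
    for i in order:
        px, py = det_points[i]
        best_j, best_d = -1, None
        for j, (gx, gy) in enumerate(gt_points):
            if not free[j]:
                continue
            d = ((gx - px) ** 2 + (gy - py) ** 2) ** 0.5
            if d <= radius_px and (best_d is None or d < best_d):
                best_j, best_d = j, d
        if best_j >= 0:
            free[best_j] = False
            is_tp.append(True)
        else:
            is_tp.append(False)
    precisions, recalls = [], []
    tp = 0
    for k, flag in enumerate(is_tp, start=1):
        tp += int(flag)
        precisions.append(tp / k)
        recalls.append(tp / len(gt_points))
    # interpolated precision: max over suffix
    interp = [max(precisions[i:]) for i in range(len(precisions))]
    ap, prev_r = 0.0, 0.0
    for p_i, r_i in zip(interp, recalls):
        if r_i > prev_r:
            ap += (r_i - prev_r) * p_i
            prev_r = r_i
    return ap


def anova_icc(counts: np.ndarray) -> tuple[float, float]:
    """Textbook two-way ANOVA mean squares -> (single-rater, averaged) ICC
    under the fixed-raters consistency model, computed with explicit loops."""
    c = np.asarray(counts, dtype=float)
    n, k = c.shape
    grand = c.sum() / (n * k)
    ss_rows = 0.0
    for i in range(n):
        ss_rows += k * (c[i].mean() - grand) ** 2
    ss_cols = 0.0
    for j in range(k):
        ss_cols += n * (c[:, j].mean() - grand) ** 2
    ss_tot = 0.0
    for i in range(n):
        for j in range(k):
            ss_tot += (c[i, j] - grand) ** 2
    ms_rows = ss_rows / (n - 1)
    ms_err = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    icc1 = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
    icck = (ms_rows - ms_err) / ms_rows
    return icc1, icck
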