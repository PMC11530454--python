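"""Inter-rater agreement statistics.

Instance-level precision/recall/F1 of each rater against the leave-one-out
consensus of the remaining panel, the intraclass correlation coefficient of
mitotic counts for a fixed panel of k raters (two-way mixed effects,
consistency; reported as the average-of-k-raters form, equivalent to the
Spearman-Brown adjusted single-rater reliability), Fleiss' kappa for
categorical verdicts, and the paired t-test protocol with Shapiro-Wilk
normality checks and Bonferroni correction.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import (ConsensusSet, Matching, PointAnnotation,
                        NUCLEUS_DIAMETER_UM)

__all__ = ["match_points", "instance_prf", "icc_avg_fixed_raters", "fleiss_kappa",
           "paired_metric_test", "rater_prf_table", "ICCResult", "PairedTestReport"]


def match_points(predictions: list[tuple[float, float]],
                 references: list[tuple[float, float]],
                 radius_um: float = NUCLEUS_DIAMETER_UM,
                 mpp: float = 0.25) -> Matching:
    """Greedy one-to-one matching by ascending pairwise distance.

    Only pairs closer than the radius are eligible; ties are broken by
    (prediction index, reference index), making the result deterministic.
    """
    if mpp <= 0:
        raise ValueError("mpp must be positive")
    radius_px = radius_um / mpp
    np_, nr = len(predictions), len(references)
    if np_ == 0 or nr == 0:
        return Matching(pairs=[], unmatched_predictions=list(range(np_)),
                        unmatched_references=list(range(nr)))
    p = np.asarray(predictions, dtype=float)
    r = np.asarray(references, dtype=float)
    d = np.hypot(p[:, None, 0] - r[None, :, 0], p[:, None, 1] - r[None, :, 1])
    pi, ri = np.nonzero(d <= radius_px)
    order = np.lexsort((ri, pi, d[pi, ri]))  # distance, then index order
    used_p = np.zeros(np_, dtype=bool)
    used_r = np.zeros(nr, dtype=bool)
    pairs = []
    for k in order:
        i, j = int(pi[k]), int(ri[k])
        if not used_p[i] and not used_r[j]:
            pairs.append((i, j))
            used_p[i] = True
            used_r[j] = True
    return Matching(pairs=pairs,
                    unmatched_predictions=[i for i in range(np_) if not used_p[i]],
                    unmatched_references=[j for j in range(nr) if not used_r[j]])


def instance_prf(rater_points: list[tuple[float, float]],
                 consensus_points: list[tuple[float, float]],
                 radius_um: float = NUCLEUS_DIAMETER_UM,
                 mpp: float = 0.25) -> tuple[float, float, float]:
    """Precision, recall and F1 of a rater against a consensus; 0/0 -> 0."""
    m = match_points(rater_points, consensus_points, radius_um=radius_um, mpp=mpp)
    tp = len(m.pairs)
    fp = len(m.unmatched_predictions)
    fn = len(m.unmatched_references)
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 \
        else 0.0
    return precision, recall, f1


def rater_prf_table(annotations: list[PointAnnotation], mpp: float,
                    radius_um: float = NUCLEUS_DIAMETER_UM,
                    classes: tuple[str, ...] | None = None,
                    loo_fn=None) -> dict[str, tuple[float, float, float]]:
    """Each rater's P/R/F1 pooled over images against the leave-one-out
    consensus of the remaining panel."""
    from .consensus import leave_one_out_consensus  # local import: no cycle at load

    if classes is not None:
        annotations = [a for a in annotations if a.cls in classes]
    raters = sorted({a.rater_id for a in annotations})
    by_rater_img: dict[str, dict[str, list[tuple[float, float]]]] = defaultdict(
        lambda: defaultdict(list))
    for a in annotations:
        by_rater_img[a.rater_id][a.image_id].append((a.x, a.y))
    loo = loo_fn or (lambda anns, r: leave_one_out_consensus(anns, r, radius_um=radius_um,
                                                             mpp=mpp))
    table = {}
    for rater in raters:
        cons: ConsensusSet = loo(annotations, rater)
        tp = fp = fn = 0
        images = set(cons.points) | set(by_rater_img[rater])
        for img in images:
            preds = by_rater_img[rater].get(img, [])
            refs = [(x, y) for x, y, _ in cons.points.get(img, [])]
            m = match_points(preds, refs, radius_um=radius_um, mpp=mpp)
            tp += len(m.pairs)
            fp += len(m.unmatched_predictions)
            fn += len(m.unmatched_references)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall \
            else 0.0
        table[rater] = (precision, recall, f1)
    return table


# ---------------------------------------------------------------------------
# ICC


@dataclass
class ICCResult:
    icc_k: float      # average of k fixed raters (two-way mixed, consistency)
    icc_1: float      # single fixed rater
    ms_targets: float
    ms_error: float


def icc_avg_fixed_raters(counts: np.ndarray) -> ICCResult:
    """ICC for a fixed panel of k raters, averaged over the k ratings.

    Two-way mixed effects, consistency definition, computed from the two-way
    ANOVA mean squares: ICC_k = (MS_R - MS_E) / MS_R, with the single-rater
    form ICC_1 = (MS_R - MS_E) / (MS_R + (k-1) MS_E); the two are linked by
    the Spearman-Brown formula ICC_k = k ICC_1 / (1 + (k-1) ICC_1).
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 2 or c.shape[0] < 2 or c.shape[1] < 2:
        raise ValueError("counts must be an n_targets x k_raters matrix, n,k >= 2")
    if not np.all(np.isfinite(c)):
        raise ValueError("counts must be finite")
    n, k = c.shape
    grand = c.mean()
    row_means = c.mean(axis=1)
    col_means = c.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((c - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_rows <= 0:
        raise ValueError("zero between-target variance: ICC undefined")
    icc_k = (ms_rows - ms_err) / ms_rows
    icc_1 = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
    return ICCResult(icc_k=float(icc_k), icc_1=float(icc_1),
                     ms_targets=float(ms_rows), ms_error=float(ms_err))


def icc_random_raters(counts: np.ndarray) -> float:
    """Two-way random-effects, absolute-agreement, average-of-k ICC(2,k);
    offered as the alternative estimator behind this flag."""
    c = np.asarray(counts, dtype=float)
    n, k = c.shape
    grand = c.mean()
    row_means = c.mean(axis=1)
    col_means = c.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((c - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return float((ms_rows - ms_err) / (ms_rows + (ms_cols - ms_err) / n))


def mitotic_count_matrix(annotations: list[PointAnnotation],
                         image_ids: list[str], rater_ids: list[str],
                         classes: tuple[str, ...] | None = None) -> np.ndarray:
    """n_images x k_raters matrix of per-rater mitotic counts."""
    counts = np.zeros((len(image_ids), len(rater_ids)), dtype=float)
    img_idx = {img: i for i, img in enumerate(image_ids)}
    rat_idx = {r: j for j, r in enumerate(rater_ids)}
    for a in annotations:
        if classes is not None and a.cls not in classes:
            continue
        if a.image_id in img_idx and a.rater_id in rat_idx:
            counts[img_idx[a.image_id], rat_idx[a.rater_id]] += 1
    return counts


# ---------------------------------------------------------------------------
# Fleiss' kappa


def fleiss_kappa(ratings: np.ndarray) -> float:
    """Fleiss' kappa from an n_subjects x n_categories count matrix.

    Rows must sum to the same number of raters; kappa = (Pbar - Pe) / (1 - Pe).
    """
    r = np.asarray(ratings, dtype=float)
    if r.ndim != 2:
        raise ValueError("ratings must be a 2-D count matrix")
    row_sums = r.sum(axis=1)
    m = row_sums[0]
    if m < 2 or not np.all(row_sums == m):
        raise ValueError("every subject must be rated by the same number "
                         "(>= 2) of raters")
    n = r.shape[0]
    p_cat = r.sum(axis=0) / (n * m)
    pe = float(np.sum(p_cat ** 2))
    if pe >= 1.0:
        raise ValueError("all ratings fall in a single category: "
                         "chance agreement is 1, kappa undefined")
    p_subj = (np.sum(r * r, axis=1) - m) / (m * (m - 1))
    pbar = float(p_subj.mean())
    return (pbar - pe) / (1.0 - pe)


# ---------------------------------------------------------------------------
# paired significance testing


@dataclass
class PairedTestReport:
    t_statistic: float
    df: int
    p_value: float
    shapiro_p: float
    alpha: float
    alpha_corrected: float
    significant: bool
    zero_variance: bool = False


def paired_metric_test(values_p1, values_p2, n_tests: int = 1,
                       alpha: float = 0.05) -> PairedTestReport:
    """Paired t-test on per-rater metric differences.

    Normality of the differences is reported via Shapiro-Wilk and the
    significance level is Bonferroni-corrected by the number of metrics
    tested.  A zero-variance difference vector is reported explicitly
    (t undefined) rather than raising.
    """
    a = np.asarray(values_p1, dtype=float)
    b = np.asarray(values_p2, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two equal-length 1-D vectors, k >= 3")
    diff = a - b
    k = len(a)
    alpha_corr = alpha / n_tests
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff, 0.0):
            return PairedTestReport(t_statistic=0.0, df=k - 1, p_value=1.0,
                                    shapiro_p=np.nan, alpha=alpha,
                                    alpha_corrected=alpha_corr, significant=False,
                                    zero_variance=True)
        return PairedTestReport(t_statistic=np.nan, df=k - 1, p_value=np.nan,
                                shapiro_p=np.nan, alpha=alpha,
                                alpha_corrected=alpha_corr, significant=False,
                                zero_variance=True)
    t, p = stats.ttest_rel(a, b)
    sw_p = float(stats.shapiro(diff).pvalue)
    return PairedTestReport(t_statistic=float(t), df=k - 1, p_value=float(p),
                            shapiro_p=sw_p, alpha=alpha, alpha_corrected=alpha_corr,
                            significant=bool(p < alpha_corr), zero_variance=False)
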