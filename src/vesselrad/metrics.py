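"""Segmentation agreement statistics.

Overlap scores (Dice, Jaccard, precision/recall/F), Lin's concordance
correlation for volume agreement, an overlap-to-disagreement error ratio, and
Bland-Altman agreement statistics for paired measurements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass
class SegScores:
    """All pairwise segmentation scores for one (prediction, truth) pair."""

    dice: float
    jaccard: float
    precision: float
    recall: float
    f_score: float
    ccc: float
    error_ratio: float

    def to_dict(self) -> dict:
        return {k: float(v) for k, v in self.__dict__.items()}


@dataclass
class AgreementStats:
    """Bland-Altman bias and 1.96-SD limits of agreement for paired values."""

    bias: float
    loa_low: float
    loa_high: float
    percent_differences: np.ndarray = field(repr=False)


def _check_masks(a, b):
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a, b


def dice(a, b) -> float:
    """Dice similarity coefficient 2|A^B| / (|A|+|B|); 1 if both masks empty."""
    a, b = _check_masks(a, b)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.count_nonzero(a & b) / denom)


def jaccard(a, b) -> float:
    """Jaccard index |A^B| / |AvB|; 1 if both masks empty."""
    a, b = _check_masks(a, b)
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return float(np.count_nonzero(a & b) / union)


def precision_recall_f(pred, truth, tolerance_px: float = 0) -> tuple[float, float, float]:
    """Precision, recall and their harmonic mean (F-score).

    With ``tolerance_px`` > 0 the scores are boundary-tolerant: a predicted
    pixel counts as correct if it lies within that distance of the truth mask
    and vice versa, which measures how closely the predicted boundary tracks
    the true one.  With tolerance 0, F equals Dice.  0/0 cases resolve to 0
    with a warning.
    """
    pred, truth = _check_masks(pred, truth)
    if tolerance_px > 0:
        truth_zone = _dilate(truth, tolerance_px)
        pred_zone = _dilate(pred, tolerance_px)
    else:
        truth_zone, pred_zone = truth, pred
    n_pred = np.count_nonzero(pred)
    n_truth = np.count_nonzero(truth)
    precision = np.count_nonzero(pred & truth_zone) / n_pred if n_pred else 0.0
    recall = np.count_nonzero(truth & pred_zone) / n_truth if n_truth else 0.0
    if n_pred == 0 or n_truth == 0:
        warnings.warn("empty mask in precision/recall: 0/0 resolved to 0")
    f = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return float(precision), float(recall), float(f)


def _dilate(mask: np.ndarray, radius_px: float) -> np.ndarray:
    """Dilation by a Euclidean disk, via the background distance transform."""
    if not mask.any():
        return mask
    dist = ndimage.distance_transform_edt(~mask)
    return dist <= radius_px


def ccc(x, y) -> float:
    """Lin's concordance correlation coefficient of paired measurements.

    2 cov(x,y) / (var x + var y + (mean x - mean y)^2), with population
    (n-denominator) moments.  Equals 1 exactly when every pair lies on the
    identity line; symmetric in its arguments.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape or x.size < 2:
        raise ValueError("ccc needs two equal-length sequences of length >= 2")
    vx, vy = np.var(x), np.var(y)
    mx, my = np.mean(x), np.mean(y)
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:  # both constant with equal means: perfect concordance
        return 1.0
    if vx == 0 or vy == 0:
        warnings.warn("one sequence is constant; concordance is 0 by convention")
        return 0.0
    cov = np.mean((x - mx) * (y - my))
    return float(2 * cov / denom)


def error_ratio(auto, manual) -> float:
    """Overlap voxels divided by disagreeing (symmetric-difference) voxels.

    Higher is better; identical non-empty masks give inf (flagged perfect),
    two empty masks give nan (undefined).
    """
    auto, manual = _check_masks(auto, manual)
    overlap = np.count_nonzero(auto & manual)
    disagree = np.count_nonzero(auto ^ manual)
    if disagree == 0:
        if overlap == 0:
            warnings.warn("error ratio undefined: both masks empty")
            return float("nan")
        warnings.warn("perfect agreement: error ratio is infinite")
        return float("inf")
    return float(overlap / disagree)


def bland_altman(x, y) -> AgreementStats:
    """Bland-Altman agreement for paired values (e.g. per-bin radii counts).

    bias = mean(x - y); limits of agreement = bias +/- 1.96 sd(x - y);
    per-pair percent difference = |x - y| / mean(x, y) x 100 (nan where the
    pair mean is 0).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("paired sequences must have equal length")
    d = x - y
    bias = float(np.mean(d))
    sd = float(np.std(d))
    pair_mean = (x + y) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(pair_mean != 0, np.abs(d) / pair_mean * 100.0, np.nan)
    return AgreementStats(bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
                          percent_differences=pct)


def _component_volume_pairs(pred: np.ndarray, truth: np.ndarray) -> list[tuple[float, float]]:
    """1-1 matched per-component (pred, truth) volume pairs.

    Truth components (largest first) greedily claim the unclaimed prediction
    component they overlap most; unmatched components on either side pair
    with volume 0.
    """
    structure = ndimage.generate_binary_structure(2, 2)
    tl, tn = ndimage.label(truth, structure=structure)
    pl, pn = ndimage.label(pred, structure=structure)
    t_sizes = np.bincount(tl.ravel(), minlength=tn + 1)
    p_sizes = np.bincount(pl.ravel(), minlength=pn + 1)
    pairs = []
    used_pred: set[int] = set()
    for t in sorted(range(1, tn + 1), key=lambda i: -t_sizes[i]):
        tmask = tl == t
        overlap_ids, counts = np.unique(pl[tmask & pred], return_counts=True)
        keep = overlap_ids > 0
        overlap_ids, counts = overlap_ids[keep], counts[keep]
        order = np.argsort(-counts)
        best = next((int(overlap_ids[i]) for i in order if int(overlap_ids[i]) not in used_pred), 0)
        if best:
            used_pred.add(best)
        pairs.append((float(p_sizes[best]) if best else 0.0, float(t_sizes[t])))
    for p in range(1, pn + 1):
        if p not in used_pred:
            pairs.append((float(p_sizes[p]), 0.0))
    return pairs


def volume_ccc(pred, truth, bin_edges=None) -> float:
    """Concordance of volume agreement between two masks.

    Pairs per-connected-component pixel counts matched 1-1 by maximal
    overlap.  When fewer than two pairs actually overlap (a single vascular
    tree, or heavy fragmentation on one side only), falls back to pairing
    per-radius-bin centerline counts of the two masks, which compares the
    calibre spectra instead.
    """
    pred, truth = _check_masks(pred, truth)
    pairs = _component_volume_pairs(pred, truth)
    n_overlapping = sum(1 for x, y in pairs if x > 0 and y > 0)
    if len(pairs) >= 2 and n_overlapping >= 2:
        x, y = zip(*pairs)
        return ccc(x, y)
    # single-component fallback: per-bin radii histogram counts
    from .radii import radii_histogram, radii_map, skeletonize

    counts = []
    for m in (pred, truth):
        rm = radii_map(m, skeletonize(m))
        counts.append(radii_histogram(rm).counts)
    return ccc(counts[0], counts[1])


def segmentation_scores(pred, truth, boundary_tolerance_px: float = 1.0) -> SegScores:
    """All evaluation scores for one prediction/truth mask pair.

    F-score uses a 1-px boundary tolerance by default (how closely the
    predicted boundary matches the true one); Dice/Jaccard are exact overlap.
    """
    pred, truth = _check_masks(pred, truth)
    p, r, f = precision_recall_f(pred, truth, tolerance_px=boundary_tolerance_px)
    return SegScores(
        dice=dice(pred, truth),
        jaccard=jaccard(pred, truth),
        precision=p,
        recall=r,
        f_score=f,
        ccc=volume_ccc(pred, truth),
        error_ratio=error_ratio(pred, truth),
    )
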