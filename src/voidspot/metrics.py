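"""Detection and segmentation quality metrics.

Implements the standard object-detection evaluation suite on spot
instances: precision, recall and F1 from TP/FP/FN counts, average
precision (AP) as the area under the score-ranked precision-recall
curve, mAP as the mean AP over categories, the COCO-style AP variants
AP50 / AP75 / AP averaged over IoU thresholds 0.50:0.05:0.95, and the
area-stratified AP_S / AP_M / AP_L with bands at 32^2 and 96^2 pixels
of bounding-box area.

Matching is greedy in descending score order: each prediction claims
the highest-IoU unmatched ground-truth instance with IoU at or above
the threshold; a prediction with no claimable truth is a false
positive, a truth never claimed is a false negative.  In the
area-stratified variants, truths outside the band are "ignored" in the
COCO sense: predictions matching them are dropped from the ranking
rather than penalised, as are unmatched predictions whose own box lies
outside the band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .instances import SpotInstance, iou_bbox, iou_mask

__all__ = [
    "EvalCounts",
    "PRCurve",
    "EvalResult",
    "CocoSummary",
    "COCO_IOU_THRESHOLDS",
    "AREA_BANDS",
    "pairwise_iou",
    "match_instances",
    "precision_recall_f1",
    "build_pr_curve",
    "average_precision",
    "mean_average_precision",
    "ap_at",
    "ap_at_dataset",
    "area_stratified_ap",
    "coco_ap",
    "coco_ap_dataset",
    "evaluate",
]

COCO_IOU_THRESHOLDS: tuple[float, ...] = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))

# bounding-box area bands (px^2): small < 32^2 <= medium < 96^2 <= large
AREA_BANDS: dict[str, tuple[float, float]] = {
    "small": (0.0, 32.0**2),
    "medium": (32.0**2, 96.0**2),
    "large": (96.0**2, float("inf")),
    "all": (0.0, float("inf")),
}


@dataclass(frozen=True)
class EvalCounts:
    """TP/FP/FN/TN tallies. TN is recorded but plays no role in AP."""

    tp: int
    fp: int
    fn: int
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")


def pairwise_iou(
    preds: list[SpotInstance], truths: list[SpotInstance], mode: str = "mask"
) -> np.ndarray:
    """IoU matrix of shape (n_pred, n_truth)."""
    if mode == "mask":
        return np.array(
            [[iou_mask(p.mask, t.mask) for t in truths] for p in preds]
        ).reshape(len(preds), len(truths))
    if mode == "bbox":
        return np.array(
            [[iou_bbox(p.bbox, t.bbox) for t in truths] for p in preds]
        ).reshape(len(preds), len(truths))
    raise ValueError(f"unknown IoU mode {mode!r}")


def _ranked_order(preds: list[SpotInstance], iou: np.ndarray) -> list[int]:
    """Descending score; score ties broken by larger best-IoU, then input order."""
    best_iou = iou.max(axis=1) if iou.size else np.zeros(len(preds))
    return sorted(range(len(preds)), key=lambda i: (-preds[i].score, -best_iou[i], i))


def match_instances(
    preds: list[SpotInstance],
    truths: list[SpotInstance],
    iou_threshold: float = 0.5,
    mode: str = "mask",
) -> tuple[EvalCounts, list[bool]]:
    """Greedy score-ranked matching at one IoU threshold.

    Returns the TP/FP/FN counts and a per-prediction flag (in the input
    order of ``preds``) saying whether that prediction was a true
    positive.  Each truth is matched at most once.
    """
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError("iou_threshold must be in (0, 1)")
    iou = pairwise_iou(preds, truths, mode)
    matched_truth = [False] * len(truths)
    tp_flags = [False] * len(preds)
    for i in _ranked_order(preds, iou):
        best_j, best = -1, iou_threshold
        for j in range(len(truths)):
            if not matched_truth[j] and iou[i, j] >= best:
                best_j, best = j, iou[i, j]
        if best_j >= 0:
            matched_truth[best_j] = True
            tp_flags[i] = True
    tp = sum(tp_flags)
    return EvalCounts(tp=tp, fp=len(preds) - tp, fn=len(truths) - tp), tp_flags


def precision_recall_f1(counts: EvalCounts) -> tuple[float, float, float]:
    """Precision, recall and F1, each on the 0-100 percent scale.

    P = TP/(TP+FP) x 100, R = TP/(TP+FN) x 100, F1 = 2PR/(P+R).
    A zero denominator makes the corresponding quantity 0 (degenerate
    case: nothing predicted / no truth / both).
    """
    p = 100.0 * counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = 100.0 * counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f1 = 2.0 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


@dataclass
class PRCurve:
    """Score-ranked precision-recall points (recall non-decreasing)."""

    recall: np.ndarray
    precision: np.ndarray
    n_truth: int

    def __post_init__(self) -> None:
        self.recall = np.asarray(self.recall, dtype=float)
        self.precision = np.asarray(self.precision, dtype=float)
        if self.recall.shape != self.precision.shape:
            raise ValueError("recall and precision must have equal length")
        if np.any(np.diff(self.recall) < 0):
            raise ValueError("recall must be non-decreasing along the ranking")


def build_pr_curve(
    tp_flags: list[bool], scores: list[float], n_truth: int
) -> PRCurve:
    """PR points from per-prediction TP flags, ranked by descending score."""
    order = sorted(range(len(tp_flags)), key=lambda i: (-scores[i], i))
    tps = np.cumsum([1 if tp_flags[i] else 0 for i in order])
    k = np.arange(1, len(order) + 1)
    precision = tps / k if len(order) else np.array([])
    recall = tps / n_truth if n_truth > 0 else np.zeros(len(order))
    return PRCurve(recall=recall, precision=precision, n_truth=n_truth)


def average_precision(curve: PRCurve, method: str = "101point") -> float:
    """Area under the precision-recall curve, in [0, 1].

    ``method="101point"`` (default) is the COCO convention: the
    precision envelope (max precision at recall >= r) sampled at 101
    evenly spaced recalls.  ``method="exact"`` integrates the raw step
    function: each true positive at rank k contributes
    ``precision(k) / n_truth``.

    Raises
    ------
    ValueError
        If the curve was built against an empty truth set (AP is
        undefined without positives).
    """
    if curve.n_truth == 0:
        raise ValueError("average precision is undefined with no ground-truth instances")
    if len(curve.recall) == 0:
        return 0.0
    if method == "exact":
        # recall increments are 1/n_truth exactly at each TP
        increments = np.diff(np.concatenate([[0.0], curve.recall]))
        return float(np.sum(curve.precision * increments))
    if method == "101point":
        envelope = np.maximum.accumulate(curve.precision[::-1])[::-1]
        sample_recalls = np.linspace(0.0, 1.0, 101)
        idx = np.searchsorted(curve.recall, sample_recalls, side="left")
        sampled = np.where(idx < len(envelope), envelope[np.minimum(idx, len(envelope) - 1)], 0.0)
        return float(sampled.mean())
    raise ValueError(f"unknown AP method {method!r}")


def mean_average_precision(aps: list[float]) -> float:
    """Arithmetic mean of per-category APs; with one category mAP = AP."""
    if len(aps) == 0:
        raise ValueError("mean_average_precision requires at least one category AP")
    return float(np.mean(aps))


def _bbox_area(inst: SpotInstance) -> float:
    r0, c0, r1, c1 = inst.bbox
    return float((r1 - r0) * (c1 - c0))


def ap_at_dataset(
    preds_by_image: dict[int, list[SpotInstance]],
    truths_by_image: dict[int, list[SpotInstance]],
    iou_threshold: float,
    mode: str = "mask",
    area_range: tuple[float, float] = (0.0, float("inf")),
    method: str = "101point",
) -> float | None:
    """AP at one IoU threshold over a whole image set.

    Predictions are pooled into a single score ranking across images
    but may only match truths on their own image.  Truths whose
    bounding-box area falls outside ``area_range`` are ignored:
    predictions matched to them are dropped from the ranking (neither
    TP nor FP), as are unmatched predictions whose own box is outside
    the band.  Returns ``None`` when the band holds no truth (AP
    undefined for that band).
    """
    lo, hi = area_range
    image_ids = sorted(set(preds_by_image) | set(truths_by_image))
    per_image: dict[int, dict] = {}
    n_truth = 0
    entries: list[tuple[float, float, int, int, int]] = []  # sort key + (img, pred idx)
    for pos, img in enumerate(image_ids):
        preds = preds_by_image.get(img, [])
        truths = truths_by_image.get(img, [])
        iou = pairwise_iou(preds, truths, mode)
        ignored = [not (lo <= _bbox_area(t) < hi) for t in truths]
        n_truth += sum(not ig for ig in ignored)
        per_image[img] = {
            "preds": preds,
            "truths": truths,
            "iou": iou,
            "ignored": ignored,
            "matched": [False] * len(truths),
        }
        best_iou = iou.max(axis=1) if iou.size else np.zeros(len(preds))
        for i, p in enumerate(preds):
            entries.append((-p.score, -float(best_iou[i]), pos, i, img))
    if n_truth == 0:
        return None

    entries.sort()
    tp_flags: list[bool] = []
    for _, _, _, i, img in entries:
        data = per_image[img]
        iou, ignored, matched = data["iou"], data["ignored"], data["matched"]
        truths = data["truths"]
        # prefer the best non-ignored truth; fall back to an ignored one
        # (ties on IoU keep the last candidate, the usual COCO convention)
        best_j, best = -1, iou_threshold
        for j in range(len(truths)):
            if matched[j] or ignored[j]:
                continue
            if iou[i, j] >= best:
                best_j, best = j, iou[i, j]
        if best_j >= 0:
            matched[best_j] = True
            tp_flags.append(True)
            continue
        ign_j, ign_best = -1, iou_threshold
        for j in range(len(truths)):
            if matched[j] or not ignored[j]:
                continue
            if iou[i, j] >= ign_best:
                ign_j, ign_best = j, iou[i, j]
        if ign_j >= 0:
            matched[ign_j] = True  # matched-to-ignored: drop silently
            continue
        if not (lo <= _bbox_area(data["preds"][i]) < hi):
            continue  # out-of-band stray prediction: ignored, not penalised
        tp_flags.append(False)

    tps = np.cumsum([1 if f else 0 for f in tp_flags])
    k = np.arange(1, len(tp_flags) + 1)
    curve = PRCurve(
        recall=tps / n_truth if len(tp_flags) else np.array([]),
        precision=tps / k if len(tp_flags) else np.array([]),
        n_truth=n_truth,
    )
    return average_precision(curve, method=method)


def ap_at(
    preds: list[SpotInstance],
    truths: list[SpotInstance],
    iou_threshold: float,
    mode: str = "mask",
    area_range: tuple[float, float] = (0.0, float("inf")),
    method: str = "101point",
) -> float | None:
    """Single-image AP at one IoU threshold (see :func:`ap_at_dataset`)."""
    return ap_at_dataset(
        {1: preds}, {1: truths}, iou_threshold, mode=mode, area_range=area_range, method=method
    )


def area_stratified_ap(
    preds: list[SpotInstance],
    truths: list[SpotInstance],
    iou_thresholds: tuple[float, ...] = COCO_IOU_THRESHOLDS,
    mode: str = "mask",
    bands: dict[str, tuple[float, float]] | None = None,
) -> dict[str, float | None]:
    """AP_S / AP_M / AP_L: AP averaged over IoU thresholds per area band.

    A band containing no ground-truth instance yields ``None``
    (undefined, e.g. AP_S on a dataset of exclusively large spots).
    """
    if bands is None:
        bands = {k: AREA_BANDS[k] for k in ("small", "medium", "large")}
    out: dict[str, float | None] = {}
    for name, rng in bands.items():
        aps = [ap_at(preds, truths, t, mode=mode, area_range=rng) for t in iou_thresholds]
        defined = [a for a in aps if a is not None]
        out[name] = float(np.mean(defined)) if defined else None
    return out


@dataclass
class CocoSummary:
    """COCO-challenge style summary for one prediction set."""

    ap: float  # mean over IoU 0.50:0.05:0.95
    ap50: float
    ap75: float
    ap_small: float | None
    ap_medium: float | None
    ap_large: float | None
    mode: str = "mask"


def coco_ap_dataset(
    preds_by_image: dict[int, list[SpotInstance]],
    truths_by_image: dict[int, list[SpotInstance]],
    mode: str = "mask",
) -> CocoSummary:
    """COCO-style summary over a whole image set (pooled ranking)."""
    if not any(truths_by_image.values()):
        raise ValueError("coco_ap is undefined with no ground-truth instances")
    per_thr = [
        ap_at_dataset(preds_by_image, truths_by_image, t, mode=mode)
        for t in COCO_IOU_THRESHOLDS
    ]
    strata: dict[str, float | None] = {}
    for name in ("small", "medium", "large"):
        aps = [
            ap_at_dataset(
                preds_by_image, truths_by_image, t, mode=mode, area_range=AREA_BANDS[name]
            )
            for t in COCO_IOU_THRESHOLDS
        ]
        defined = [a for a in aps if a is not None]
        strata[name] = float(np.mean(defined)) if defined else None
    return CocoSummary(
        ap=float(np.mean([a for a in per_thr if a is not None])),
        ap50=per_thr[0],
        ap75=per_thr[5],
        ap_small=strata["small"],
        ap_medium=strata["medium"],
        ap_large=strata["large"],
        mode=mode,
    )


def coco_ap(
    preds: list[SpotInstance],
    truths: list[SpotInstance],
    mode: str = "mask",
) -> CocoSummary:
    """AP averaged over IoU thresholds 0.50:0.05:0.95, with AP50/AP75
    and the area-stratified variants, on a single image."""
    return coco_ap_dataset({1: preds}, {1: truths}, mode=mode)


@dataclass
class EvalResult:
    """Full evaluation of one prediction set against ground truth."""

    counts: EvalCounts
    precision_pct: float
    recall_pct: float
    f1_pct: float
    ap_by_iou: dict[float, float]
    ap50: float
    ap75: float
    map: float
    ap_small: float | None
    ap_medium: float | None
    ap_large: float | None
    n_categories: int = 1
    iou_threshold: float = 0.5
    mode: str = "mask"
    extras: dict = field(default_factory=dict)


def evaluate(
    preds: list[SpotInstance],
    truths: list[SpotInstance],
    iou_threshold: float = 0.5,
    mode: str = "mask",
) -> EvalResult:
    """One-call evaluation: counts, P/R/F1 at ``iou_threshold``, COCO APs.

    With the single "spot" category, mAP equals the COCO AP averaged
    over IoU thresholds.
    """
    counts, _ = match_instances(preds, truths, iou_threshold, mode)
    p, r, f1 = precision_recall_f1(counts)
    summary = coco_ap(preds, truths, mode=mode)
    ap_by_iou = {
        t: ap_at(preds, truths, t, mode=mode) for t in COCO_IOU_THRESHOLDS
    }
    return EvalResult(
        counts=counts,
        precision_pct=p,
        recall_pct=r,
        f1_pct=f1,
        ap_by_iou={t: (math.nan if a is None else a) for t, a in ap_by_iou.items()},
        ap50=summary.ap50,
        ap75=summary.ap75,
        map=summary.ap,
        ap_small=summary.ap_small,
        ap_medium=summary.ap_medium,
        ap_large=summary.ap_large,
        iou_threshold=iou_threshold,
        mode=mode,
    )
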