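"""Independent reference COCO-style evaluator used only as a test oracle.

A deliberately naive, from-scratch transcription of the published COCO
challenge evaluation protocol (per-image greedy matching in descending
score order with ignore semantics, pooled ranking, 101-point
interpolated precision), operating directly on raw COCO JSON
dictionaries.  It shares no code with the package implementation it
cross-checks.
"""

from __future__ import annotations

import numpy as np


def decode_rle(seg: dict) -> np.ndarray:
    h, w = seg["size"]
    flat = []
    val = 0
    for run in seg["counts"]:
        flat.extend([val] * run)
        val = 1 - val
    return np.array(flat, dtype=bool).reshape((w, h)).T  # column-major layout


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = int(np.sum(a & b))
    union = int(np.sum(a | b))
    return inter / union if union else 0.0


def box_iou(a, b) -> float:
    # boxes as COCO [x, y, w, h]
    ax0, ay0, aw, ah = a
    bx0, by0, bw, bh = b
    ix = min(ax0 + aw, bx0 + bw) - max(ax0, bx0)
    iy = min(ay0 + ah, by0 + bh) - max(ay0, by0)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union if union else 0.0


def _bbox_of_mask(mask: np.ndarray):
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    r = np.flatnonzero(rows)
    c = np.flatnonzero(cols)
    return [float(c[0]), float(r[0]), float(c[-1] - c[0] + 1), float(r[-1] - r[0] + 1)]


def ref_evaluate(
    truth_json: dict,
    pred_json: dict,
    iou_threshold: float,
    mode: str = "mask",
    area_range: tuple[float, float] = (0.0, float("inf")),
) -> float | None:
    """AP at one IoU threshold per the COCO protocol; None if the band is empty.

    Area-band membership follows the package convention: bounding-box
    area of the (tight) mask box.
    """
    lo, hi = area_range
    gts_by_img: dict[int, list[dict]] = {}
    for ann in truth_json["annotations"]:
        mask = decode_rle(ann["segmentation"])
        box = _bbox_of_mask(mask)
        ignore = not (lo <= box[2] * box[3] < hi)
        gts_by_img.setdefault(ann["image_id"], []).append(
            {"mask": mask, "bbox": box, "ignore": ignore, "matched": False}
        )
    dts_by_img: dict[int, list[dict]] = {}
    pred_anns = pred_json if isinstance(pred_json, list) else pred_json["annotations"]
    for ann in pred_anns:
        mask = decode_rle(ann["segmentation"])
        box = _bbox_of_mask(mask)
        dts_by_img.setdefault(ann["image_id"], []).append(
            {"mask": mask, "bbox": box, "score": ann.get("score", 1.0)}
        )

    n_pos = sum(not g["ignore"] for gts in gts_by_img.values() for g in gts)
    if n_pos == 0:
        return None

    pooled: list[tuple[float, bool, bool]] = []  # (score, is_tp, is_ignored)
    image_ids = sorted(set(gts_by_img) | set(dts_by_img))
    for img in image_ids:
        gts = gts_by_img.get(img, [])
        # unignored gts first, stable (COCO sorts by ignore flag)
        gts = sorted(gts, key=lambda g: g["ignore"])
        dts = sorted(dts_by_img.get(img, []), key=lambda d: -d["score"])
        for dt in dts:
            best = iou_threshold
            m = -1
            for gi, gt in enumerate(gts):
                if gt["matched"]:
                    continue
                if m > -1 and not gts[m]["ignore"] and gt["ignore"]:
                    break
                iou = (
                    mask_iou(dt["mask"], gt["mask"])
                    if mode == "mask"
                    else box_iou(dt["bbox"], gt["bbox"])
                )
                if iou < best:
                    continue
                best = iou
                m = gi
            if m > -1:
                gts[m]["matched"] = True
                pooled.append((dt["score"], True, gts[m]["ignore"]))
            else:
                out_of_band = not (lo <= dt["bbox"][2] * dt["bbox"][3] < hi)
                pooled.append((dt["score"], False, out_of_band))

    pooled.sort(key=lambda e: -e[0])
    tp = fp = 0
    rc, pr = [], []
    for _, is_tp, is_ign in pooled:
        if is_ign:
            continue
        if is_tp:
            tp += 1
        else:
            fp += 1
        rc.append(tp / n_pos)
        pr.append(tp / (tp + fp))

    # COCO 101-point interpolation
    pr = list(pr)
    for i in range(len(pr) - 1, 0, -1):
        if pr[i] > pr[i - 1]:
            pr[i - 1] = pr[i]
    rec_thrs = np.linspace(0.0, 1.0, 101)
    q = np.zeros(101)
    inds = np.searchsorted(rc, rec_thrs, side="left")
    for ri, pi in enumerate(inds):
        if pi < len(pr):
            q[ri] = pr[pi]
    return float(q.mean())


def brute_force_ap_exact(masks_pred, scores, masks_truth, iou_threshold: float) -> float:
    """Step-function PR integral computed by explicit rectangle summation.

    Re-derives precision and recall from scratch at every rank cutoff
    and integrates precision over the recall increments.
    """
    order = sorted(range(len(masks_pred)), key=lambda i: (-scores[i], i))
    matched = [False] * len(masks_truth)
    flags = []
    for i in order:
        best, bj = iou_threshold, -1
        for j, tm in enumerate(masks_truth):
            if matched[j]:
                continue
            iou = mask_iou(masks_pred[i], tm)
            if iou >= best:
                best, bj = iou, j
        if bj >= 0:
            matched[bj] = True
            flags.append(True)
        else:
            flags.append(False)
    n_truth = len(masks_truth)
    area = 0.0
    prev_recall = 0.0
    tp = 0
    for k, flag in enumerate(flags, start=1):
        if flag:
            tp += 1
        recall = tp / n_truth
        precision = tp / k
        area += precision * (recall - prev_recall)
        prev_recall = recall
    return area


def brute_force_assignment(cost: np.ndarray, gate: np.ndarray) -> tuple[int, float]:
    """Best matching by exhaustive permutation enumeration.

    Returns (max feasible cardinality, min total cost at that
    cardinality) — the semantics the tracker's Hungarian wrapper claims.
    """
    from itertools import permutations

    n, m = cost.shape
    best = (0, 0.0)
    found = False
    if n <= m:
        for perm in permutations(range(m), n):
            k = sum(1 for i, j in enumerate(perm) if gate[i, j])
            c = sum(cost[i, j] for i, j in enumerate(perm) if gate[i, j])
            cand = (-k, c)
            if not found or cand < best:
                best, found = cand, True
    else:
        for perm in permutations(range(n), m):
            k = sum(1 for j, i in enumerate(perm) if gate[i, j])
            c = sum(cost[i, j] for j, i in enumerate(perm) if gate[i, j])
            cand = (-k, c)
            if not found or cand < best:
                best, found = cand, True
    if not found:
        return 0, 0.0
    return -best[0], best[1]
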