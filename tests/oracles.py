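"""Independent brute-force reimplementations used as test oracles.

Everything here is written with plain Python loops directly from the
definitions, deliberately sharing no code path with the package.
"""

from __future__ import annotations

import math
import statistics

import numpy as np


# ---------------------------------------------------------------------------
# ranking

def loop_class_means(patterns, labels):
    """Column means per class via explicit loops; classes sorted by label."""
    c1, c2 = sorted(set(labels))
    n = len(patterns[0])
    out = []
    for cls in (c1, c2):
        means = []
        for j in range(n):
            vals = [row[j] for row, lab in zip(patterns, labels) if lab == cls]
            means.append(sum(vals) / len(vals))
        out.append(means)
    return out[0], out[1]


def loop_permutation(patterns, labels, mode="signed"):
    """Sort attribute positions by descending difference, stable ties."""
    m1, m2 = loop_class_means(patterns, labels)
    d = [a - b for a, b in zip(m1, m2)]
    if mode == "absolute":
        d = [abs(v) for v in d]
    ranked = sorted(range(len(d)), key=lambda j: (-d[j], j))
    return [j + 1 for j in ranked], [d[j] for j in ranked]


# ---------------------------------------------------------------------------
# classifier

def loop_project(pattern, positions):
    vals = [pattern[p - 1] for p in positions]
    return statistics.stdev(vals), statistics.fmean(vals)


def loop_train(patterns, labels, mode="signed", k_schedule=None, tie_policy="below"):
    """Exhaustive attribute-growth sweep, one k at a time.

    Returns (k_star, h, side_map, accuracy, per_k) where per_k maps k to
    (h, accuracy, fully_separated).
    """
    order, _ = loop_permutation(patterns, labels, mode)
    n = len(order)
    m = len(patterns)
    c1, c2 = sorted(set(labels))
    ks = list(k_schedule) if k_schedule is not None else list(range(2, n + 1))
    per_k = {}
    chosen = None
    for k in ks:
        pos = order[:k]
        ys = [loop_project(p, pos)[1] for p in patterns]
        y1 = [y for y, lab in zip(ys, labels) if lab == c1]
        y2 = [y for y, lab in zip(ys, labels) if lab == c2]
        if sum(y1) / len(y1) <= sum(y2) / len(y2):
            minor, major, ymin, ymaj = c1, c2, y1, y2
        else:
            minor, major, ymin, ymaj = c2, c1, y2, y1
        h = (max(ymin) + min(ymaj)) / 2.0
        correct = 0
        for y, lab in zip(ys, labels):
            if y < h:
                pred = minor
            elif y > h:
                pred = major
            else:
                pred = minor if tie_policy == "below" else major
            correct += pred == lab
        acc = correct / m
        per_k[k] = (h, acc, max(ymin) < min(ymaj), minor, major)
        if chosen is None and correct == m:
            chosen = k
    if chosen is None:
        best = max(acc for (_, acc, _, _, _) in per_k.values())
        chosen = min(k for k, v in per_k.items() if v[1] == best)
    h, acc, _, minor, major = per_k[chosen]
    return chosen, h, {"below": minor, "above": major}, acc, per_k


def loop_assign(pattern, positions, h, side_map, tie_policy="below"):
    _, y = loop_project(pattern, positions)
    if y < h:
        return side_map["below"]
    if y > h:
        return side_map["above"]
    return side_map[tie_policy]


def loop_loocv(patterns, labels, mode="signed", tie_policy="below"):
    """Exhaustive fold-by-fold LOOCV using the loop trainer."""
    preds = []
    models = []
    for i in range(len(patterns)):
        tr_p = [p for j, p in enumerate(patterns) if j != i]
        tr_l = [l for j, l in enumerate(labels) if j != i]
        k, h, side_map, _, _ = loop_train(tr_p, tr_l, mode, None, tie_policy)
        order, _ = loop_permutation(tr_p, tr_l, mode)
        preds.append(loop_assign(patterns[i], order[:k], h, side_map, tie_policy))
        models.append((k, h))
    return preds, models


def loop_confusion(y_true, y_pred, positive):
    tp = tn = fp = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == positive:
            if p == positive:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive:
                fp += 1
            else:
                tn += 1
    return tp, tn, fp, fn


# ---------------------------------------------------------------------------
# imaging

def _window(img, r, c, size, pad="replicate"):
    h, w = len(img), len(img[0])
    half = size // 2
    vals = []
    for dr in range(-half, half + 1):
        for dc in range(-half, half + 1):
            rr = min(max(r + dr, 0), h - 1) if pad == "replicate" else r + dr
            cc = min(max(c + dc, 0), w - 1) if pad == "replicate" else c + dc
            vals.append(int(img[rr][cc]))
    return vals


def loop_mean_filter(img, size):
    img = np.asarray(img)
    out = np.zeros_like(img)
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            vals = _window(img, r, c, size)
            out[r, c] = min(255, math.floor(sum(vals) / len(vals) + 0.5))
    return out


def loop_median_filter(img, size):
    img = np.asarray(img)
    out = np.zeros_like(img)
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            out[r, c] = int(statistics.median(_window(img, r, c, size)))
    return out


def loop_erode(mask, se, pad=0):
    """Direct set definition: pixel kept iff every SE cell lands on
    foreground (outside cells count as ``pad``)."""
    mask = np.asarray(mask)
    se = np.asarray(se).astype(bool)
    h, w = mask.shape
    cy, cx = se.shape[0] // 2, se.shape[1] // 2
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            keep = True
            for i in range(se.shape[0]):
                for j in range(se.shape[1]):
                    if not se[i, j]:
                        continue
                    rr, cc = r + i - cy, c + j - cx
                    inside = 0 <= rr < h and 0 <= cc < w
                    val = mask[rr, cc] > 0 if inside else bool(pad)
                    if not val:
                        keep = False
            out[r, c] = 255 if keep else 0
    return out


def loop_dilate(mask, se):
    """Direct set definition: pixel set iff the reflected SE translated
    there hits the foreground."""
    mask = np.asarray(mask)
    se = np.asarray(se).astype(bool)
    h, w = mask.shape
    cy, cx = se.shape[0] // 2, se.shape[1] // 2
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            hit = False
            for i in range(se.shape[0]):
                for j in range(se.shape[1]):
                    if not se[i, j]:
                        continue
                    # reflected SE cell (i, j) -> offset (cy - i, cx - j)
                    rr, cc = r + cy - i, c + cx - j
                    if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] > 0:
                        hit = True
            out[r, c] = 255 if hit else 0
    return out
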