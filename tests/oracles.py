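"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities by the most literal method
available (per-pixel scalar loops, O(n^2) pair counting) so they share no
code path with the package implementations they check.
"""

from __future__ import annotations

import math

import numpy as np


def point_segment(px, py, ax, ay, bx, by):
    """Scalar point-to-segment distance plus unclamped parameter and cross."""
    dx, dy = bx - ax, by - ay
    len2 = dx * dx + dy * dy
    if len2 == 0:
        return math.hypot(px - ax, py - ay), 0.0, 0.0
    t = ((px - ax) * dx + (py - ay) * dy) / len2
    tc = min(1.0, max(0.0, t))
    qx, qy = ax + tc * dx, ay + tc * dy
    dist = math.hypot(px - qx, py - qy)
    cross = dx * (py - ay) - dy * (px - ax)
    return dist, t, cross


def _pixel_state(px, py, polyline, depth_mm):
    """(in_tube, side_sign) of one pixel centre against a polyline band.

    ``in_tube`` applies the unsigned band rule: strictly within depth, not
    in an end-cap region, not exactly on the line.  ``side_sign`` is the
    sign of the cross product against the nearest segment.
    """
    best = (math.inf, 0.0, 0.0, -1)
    n_seg = len(polyline) - 1
    for s in range(n_seg):
        dist, t, cross = point_segment(px, py, polyline[s][0], polyline[s][1],
                                       polyline[s + 1][0], polyline[s + 1][1])
        if dist < best[0]:
            best = (dist, t, cross, s)
    dist, t, cross, s = best
    cap = (s == 0 and t < 0.0) or (s == n_seg - 1 and t > 1.0)
    in_tube = (dist < depth_mm) and not cap and cross != 0.0
    return in_tube, (0 if cross == 0 else (1 if cross > 0 else -1))


def brute_force_band(image, ann, depth_mm: float) -> np.ndarray:
    """Per-pixel point-in-band test for an endplate annotation."""
    h, w = image.shape
    s = image.spacing_mm
    pl = np.asarray(ann.polyline_mm, dtype=float)
    hx, hy = ann.body_side_hint_mm
    _, hint_sign = _pixel_state(hx, hy, pl, depth_mm)
    mask = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            in_tube, sign = _pixel_state((j + 0.5) * s, (i + 0.5) * s, pl, depth_mm)
            mask[i, j] = in_tube and sign == hint_sign
    return mask


def brute_force_tube(image, polyline, depth_mm: float) -> np.ndarray:
    """The unsigned band (both sides, on-line pixels excluded)."""
    h, w = image.shape
    s = image.spacing_mm
    pl = np.asarray(polyline, dtype=float)
    mask = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            in_tube, _ = _pixel_state((j + 0.5) * s, (i + 0.5) * s, pl, depth_mm)
            mask[i, j] = in_tube
    return mask


def auc_pair_count(scores, labels) -> float:
    """AUC as the fraction of concordant positive/negative pairs (ties 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
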