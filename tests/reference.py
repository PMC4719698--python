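"""Independent brute-force reference implementations used as oracles.

Everything here is deliberately written as plain per-element Python
(loops, colorsys, closed-form rank formulas) so it shares no code path
with the vectorised package implementation it checks.
"""

from __future__ import annotations

import colorsys
import math

import numpy as np


# ---------------------------------------------------------------------------
# Per-pixel chromogen classifier


def ycbcr_pixel(r: float, g: float, b: float) -> tuple[float, float, float]:
    y = 0.299 * r + 0.587 * g + 0.114 * b
    cb = 128.0 - 0.168736 * r - 0.331264 * g + 0.5 * b
    cr = 128.0 + 0.5 * r - 0.418688 * g - 0.081312 * b
    clip = lambda v: min(255.0, max(0.0, v))
    return clip(y), clip(cb), clip(cr)


def _adjusted_cr(r: float, g: float, b: float, params) -> float:
    cr = ycbcr_pixel(r, g, b)[2]
    v = params.contrast_gain * (cr - 128.0) + 128.0 + params.brightness_offset
    return min(255.0, max(0.0, v))


def _in_brown_band(r: float, g: float, b: float, params) -> bool:
    h, s, v = colorsys.rgb_to_hsv(r / 255.0, g / 255.0, b / 255.0)
    hue, sat, val = h * 255.0, s * 255.0, v * 255.0
    lo, hi = params.brown_hue_band
    in_band = (lo <= hue <= hi) if lo <= hi else (hue >= lo or hue <= hi)
    return in_band and sat >= params.brown_sat_min and val >= params.brown_val_min


def _shift_target_rgb(params) -> tuple[int, int, int]:
    h, s, v = params.brown_shift_target
    rgb = colorsys.hsv_to_rgb(h / 255.0, s / 255.0, v / 255.0)
    return tuple(int(np.clip(np.round(c * 255.0), 0, 255)) for c in rgb)


def masks_by_loop(tile: np.ndarray, params) -> tuple[np.ndarray, np.ndarray]:
    """(red_mask, brown_mask) classified pixel by pixel ('target' shift mode)."""
    assert params.brown_shift_mode == "target"
    h, w = tile.shape[:2]
    red = np.zeros((h, w), dtype=bool)
    brown = np.zeros((h, w), dtype=bool)
    target = _shift_target_rgb(params)
    for i in range(h):
        for j in range(w):
            r, g, b = (float(c) for c in tile[i, j])
            is_red = _adjusted_cr(r, g, b, params) > params.cr_threshold
            red[i, j] = is_red
            sr, sg, sb = target if _in_brown_band(r, g, b, params) else (r, g, b)
            is_brown = _adjusted_cr(sr, sg, sb, params) > params.cr_threshold
            if params.mutual_exclusion:
                is_brown = is_brown and not is_red
            brown[i, j] = is_brown
    return red, brown


# ---------------------------------------------------------------------------
# Agreement statistics


def icc_ref(M: np.ndarray) -> float:
    """ICC(2,1) from an explicitly looped two-way ANOVA decomposition."""
    M = np.asarray(M, dtype=float)
    n, k = M.shape
    grand = sum(M[i, j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(M[i, j] for j in range(k)) / k for i in range(n)]
    col = [sum(M[i, j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((m - grand) ** 2 for m in row)
    ssc = n * sum((m - grand) ** 2 for m in col)
    sse = sum(
        (M[i, j] - row[i] - col[j] + grand) ** 2 for i in range(n) for j in range(k)
    )
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def bland_altman_ref(x, y) -> tuple[float, float, float]:
    d = [yi - xi for xi, yi in zip(x, y)]
    n = len(d)
    bias = sum(d) / n
    sd = math.sqrt(sum((di - bias) ** 2 for di in d) / (n - 1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def pearson_ref(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    vx = sum((xi - mx) ** 2 for xi in x)
    vy = sum((yi - my) ** 2 for yi in y)
    return cov / math.sqrt(vx * vy)


def midranks(values) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for idx in order[i : j + 1]:
            ranks[idx] = avg
        i = j + 1
    return ranks


def spearman_ref(x, y) -> float:
    return pearson_ref(midranks(list(x)), midranks(list(y)))


def mannwhitney_u_ref(a, b) -> float:
    """U statistic of sample a: pairwise win count with half-credit ties."""
    u = 0.0
    for ai in a:
        for bi in b:
            if ai > bi:
                u += 1.0
            elif ai == bi:
                u += 0.5
    return u


def kruskal_h_ref(groups) -> float:
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    ranks = midranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        start += len(g)
        h += (sum(r)) ** 2 / len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    counts = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    tie = sum(c**3 - c for c in counts.values())
    return h / (1.0 - tie / (n**3 - n))
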