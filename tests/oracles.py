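"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (flood fill, per-pixel loops, full
enumeration) and shares no code with the package's implementations.
"""

from __future__ import annotations

from collections import deque
from itertools import product

import numpy as np


def flood_fill_components(binary: np.ndarray) -> list:
    """4-connected components of a binary image as a list of frozensets of
    (row, col), via breadth-first flood fill."""
    binary = np.asarray(binary, dtype=bool)
    h, w = binary.shape
    seen = np.zeros_like(binary)
    comps = []
    for r0 in range(h):
        for c0 in range(w):
            if not binary[r0, c0] or seen[r0, c0]:
                continue
            comp = []
            q = deque([(r0, c0)])
            seen[r0, c0] = True
            while q:
                r, c = q.popleft()
                comp.append((r, c))
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and binary[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        q.append((rr, cc))
            comps.append(frozenset(comp))
    return comps


def median_filter_5x5(binary: np.ndarray) -> np.ndarray:
    """5×5 median of a binary image with reflected borders, per-pixel."""
    binary = np.asarray(binary, dtype=np.uint8)
    padded = np.pad(binary, 2, mode="symmetric")   # scipy.ndimage's 'reflect'
    out = np.zeros_like(binary)
    h, w = binary.shape
    for r in range(h):
        for c in range(w):
            win = padded[r:r + 5, c:c + 5].ravel()
            out[r, c] = int(np.median(win))
    return out.astype(bool)


def green_marker_pipeline(rgb: np.ndarray, hand_coords, mm_per_px: float,
                          min_px: int = 10, excl_mm: float = 10.0) -> list:
    """Reference green-marker detector: strict green mask, 5×5 median,
    flood-fill grouping, size filter, hand-proximity exclusion."""
    rgb = np.asarray(rgb, dtype=int)
    mask = (rgb[..., 0] < rgb[..., 1]) & (rgb[..., 2] < rgb[..., 1])
    mask = median_filter_5x5(mask)
    cents = []
    for comp in flood_fill_components(mask):
        if len(comp) < min_px:
            continue
        pts = np.array(sorted(comp), dtype=float)
        cen = pts.mean(axis=0)
        if hand_coords is not None and len(hand_coords):
            d = np.hypot(hand_coords[:, 0] - cen[0], hand_coords[:, 1] - cen[1]).min()
            if d * mm_per_px < excl_mm:
                continue
        cents.append((float(cen[0]), float(cen[1])))
    return sorted(cents)


def wilcoxon_two_sided_enumeration(d) -> float:
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns
    (zeros dropped, midranks for ties): min(1, 2·min(P(W≤w), P(W≥w)))."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    absd = np.abs(d)
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(n)
    sorted_abs = absd[order]
    i = 0
    while i < n:
        j = i
        while j < n and sorted_abs[j] == sorted_abs[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0   # midrank of positions i..j-1 (1-based)
        i = j
    w = ranks[d > 0].sum()
    stats = []
    for signs in product((False, True), repeat=n):
        stats.append(sum(r for r, s in zip(ranks, signs) if s))
    stats = np.asarray(stats)
    eps = 1e-9
    p_le = np.mean(stats <= w + eps)
    p_ge = np.mean(stats >= w - eps)
    return min(1.0, 2.0 * min(p_le, p_ge))
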