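"""Independent brute-force oracles used to validate the fast implementations.

These deliberately use naive algorithms (explicit loops, flood fill,
O(n^2) pair counting) so they share no code path with the library.
"""

from __future__ import annotations

import math

import numpy as np


def triangle_threshold_bruteforce(hist: np.ndarray) -> int:
    """O(bins) geometric search: max point-line distance, smallest index ties.

    Line runs from the (first) peak bin to the farthest nonzero bin on the
    longer tail (right tail on ties); distance computed per bin with the
    explicit point-to-line formula.
    """
    h = [float(x) for x in hist]
    peak = max(range(len(h)), key=lambda i: (h[i], -i))
    nz = [i for i, x in enumerate(h) if x > 0]
    left, right = nz[0], nz[-1]
    end = right if (right - peak) >= (peak - left) else left
    if end == peak:
        return peak
    x1, y1, x2, y2 = peak, h[peak], end, h[end]
    norm = math.hypot(x2 - x1, y2 - y1)
    best_bin, best_d = None, -1.0
    rng = range(min(peak, end), max(peak, end) + 1)
    for b in rng:
        d = abs((y2 - y1) * (b - x1) - (x2 - x1) * (h[b] - y1)) / norm
        if d > best_d + 1e-12:
            best_d, best_bin = d, b
    return best_bin


def flood_fill_components(binary: np.ndarray) -> list[np.ndarray]:
    """4-connected components of a bool grid via explicit stack flood fill."""
    binary = np.asarray(binary, dtype=bool)
    seen = np.zeros_like(binary)
    comps = []
    H, W = binary.shape
    for sr in range(H):
        for sc in range(W):
            if not binary[sr, sc] or seen[sr, sc]:
                continue
            comp = np.zeros_like(binary)
            stack = [(sr, sc)]
            seen[sr, sc] = True
            while stack:
                r, c = stack.pop()
                comp[r, c] = True
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < H and 0 <= cc < W and binary[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        stack.append((rr, cc))
            comps.append(comp)
    return comps


def auc_pairwise(scores, labels) -> float:
    """O(n^2) Mann-Whitney: P(pos > neg) + 0.5 P(tie) over all pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def mcc_pearson(tp: int, tn: int, fp: int, fn: int) -> float:
    """MCC as the Pearson correlation of the binary prediction/label vectors."""
    preds = [1] * tp + [0] * tn + [1] * fp + [0] * fn
    labels = [1] * tp + [0] * tn + [0] * fp + [1] * fn
    p = np.asarray(preds, dtype=float)
    l = np.asarray(labels, dtype=float)
    sp, sl = p.std(), l.std()
    if sp == 0 or sl == 0:
        return 0.0
    return float(((p - p.mean()) * (l - l.mean())).mean() / (sp * sl))
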