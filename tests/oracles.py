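"""Independent brute-force oracles used by the test suite.

Each oracle is a direct, naive evaluation of a definition — per-pixel
inequalities, exhaustive scans, flood fills — deliberately sharing no code
with the implementation it checks.
"""

from __future__ import annotations

import numpy as np


def disc_pixels_bruteforce(shape, cy, cx, r):
    """Set of (y, x) satisfying the disc inequality, by per-pixel loop."""
    pixels = set()
    for y in range(shape[0]):
        for x in range(shape[1]):
            if (y - cy) ** 2 + (x - cx) ** 2 <= r**2:
                pixels.add((y, x))
    return pixels


def otsu_exhaustive(hist):
    """Otsu level by exhaustive scan of between-class variance.

    For each cut k (background = levels <= k) compute class weights and
    means directly and evaluate w0*w1*(m0-m1)^2; return the lowest argmax.
    """
    hist = np.asarray(hist, dtype=float)
    levels = np.arange(hist.size, dtype=float)
    total = hist.sum()
    best_k, best_v = None, -1.0
    for k in range(hist.size - 1):
        n0 = hist[: k + 1].sum()
        n1 = total - n0
        if n0 == 0 or n1 == 0:
            continue
        m0 = (hist[: k + 1] * levels[: k + 1]).sum() / n0
        m1 = (hist[k + 1 :] * levels[k + 1 :]).sum() / n1
        v = (n0 / total) * (n1 / total) * (m0 - m1) ** 2
        if v > best_v + 1e-15:
            best_v, best_k = v, k
    return best_k


def plateau_maxima_oracle(frame):
    """Regional-maxima representatives by flood-fill plateau enumeration.

    BFS each connected (8-neighborhood) equal-value plateau; it is a
    regional maximum iff no outside neighbor is strictly higher.  The
    representative is the plateau centroid rounded half-down.
    """
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape
    visited = np.zeros((h, w), dtype=bool)
    reps = set()
    for sy in range(h):
        for sx in range(w):
            if visited[sy, sx]:
                continue
            v = frame[sy, sx]
            plateau = [(sy, sx)]
            visited[sy, sx] = True
            is_max = True
            i = 0
            while i < len(plateau):
                y, x = plateau[i]
                i += 1
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        if dy == 0 and dx == 0:
                            continue
                        ny, nx = y + dy, x + dx
                        if not (0 <= ny < h and 0 <= nx < w):
                            continue
                        if frame[ny, nx] == v:
                            if not visited[ny, nx]:
                                visited[ny, nx] = True
                                plateau.append((ny, nx))
                        elif frame[ny, nx] > v:
                            is_max = False
            if is_max:
                ys = np.array([p[0] for p in plateau], dtype=float)
                xs = np.array([p[1] for p in plateau], dtype=float)
                reps.add(
                    (int(np.ceil(ys.mean() - 0.5)),
                     int(np.ceil(xs.mean() - 0.5)))
                )
    return reps


def min_cost_matching(prev, curr, max_distance):
    """Optimal one-to-one frame linking by exhaustive assignment search.

    Enumerates every injective assignment of previous to current positions,
    drops pairs beyond ``max_distance``, and returns the assignment with the
    most links, breaking ties by total distance.
    """
    from itertools import permutations

    prev = np.asarray(prev, dtype=float)
    curr = np.asarray(curr, dtype=float)
    n, m = len(prev), len(curr)
    best_pairs = []
    best_key = (0, 0.0)
    for perm in permutations(range(m), min(n, m)):
        pairs = []
        cost = 0.0
        for i, j in zip(range(min(n, m)), perm):
            d = float(np.hypot(*(prev[i] - curr[j])))
            if d <= max_distance:
                pairs.append((i, j))
                cost += d
        key = (-len(pairs), cost)
        if key < (-best_key[0], best_key[1]) or not best_pairs:
            best_pairs, best_key = pairs, (len(pairs), cost)
    return best_pairs
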