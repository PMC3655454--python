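"""Independent brute-force oracles shared by unit and acceptance tests.

These deliberately re-derive results by the most literal method available
(pure-Python enumeration, geometric clipping of every cell, naive scans)
so they stay independent of the library's vectorized implementations.
"""

import itertools

import numpy as np


def brute_sign_search(values, t, p, W):
    """Naive enumeration of all 2^(p-1) sign vectors; returns (signs, c, rss).

    ``values`` is the raw sample array, ``t`` the 1-based forecast origin.
    """
    best = None
    for tail in itertools.product((1, -1), repeat=p - 1):
        pi = (1,) + tail
        resid = []
        for s in range(t - W, t):  # 1-based targets
            pred = sum(pi[i] * values[s - i - 2] for i in range(p))
            resid.append(values[s - 1] - pred)
        c = sum(resid) / len(resid)
        rss = sum((r - c) ** 2 for r in resid)
        if best is None or rss < best[2]:
            best = (pi, c, rss)
    return best


def brute_curve_cells(t, y, eps):
    """Cells touched by the polyline: closed segment-rectangle clipping
    of every grid cell in the bounding box (Liang-Barsky)."""
    a, b = t[0], y.min()
    ni = int(np.floor((t[-1] - a) / eps)) + 1
    nj = int(np.floor((y.max() - b) / eps)) + 1
    x0s, y0s, x1s, y1s = t[:-1], y[:-1], t[1:], y[1:]
    dx, dy = x1s - x0s, y1s - y0s
    cells = set()
    for i in range(ni):
        cx0, cx1 = a + i * eps, a + (i + 1) * eps
        for j in range(nj):
            cy0, cy1 = b + j * eps, b + (j + 1) * eps
            s0 = np.zeros_like(dx)
            s1 = np.ones_like(dx)
            ok = np.ones(dx.shape, bool)
            for pnum, q in (
                (-dx, x0s - cx0),
                (dx, cx1 - x0s),
                (-dy, y0s - cy0),
                (dy, cy1 - y0s),
            ):
                para = pnum == 0
                ok &= ~(para & (q < 0))
                with np.errstate(divide="ignore", invalid="ignore"):
                    r = np.where(para, 0.0, q / np.where(para, 1.0, pnum))
                s0 = np.where((~para) & (pnum < 0), np.maximum(s0, r), s0)
                s1 = np.where((~para) & (pnum > 0), np.minimum(s1, r), s1)
            if np.any(ok & (s0 <= s1)):
                cells.add((i, j))
    return cells


def brute_point_cells(pts, eps):
    """Occupied cells of a point cloud by per-point flooring."""
    mins = pts.min(axis=0)
    return {
        tuple(int(np.floor((v - m) / eps)) for v, m in zip(row, mins))
        for row in pts
    }


def brute_nn_prediction(values, origin, window_m, limit):
    """Naive nearest-neighbor scan: over all windows of length window_m
    whose successor index (1-based) is <= limit, return the successor of
    the window closest to the trailing query; earliest wins ties."""
    query = values[origin - 1 - window_m : origin - 1]
    best = None
    for e in range(window_m, limit):  # 1-based window end index
        cand = values[e - window_m : e]
        d = float(sum((cand - query) ** 2))
        if best is None or d < best[0]:
            best = (d, values[e])  # successor = 1-based e+1 = 0-based e
    return best[1]
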