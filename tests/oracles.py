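"""Independent brute-force reference implementations used only by tests.

Deliberately naive (explicit loops, textbook formulas) so that they
share no code path with the package under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def pearson_bruteforce(x, y) -> float:
    """Sample Pearson correlation via the textbook sum formula."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((x[i] - mx) * (y[i] - my) for i in range(n))
    dx = math.sqrt(sum((x[i] - mx) ** 2 for i in range(n)))
    dy = math.sqrt(sum((y[i] - my) ** 2 for i in range(n)))
    return num / (dx * dy)


def rdm_bruteforce(patterns) -> np.ndarray:
    """1 - Pearson RDM computed pair by pair with explicit loops."""
    P = np.asarray(patterns, float)
    n = P.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                d[i, j] = 1.0 - pearson_bruteforce(list(P[i]), list(P[j]))
    return d


def average_ranks(values) -> list[float]:
    """Average ranks (1-based) with explicit tie handling."""
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_bruteforce(a, b) -> float:
    """Spearman rho: Pearson correlation of explicitly enumerated ranks."""
    return pearson_bruteforce(average_ranks(a), average_ranks(b))


def lower_triangle_list(rdm) -> list[float]:
    rdm = np.asarray(rdm, float)
    n = rdm.shape[0]
    return [rdm[i, j] for i in range(n) for j in range(i)]


def exhaustive_signflip_p(values, tail: str = "two") -> float:
    """Exact sign-flip p over all 2^N flips of a 1-D sample (mean statistic)."""
    values = list(values)
    n = len(values)
    obs = sum(values) / n
    hits = 0
    for signs in itertools.product((1, -1), repeat=n):
        m = sum(s * v for s, v in zip(signs, values)) / n
        if tail == "two":
            hits += abs(m) >= abs(obs) - 1e-12
        else:
            hits += m >= obs - 1e-12
    return hits / 2**n


def bilinear_by_hand(grid, out_h, out_w) -> np.ndarray:
    """Corner-aligned bilinear interpolation with explicit weights."""
    grid = np.asarray(grid, float)
    H, W = grid.shape
    out = np.zeros((out_h, out_w))
    for i in range(out_h):
        for j in range(out_w):
            y = i * (H - 1) / (out_h - 1)
            x = j * (W - 1) / (out_w - 1)
            y0, x0 = int(math.floor(y)), int(math.floor(x))
            y1, x1 = min(y0 + 1, H - 1), min(x0 + 1, W - 1)
            fy, fx = y - y0, x - x0
            out[i, j] = (
                grid[y0, x0] * (1 - fy) * (1 - fx)
                + grid[y1, x0] * fy * (1 - fx)
                + grid[y0, x1] * (1 - fy) * fx
                + grid[y1, x1] * fy * fx
            )
    return out
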