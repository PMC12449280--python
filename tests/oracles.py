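"""Independent straight-line reference implementations used as test oracles.

These are deliberately naive (per-voxel loops, exhaustive enumeration,
hand-rolled formulas) and share no code with the package's
implementations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def percentile_linear(values, p: float) -> float:
    """Textbook linear-interpolation percentile over a flat sequence."""
    ordered = sorted(float(v) for v in values)
    h = (len(ordered) - 1) * p / 100.0
    lo = math.floor(h)
    hi = math.ceil(h)
    if lo == hi:
        return ordered[lo]
    return ordered[lo] + (h - lo) * (ordered[hi] - ordered[lo])


def naive_invert_black(data: np.ndarray, p: float = 1.0) -> np.ndarray:
    """Per-voxel loop: zero at/below the p-th percentile, else max-x+min."""
    flat = [float(v) for v in data.ravel()]
    t = percentile_linear(flat, p)
    hi = max(flat)
    lo = min(flat)
    out = np.empty(data.shape, dtype=np.float64)
    for i in range(data.shape[0]):
        for j in range(data.shape[1]):
            for k in range(data.shape[2]):
                x = float(data[i, j, k])
                out[i, j, k] = 0.0 if x <= t else hi - x + lo
    return out


def naive_invert_plain(data: np.ndarray) -> np.ndarray:
    flat = [float(v) for v in data.ravel()]
    hi = max(flat)
    lo = min(flat)
    out = np.empty(data.shape, dtype=np.float64)
    for idx in np.ndindex(data.shape):
        out[idx] = hi - float(data[idx]) + lo
    return out


def brute_force_dice(a: np.ndarray, b: np.ndarray) -> float:
    """Triple-loop voxel counting of 2|A.B| / (|A|+|B|); NaN if both empty."""
    na = nb = ninter = 0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            for k in range(a.shape[2]):
                va = bool(a[i, j, k])
                vb = bool(b[i, j, k])
                na += va
                nb += vb
                ninter += va and vb
    if na + nb == 0:
        return float("nan")
    return 2.0 * ninter / (na + nb)


def _midranks(values) -> list[float]:
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


def wilcoxon_exact_enumeration(diff) -> float:
    """Two-sided signed-rank p by enumerating all 2^n sign assignments.

    Zero differences are dropped; ranks of |d| use midranks.  The
    two-sided p doubles the smaller tail of W+ (capped at 1), the
    convention of the exact signed-rank test.
    """
    d = [float(x) for x in diff if x != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = _midranks([abs(x) for x in d])
    w_obs = sum(r for r, x in zip(ranks, d) if x > 0)
    n_le = n_ge = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        n_le += w <= w_obs
        n_ge += w >= w_obs
    total = 2 ** n
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


def bh_step_up(pvalues) -> list[float]:
    """Hand-rolled Benjamini-Hochberg: sort, m*p/j, running min from top."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        running = min(running, m * pvalues[i] / (pos + 1))
        adjusted[i] = running
    return adjusted


def spearman_hand(x, y) -> float:
    """Product-moment correlation of midranks."""
    rx = _midranks(list(x))
    ry = _midranks(list(y))
    mx = sum(rx) / len(rx)
    my = sum(ry) / len(ry)
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    return cov / math.sqrt(vx * vy)
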