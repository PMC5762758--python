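"""Independent brute-force oracles used to cross-check the implementation."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
from scipy import optimize


def fisher_two_sided_exact(table) -> float:
    """Two-sided Fisher p by exact rational hypergeometric enumeration.

    Sums the probabilities of every table with the observed margins whose
    probability does not exceed the observed one, in exact arithmetic.
    """
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return 1.0

    def pmf(x: int) -> Fraction:
        return Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), math.comb(n, c1))

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = pmf(a)
    total = Fraction(0)
    for x in range(lo, hi + 1):
        p = pmf(x)
        if p <= p_obs:
            total += p
    return float(total)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg q-values by direct sort-based computation."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        val = p[i] * m / (rank_from_top + 1)
        running_min = min(running_min, val)
        q[i] = min(running_min, 1.0)
    return q


def restricted_nnls(v, W, keep_mask):
    """NNLS restricted to a signature subset, zero elsewhere."""
    v = np.asarray(v, dtype=float)
    W = np.asarray(W, dtype=float)
    h = np.zeros(W.shape[1])
    idx = np.flatnonzero(keep_mask)
    if idx.size:
        h[idx], _ = optimize.nnls(W[:, idx], v)
    return h


def best_two_state_window(states, breakpoints):
    """Exhaustive enumeration of two-state alternating windows.

    Scans every contiguous window of segments; a window qualifies when all
    adjacent states differ and at most two distinct states occur. Returns
    (n_switches, span_mb) of the window with the most switches (ties:
    smallest span); (0, 0.0) when no window has >= 1 switch.
    """
    n = len(states)
    best = (0, 0.0)
    best_key = None
    for a in range(n):
        for b in range(a + 1, n):
            window = states[a : b + 1]
            if any(x == y for x, y in zip(window, window[1:])):
                continue
            if len(set(window)) > 2:
                continue
            switches = b - a
            span = (breakpoints[b - 1] - breakpoints[a]) / 1e6 if switches >= 2 else 0.0
            key = (switches, -span)
            if best_key is None or key > best_key:
                best_key = key
                best = (switches, span)
    return best
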