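"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths of the package: the exact-test
oracle computes hypergeometric weights from integer binomial coefficients
and maximises the conditional likelihood by dense grid search with local
zoom refinement; the region oracle marks window extents on a base array and
reads off connected components.
"""

from __future__ import annotations

import math

import numpy as np

_LOG_PSI_LIMIT = 40.0


def _support_and_weights(a: int, b: int, c: int, d: int):
    m, n, k = a + c, b + d, a + b
    lo, hi = max(0, k - n), min(k, m)
    xs = list(range(lo, hi + 1))
    weights = [math.comb(m, x) * math.comb(n, k - x) for x in xs]
    return lo, hi, xs, weights


def oracle_fisher_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided p: tail sum of conditional probabilities <= observed (1e-7 slack)."""
    lo, hi, xs, weights = _support_and_weights(a, b, c, d)
    total = sum(weights)
    w_obs = weights[a - lo]
    # integer-only comparison: w <= w_obs * (1 + 1e-7)
    acc = sum(w for w in weights if w * 10**7 <= w_obs * (10**7 + 1))
    return min(acc / total, 1.0)


def _grid_mle(x: int, ks: np.ndarray, logw: np.ndarray, zooms: int = 5) -> float:
    """Maximise logw[x] + x*g - logsumexp(logw + ks*g) over g = log psi."""
    centre, half = 0.0, _LOG_PSI_LIMIT
    best = 0.0
    for _ in range(zooms + 1):
        grid = np.linspace(centre - half, centre + half, 81)
        mat = logw[:, None] + ks[:, None] * grid[None, :]
        mx = mat.max(axis=0)
        lse = mx + np.log(np.exp(mat - mx).sum(axis=0))
        ll = x * grid - lse
        best = float(grid[int(np.argmax(ll))])
        centre, half = best, half * (2.0 / 80) * 2  # bracket two grid steps wide
    return math.exp(best)


def oracle_conditional_mle(a: int, b: int, c: int, d: int) -> float:
    """Conditional-MLE odds ratio by dense grid + zoom refinement."""
    lo, hi, xs, weights = _support_and_weights(a, b, c, d)
    if lo == hi:
        return math.nan
    if a == lo:
        return 0.0
    if a == hi:
        return math.inf
    ks = np.array(xs, dtype=float)
    logw = np.array([math.log(w) for w in weights])
    return _grid_mle(a, ks, logw)


def oracle_tables_for_margins(r1: int, r2: int, c1: int):
    """All 2x2 tables (a, b, c, d) with the given row sums and column-1 sum."""
    n2 = r1 + r2 - c1
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return [(x, r1 - x, c1 - x, r2 - (c1 - x)) for x in range(lo, hi + 1)], lo, hi


def oracle_batch(r1: int, r2: int, c1: int):
    """p-values and MLEs for every table sharing one margin triple.

    Shares the weight vector across the support, so a full sweep over all
    margin combinations stays fast. Returns {a: (p, or)}.
    """
    tables, lo, hi = oracle_tables_for_margins(r1, r2, c1)
    a0, b0, c0, d0 = tables[0]
    _, _, xs, weights = _support_and_weights(a0, b0, c0, d0)
    total = sum(weights)
    ks = np.array(xs, dtype=float)
    logw = np.array([math.log(w) for w in weights])
    out = {}
    for (a, b, c, d) in tables:
        w_obs = weights[a - lo]
        p = min(sum(w for w in weights if w * 10**7 <= w_obs * (10**7 + 1)) / total, 1.0)
        if lo == hi:
            orr = math.nan
        elif a == lo:
            orr = 0.0
        elif a == hi:
            orr = math.inf
        else:
            orr = _grid_mle(a, ks, logw)
        out[a] = (p, orr)
    return out


def oracle_union_regions(qualifying_offsets, window_size: int):
    """Connected components of window extents, by marking a base array."""
    if not qualifying_offsets:
        return []
    hi = max(qualifying_offsets) + window_size - 1
    covered = np.zeros(hi + 2, dtype=bool)
    for o in qualifying_offsets:
        covered[o : o + window_size] = True
    regions = []
    start = None
    for i in range(1, hi + 2):
        if covered[i] and start is None:
            start = i
        elif not covered[i] and start is not None:
            regions.append((start, i - 1))
            start = None
    return regions
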