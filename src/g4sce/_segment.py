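"""Penalized changepoint search for binary (W/C) label sequences.

PELT (pruned exact linear time) minimization of the negative binomial
log-likelihood with a free Watson-fraction per segment plus a constant
penalty per changepoint.  The free-rate cost makes every genuine rate
change detectable (a three-state-constrained cost is blind to splits
where both sides stay heterozygous); segments are snapped to the
WW/WC/CC states afterwards by the caller.

For speed the search runs on small fixed-size read bins (the binomial
cost depends only on cumulative counts, so restricting boundaries to
bin edges is exact for that boundary set) and each found boundary is
then refined to the maximum-likelihood read index between its
neighbouring boundaries.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _cost(ck: np.ndarray, cn: np.ndarray, s: int, t: int) -> float:
    # negative max log-likelihood of bins [s, t) under a free rate
    k = ck[t] - ck[s]
    m = cn[t] - cn[s]
    if k == 0 or k == m:
        return 0.0
    # symmetric form: identical under k <-> m - k (label swap)
    return -(k * (np.log(k) - np.log(m)) + (m - k) * (np.log(m - k) - np.log(m)))


@njit(cache=False)
def _pelt(ck: np.ndarray, cn: np.ndarray, penalty: float, min_size: int) -> np.ndarray:
    n = ck.shape[0] - 1
    inf = np.inf
    F = np.full(n + 1, inf)
    F[0] = -penalty
    prev = np.zeros(n + 1, dtype=np.int64)
    cand = np.zeros(n + 2, dtype=np.int64)
    n_cand = 0
    for t in range(min_size, n + 1):
        # candidate last-changepoints are s <= t - min_size, added once each
        cand[n_cand] = t - min_size
        n_cand += 1
        best = inf
        best_s = 0
        for ci in range(n_cand):
            s = cand[ci]
            if F[s] == inf:
                continue
            v = F[s] + _cost(ck, cn, s, t) + penalty
            if v < best:
                best = v
                best_s = s
        F[t] = best
        prev[t] = best_s
        # prune candidates that can never be optimal again
        kept = 0
        for ci in range(n_cand):
            s = cand[ci]
            if F[s] != inf and F[s] + _cost(ck, cn, s, t) <= F[t]:
                cand[kept] = s
                kept += 1
        n_cand = kept
    bounds = np.zeros(n + 1, dtype=np.int64)
    n_b = 0
    t = n
    while t > 0:
        bounds[n_b] = t
        n_b += 1
        t = prev[t]
    out = np.zeros(n_b, dtype=np.int64)
    for i in range(n_b):
        out[i] = bounds[n_b - 1 - i]
    return out


def _free_rate_ll(k: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Vectorized max log-likelihood of (k W-reads out of m) under a free rate."""
    k = np.asarray(k, dtype=float)
    m = np.asarray(m, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(k > 0, k * (np.log(k) - np.log(m)), 0.0)
        term2 = np.where(m - k > 0, (m - k) * (np.log(m - k) - np.log(m)), 0.0)
    return term1 + term2


def _refine(cw: np.ndarray, a: int, b: int, c: int) -> int:
    """ML position of the boundary between segments [a, b) and [b, c)."""
    cand = np.arange(a + 1, c)
    k_left = cw[cand] - cw[a]
    n_left = cand - a
    k_right = cw[c] - cw[cand]
    n_right = c - cand
    ll = _free_rate_ll(k_left, n_left) + _free_rate_ll(k_right, n_right)
    return int(cand[int(np.argmax(ll))])


def segment_labels(w: np.ndarray, penalty: float, min_reads: int, bin_size: int = 5) -> list[int]:
    """Changepoints (read indices, excluding 0, including n).

    Runs the penalized search on `bin_size`-read bins, then refines each
    boundary to the maximum-likelihood read between its neighbours.
    """
    w = np.ascontiguousarray(w, dtype=np.int64)
    n = len(w)
    if n < 2 * min_reads:
        return [n]
    cw = np.concatenate([[0], np.cumsum(w)])
    edges = np.arange(0, n + 1, bin_size)
    if edges[-1] != n:
        edges = np.append(edges, n)
    ck = cw[edges]
    cn = edges.astype(np.int64)
    min_bins = max(1, int(np.ceil(min_reads / bin_size)))
    bin_bounds = _pelt(ck, cn, penalty, min_bins)
    bounds = [int(edges[b]) for b in bin_bounds]
    if len(bounds) <= 1:
        return [n]
    # refine interior boundaries at read resolution
    full = [0] + bounds
    refined = []
    for i in range(1, len(full) - 1):
        a = refined[-1] if refined else 0
        refined.append(_refine(cw, a, full[i], full[i + 1]))
    return refined + [n]
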