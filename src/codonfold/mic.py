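"""Maximal information coefficient (MIC).

MIC measures general (not necessarily linear) statistical dependence
between two variables on a 0-1 scale: the maximal normalized mutual
information achievable by any grid drawn over the scatter plot, with
grid resolution bounded by B(n) = n^alpha.  The search uses the MINE
approximation: one axis is equipartitioned, the other optimized by
dynamic programming over "clumps" (runs of points sharing a row), with
the clump count capped at c times the number of target columns.  Both
axis orientations are tried.  Significance comes from a permutation
test.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["mic_score", "mic_statistic"]


def _equipartition(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign each point to one of ``n_bins`` rows of near-equal count.

    Tied values always share a row (the row of the tie group's first
    occurrence in sort order), so the partition is a function of the
    data, not of sort stability.
    """
    n = len(values)
    order = np.argsort(values, kind="mergesort")
    raw = np.arange(n) * n_bins // n            # bin of each sort position
    sorted_vals = values[order]
    new_group = np.empty(n, dtype=bool)
    new_group[0] = True
    new_group[1:] = sorted_vals[1:] != sorted_vals[:-1]
    group_id = np.cumsum(new_group) - 1
    first_pos = np.flatnonzero(new_group)       # sort position of group head
    bins_sorted = raw[first_pos][group_id]
    # renumber to consecutive bins, back in original point order
    _, consec = np.unique(bins_sorted, return_inverse=True)
    out = np.empty(n, dtype=np.int64)
    out[order] = consec
    return out


def _clumps(x: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Cumulative per-row counts at clump boundaries.

    Points are ordered by x; points with equal x form one clump, and
    adjacent clumps whose points all share one row are merged.  Returns
    an array of shape (n_clumps + 1, n_rows).
    """
    n = len(x)
    order = np.lexsort((rows, x))
    xs, rs = x[order], rows[order]
    n_rows = int(rows.max()) + 1
    new_grp = np.empty(n, dtype=bool)
    new_grp[0] = True
    new_grp[1:] = xs[1:] != xs[:-1]
    gidx = np.cumsum(new_grp) - 1
    n_groups = int(gidx[-1]) + 1
    counts = np.zeros((n_groups, n_rows), dtype=np.int64)
    np.add.at(counts, (gidx, rs), 1)
    # merge adjacent single-row groups in the same row
    nonzero = counts > 0
    single = nonzero.sum(axis=1) == 1
    row_of = np.argmax(counts, axis=1)
    keep = np.ones(n_groups, dtype=bool)
    merged = counts
    for g in range(1, n_groups):
        prev = g - 1
        while not keep[prev]:
            prev -= 1
        if single[g] and single[prev] and row_of[g] == row_of[prev]:
            merged[prev] += merged[g]
            keep[g] = False
    merged = merged[keep]
    cum = np.zeros((merged.shape[0] + 1, n_rows), dtype=np.int64)
    np.cumsum(merged, axis=0, out=cum[1:])
    return cum


def _superclumps(cum: np.ndarray, max_clumps: int) -> np.ndarray:
    """Coarsen clump boundaries to at most ``max_clumps`` superclumps."""
    k = cum.shape[0] - 1
    if k <= max_clumps:
        return cum
    totals = cum.sum(axis=1)
    n = totals[-1]
    # keep the clump boundary closest to each equipartition quantile
    targets = np.arange(1, max_clumps) * n / max_clumps
    keep = sorted({int(np.argmin(np.abs(totals - t))) for t in targets}
                  - {0, k})
    idx = [0] + keep + [k]
    return cum[idx]


@njit(cache=True)
def _optimize_axis(cum, n_total, max_bins):  # pragma: no cover - jitted
    """Max of H(P) - H(P,Q) over partitions of the clumps into <= max_bins."""
    k = cum.shape[0] - 1
    n_rows = cum.shape[1]
    tot = np.zeros(k + 1, dtype=np.int64)
    for t in range(k + 1):
        s = 0
        for q in range(n_rows):
            s += cum[t, q]
        tot[t] = s
    NEG = -1e18
    # bincost[s, t]: contribution of a bin spanning clumps (s, t]
    cost = np.full((k + 1, k + 1), NEG)
    for s in range(k):
        for t in range(s + 1, k + 1):
            nb = tot[t] - tot[s]
            v = -(nb / n_total) * np.log(nb / n_total)
            for q in range(n_rows):
                nbq = cum[t, q] - cum[s, q]
                if nbq > 0:
                    v += (nbq / n_total) * np.log(nbq / n_total)
            cost[s, t] = v
    F = np.full((k + 1, max_bins + 1), NEG)
    F[0, 0] = 0.0
    for t in range(1, k + 1):
        top = max_bins if max_bins < t else t
        for l in range(1, top + 1):
            best = NEG
            for s in range(l - 1, t):
                if F[s, l - 1] > NEG:
                    c = F[s, l - 1] + cost[s, t]
                    if c > best:
                        best = c
            F[t, l] = best
    best = NEG
    for l in range(1, max_bins + 1):
        if F[k, l] > best:
            best = F[k, l]
    return best


def _entropy(counts: np.ndarray, n: int) -> float:
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


class _AxisState:
    """Equipartition rows and clump table for one (data, n_bins) pair."""

    def __init__(self, x: np.ndarray, y: np.ndarray, n_bins: int):
        rows = _equipartition(y, n_bins)
        self.n_rows = int(rows.max()) + 1
        self.hq = _entropy(np.bincount(rows), len(y))
        self.cum = _clumps(x, rows) if self.n_rows > 1 else None


def _axis_mi(state: _AxisState, n: int, a: int, c: int) -> float:
    """MI with the state's rows fixed and the x-axis optimized into <= a bins."""
    if state.cum is None:
        return 0.0
    cum = state.cum
    if c > 0:
        cum = _superclumps(cum, max(1, c * a))
    return state.hq + float(_optimize_axis(cum, n, a))


def mic_statistic(x, y, alpha: float = 0.6, c: int = 15) -> float:
    """MIC of paired observations (no p-value).

    ``alpha`` sets the grid-resolution bound B(n) = n^alpha; ``c``
    bounds the DP search (clumps <= c * columns); ``c=0`` disables the
    superclump cap, making the per-grid optimization exact over the
    equipartitioned axis.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0
    B = max(float(n) ** alpha, 4.0)
    states_xy: dict[int, _AxisState] = {}   # y binned into b rows, x optimized
    states_yx: dict[int, _AxisState] = {}   # x binned into a rows, y optimized
    best = 0.0
    for a in range(2, int(B // 2) + 1):
        for b in range(2, int(B // a) + 1):
            if b not in states_xy:
                states_xy[b] = _AxisState(x, y, b)
            if a not in states_yx:
                states_yx[a] = _AxisState(y, x, a)
            mi = max(_axis_mi(states_xy[b], n, a, c),
                     _axis_mi(states_yx[a], n, b, c))
            val = mi / np.log(min(a, b))
            if val > best:
                best = val
    return float(min(best, 1.0))


def mic_score(x, y, permutations: int = 10000, seed: int | None = None,
              alpha: float = 0.6, c: int = 15) -> tuple[float, float]:
    """(MIC, permutation p) for paired observations.

    p is the upper-tail probability of the observed MIC under random
    re-pairings of y, with the +1 correction: (1 + #{MIC_perm >=
    MIC_obs}) / (permutations + 1).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    obs = mic_statistic(x, y, alpha, c)
    if permutations < 1:
        return obs, float("nan")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        if mic_statistic(x, rng.permutation(y), alpha, c) >= obs:
            hits += 1
    return obs, (1 + hits) / (permutations + 1)
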