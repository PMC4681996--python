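"""Numba kernels for the fixed-margin (curveball) null model.

The incidence matrix is held as a padded adjacency-list: ``rows[r, :lens[r]]``
are the sorted column indices of row r.  A curveball trade picks two distinct
rows, splits their columns into shared and non-shared, shuffles the pooled
non-shared columns and deals them back keeping both row sums — a move that
preserves all margins and, iterated, samples the fill class uniformly.

Per-replicate co-occurrence is accumulated into ragged per-pair histograms:
pair p of columns (i, j) with i < j owns ``hist[offsets[p]:offsets[p+1]]``,
whose width is min(col_sum_i, col_sum_j) + 1, the exact upper bound of the
pair's co-occurrence.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def seed_rng(seed: int) -> None:
    np.random.seed(seed)


@njit(cache=True)
def curveball_trades(rows, lens, n_trades, scratch):
    """Perform ``n_trades`` curveball trades in place.

    ``scratch`` is an int64 workspace of length >= 3 * max row length.
    Row entries stay sorted.
    """
    n_rows = rows.shape[0]
    if n_rows < 2:
        return
    max_k = rows.shape[1]
    shared = scratch[:max_k]
    only_a = scratch[max_k : 2 * max_k]
    only_b = scratch[2 * max_k : 3 * max_k]
    for _ in range(n_trades):
        i = np.random.randint(n_rows)
        j = np.random.randint(n_rows - 1)
        if j >= i:
            j += 1
        li = lens[i]
        lj = lens[j]
        # merge the two sorted rows into shared / exclusive parts
        x = 0
        y = 0
        ns = 0
        na = 0
        nb = 0
        while x < li and y < lj:
            ca = rows[i, x]
            cb = rows[j, y]
            if ca == cb:
                shared[ns] = ca
                ns += 1
                x += 1
                y += 1
            elif ca < cb:
                only_a[na] = ca
                na += 1
                x += 1
            else:
                only_b[nb] = cb
                nb += 1
                y += 1
        while x < li:
            only_a[na] = rows[i, x]
            na += 1
            x += 1
        while y < lj:
            only_b[nb] = rows[j, y]
            nb += 1
            y += 1
        if na == 0 or nb == 0:
            continue  # nothing tradeable
        # pool the exclusives in-place in only_a then only_b order
        pool_n = na + nb
        for t in range(nb):
            only_a[na + t] = only_b[t]
        # Fisher-Yates shuffle of the pool
        for t in range(pool_n - 1, 0, -1):
            u = np.random.randint(t + 1)
            tmp = only_a[t]
            only_a[t] = only_a[u]
            only_a[u] = tmp
        # deal back: first na to row i, rest to row j, plus shared
        for t in range(ns):
            rows[i, t] = shared[t]
            rows[j, t] = shared[t]
        for t in range(na):
            rows[i, ns + t] = only_a[t]
        for t in range(nb):
            rows[j, ns + t] = only_a[na + t]
        rows[i, :li] = np.sort(rows[i, :li])
        rows[j, :lj] = np.sort(rows[j, :lj])


@njit(cache=True)
def accumulate_cooccurrence(rows, lens, pair_id, cooc):
    """Pairwise co-occurrence counts of the current matrix into ``cooc``."""
    cooc[:] = 0
    for r in range(rows.shape[0]):
        l = lens[r]
        for x in range(l):
            cx = rows[r, x]
            for y in range(x + 1, l):
                cooc[pair_id[cx, rows[r, y]]] += 1


@njit(cache=True)
def run_chain(rows, lens, pair_id, offsets, n_reps, burn_trades, thin_trades, seed):
    """One long curveball chain; returns ragged per-pair histograms.

    Burn-in of ``burn_trades`` trades, then ``n_reps`` samples separated by
    ``thin_trades`` trades each.  ``rows`` is modified in place.
    """
    np.random.seed(seed)
    n_pairs = offsets.shape[0] - 1
    hist = np.zeros(offsets[n_pairs], dtype=np.int64)
    cooc = np.zeros(n_pairs, dtype=np.int64)
    max_k = rows.shape[1]
    scratch = np.empty(3 * max_k, dtype=rows.dtype)
    curveball_trades(rows, lens, burn_trades, scratch)
    for _ in range(n_reps):
        curveball_trades(rows, lens, thin_trades, scratch)
        accumulate_cooccurrence(rows, lens, pair_id, cooc)
        for p in range(n_pairs):
            hist[offsets[p] + cooc[p]] += 1
    return hist


@njit(cache=True)
def run_independent(rows0, lens, pair_id, offsets, n_reps, burn_trades, seed):
    """Independent-chain sampling: every replicate restarts from the input."""
    np.random.seed(seed)
    n_pairs = offsets.shape[0] - 1
    hist = np.zeros(offsets[n_pairs], dtype=np.int64)
    cooc = np.zeros(n_pairs, dtype=np.int64)
    max_k = rows0.shape[1]
    scratch = np.empty(3 * max_k, dtype=rows0.dtype)
    rows = np.empty_like(rows0)
    for _ in range(n_reps):
        rows[:] = rows0
        curveball_trades(rows, lens, burn_trades, scratch)
        accumulate_cooccurrence(rows, lens, pair_id, cooc)
        for p in range(n_pairs):
            hist[offsets[p] + cooc[p]] += 1
    return hist
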