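"""Numba kernels: exhaustive solution counting and the inner search loop.

These are performance backends only.  Their contracts live in
:mod:`cryptoswarm.puzzle` and :mod:`cryptoswarm.dynamics`, which also provide
a pure-Python reference implementation of the search used by the test suite
for cross-validation.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Outcome codes shared with dynamics.py
MOVED = 0
IMITATED = 1
WASTED = 2


@njit(cache=True)
def count_zero_cost_kernel(coefs, lead_mask, limit):  # pragma: no cover - thin
    """Count injective letter->digit maps with zero cost.

    Depth-first enumeration over all 10!/(10-L)! injective maps, maintaining
    the partial signed sum sum_i coefs[i]*digit[i].  Subtrees rooted at a
    leading letter holding digit 0 are skipped (those states carry the
    penalty cost, never zero).  Stops early once ``limit`` solutions are
    found.
    """
    L = coefs.shape[0]
    used = np.zeros(10, dtype=np.bool_)
    choice = np.full(L, -1, dtype=np.int64)
    partial = np.zeros(L + 1, dtype=np.int64)
    count = 0
    pos = 0
    while pos >= 0:
        d = choice[pos]
        if d >= 0:
            used[d] = False
        d += 1
        while d < 10 and used[d]:
            d += 1
        if d == 10:
            choice[pos] = -1
            pos -= 1
            continue
        choice[pos] = d
        used[d] = True
        if d == 0 and lead_mask[pos]:
            continue
        partial[pos + 1] = partial[pos] + coefs[pos] * d
        if pos == L - 1:
            if partial[L] == 0:
                count += 1
                if count >= limit:
                    return count
            continue
        pos += 1
    return count


@njit(inline="always")
def _sum_of(coefs, row):
    s = 0
    for j in range(coefs.shape[0]):
        s += coefs[j] * row[j]
    return s


@njit(inline="always")
def _cost_from_sum(s, lead_idx, penalty, row):
    for k in range(lead_idx.shape[0]):
        if row[lead_idx[k]] == 0:
            return penalty
    return abs(s)


@njit(cache=True)
def search_kernel(
    coefs,
    lead_idx,
    penalty,
    assign,
    net,
    p,
    use_global,
    max_trials,
    seed,
    want_trace,
):  # pragma: no cover - exercised via dynamics.run_search
    """Run one search to completion; mutates ``assign`` in place.

    Parameters: ``coefs`` int64[L] signed positional weights; ``lead_idx``
    indices of leading letters; ``assign`` int64[N, L] initial states;
    ``net`` int64[N, K] influencer lists (K may be 0 when p == 0).

    Returns ``(t_star, n_change_events, wasted, n_imitations, capped,
    trace)`` where ``trace[t-1]`` is the population minimum cost after trial
    ``t`` (empty array unless ``want_trace``).
    """
    np.random.seed(seed)
    N, L = assign.shape
    K = net.shape[1]

    costs = np.empty(N, dtype=np.int64)
    sums = np.empty(N, dtype=np.int64)
    # inv[i, d] = letter position of digit d for agent i, or -1 if unused
    inv = np.full((N, 10), -1, dtype=np.int64)
    for i in range(N):
        sums[i] = _sum_of(coefs, assign[i])
        costs[i] = _cost_from_sum(sums[i], lead_idx, penalty, assign[i])
        for j in range(L):
            inv[i, assign[i, j]] = j

    prev_min = costs[0]
    for i in range(1, N):
        if costs[i] < prev_min:
            prev_min = costs[i]

    trace = np.empty(1024 if want_trace else 0, dtype=np.int64)
    order = np.arange(N)
    digits = np.arange(10)
    # number of injective draws 10*9*...*(10-L+1), for the global move
    n_inj = 1
    for k in range(L):
        n_inj *= 10 - k
    wasted = 0
    n_imit = 0
    changes = 0

    for t in range(1, max_trials + 1):
        # random update order (Fisher-Yates)
        for k in range(N - 1, 0, -1):
            r = np.random.randint(0, k + 1)
            tmp = order[k]
            order[k] = order[r]
            order[r] = tmp

        for n in range(N):
            idx = order[n]
            if p > 0.0 and np.random.random() < p:
                # model = minimum-cost influencer, ties uniform (reservoir)
                best = net[idx, 0]
                bc = costs[best]
                ties = 1
                for k in range(1, K):
                    m = net[idx, k]
                    cm = costs[m]
                    if cm < bc:
                        bc = cm
                        best = m
                        ties = 1
                    elif cm == bc:
                        ties += 1
                        if np.random.random() * ties < 1.0:
                            best = m
                if costs[idx] < bc:
                    wasted += 1
                    continue
                ndiff = 0
                for j in range(L):
                    if assign[idx, j] != assign[best, j]:
                        ndiff += 1
                if ndiff == 0:  # identical to model
                    wasted += 1
                    continue
                # assimilate one differing letter-digit pairing
                r = np.random.randint(0, ndiff)
                q = -1
                seen = 0
                for j in range(L):
                    if assign[idx, j] != assign[best, j]:
                        if seen == r:
                            q = j
                            break
                        seen += 1
                dm = assign[best, q]
                dt = assign[idx, q]
                pos2 = inv[idx, dm]
                if pos2 >= 0:
                    assign[idx, pos2] = dt
                    inv[idx, dt] = pos2
                    sums[idx] += coefs[pos2] * (dt - dm)
                else:
                    inv[idx, dt] = -1
                assign[idx, q] = dm
                inv[idx, dm] = q
                sums[idx] += coefs[q] * (dm - dt)
                costs[idx] = _cost_from_sum(sums[idx], lead_idx, penalty, assign[idx])
                n_imit += 1
            else:
                if use_global:
                    # uniform injective draw: one uniform index decoded in
                    # factorial base drives a partial Fisher-Yates over 0..9
                    s = 0
                    for d in range(10):
                        inv[idx, d] = -1
                    code = np.random.randint(0, n_inj)
                    for k in range(L):
                        r = k + code % (10 - k)
                        code //= 10 - k
                        tmp = digits[k]
                        digits[k] = digits[r]
                        digits[r] = tmp
                        assign[idx, k] = digits[k]
                        inv[idx, digits[k]] = k
                        s += coefs[k] * digits[k]
                    sums[idx] = s
                else:
                    # letter i1 takes a new digit d; if d is in use the two
                    # letters swap (== uniform pair swap when L == 10)
                    i1 = np.random.randint(0, L)
                    d_old = assign[idx, i1]
                    d = np.random.randint(0, 9)
                    if d >= d_old:
                        d += 1
                    i2 = inv[idx, d]
                    if i2 >= 0:
                        assign[idx, i2] = d_old
                        inv[idx, d_old] = i2
                        sums[idx] += coefs[i2] * (d_old - d)
                    else:
                        inv[idx, d_old] = -1
                    assign[idx, i1] = d
                    inv[idx, d] = i1
                    sums[idx] += coefs[i1] * (d - d_old)
                costs[idx] = _cost_from_sum(sums[idx], lead_idx, penalty, assign[idx])

        cur_min = costs[0]
        for i in range(1, N):
            if costs[i] < cur_min:
                cur_min = costs[i]
        if want_trace:
            if t > trace.shape[0]:
                grown = np.empty(trace.shape[0] * 2, dtype=np.int64)
                grown[: trace.shape[0]] = trace
                trace = grown
            trace[t - 1] = cur_min
        if cur_min != prev_min:
            changes += 1
            prev_min = cur_min
        if cur_min == 0:
            return t, changes, wasted, n_imit, False, trace[:t]

    return max_trials, changes, wasted, n_imit, True, trace[:max_trials]
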