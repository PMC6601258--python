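"""Compiled inner loops for the connected-cluster search.

The heuristic search (multi-seed greedy growth with best-prefix tracking,
followed by a 1-swap local search per seed) runs once per Monte Carlo
replicate, i.e. tens of thousands of times per analysis, so it is compiled
with numba over CSR adjacency arrays.  The exact enumeration oracle lives
in :mod:`graphscan.search` in plain Python and never calls into here.

Tie-breaking is deterministic throughout: candidate nodes are scanned in
ascending index order with strict-improvement updates, and equal-score
clusters are resolved by lexicographic order of the sorted member index
list.  Node indices follow the sorted county-id order, so index order and
county-id order coincide.
"""

from __future__ import annotations

import numpy as np
from numba import njit

KULLDORFF = 0
EXPECTATION = 1


@njit(cache=False)
def score_cb(c, b, c_tot, b_tot, kind):
    """Log likelihood ratio for aggregated (events c, baseline b)."""
    if kind == KULLDORFF:
        if b_tot <= 0.0 or c_tot <= 0.0:
            return 0.0
        expected = c_tot * b / b_tot
        if c <= expected or expected <= 0.0:
            return 0.0
        s = c * np.log(c / expected)
        rem = c_tot - c
        if rem > 0.0:
            s += rem * np.log(rem / (c_tot - expected))
        return s
    else:
        if b <= 0.0 or c <= b:
            return 0.0
        return c * np.log(c / b) + b - c


@njit(cache=False)
def _lex_less(a, b):
    """True when sorted index array ``a`` precedes ``b`` lexicographically."""
    n = min(a.size, b.size)
    for i in range(n):
        if a[i] < b[i]:
            return True
        if a[i] > b[i]:
            return False
    return a.size < b.size


@njit(cache=False)
def _connected_without(members, m, skip, indptr, indices, mem_mask, visited, stack):
    """Is the member set minus members[skip] connected? (m >= 2)"""
    skip_node = members[skip]
    start = members[1] if skip == 0 else members[0]
    top = 0
    stack[top] = start
    top += 1
    visited[start] = 1
    count = 1
    while top > 0:
        top -= 1
        v = stack[top]
        for ptr in range(indptr[v], indptr[v + 1]):
            w = indices[ptr]
            if mem_mask[w] == 1 and w != skip_node and visited[w] == 0:
                visited[w] = 1
                stack[top] = w
                top += 1
                count += 1
    for i in range(m):
        visited[members[i]] = 0
    return count == m - 1


@njit(cache=False)
def _local_search(
    members, m, indptr, indices, ev, base, c_tot, b_tot, kind, active,
    mem_mask, visited, stack,
):
    """1-swap hill climbing: drop one member, add one neighbour of the rest.

    Mutates ``members[:m]`` in place; returns the final score.  Strict
    improvement guarantees termination; the iteration cap is a safety net.
    """
    n = ev.shape[0]
    for i in range(m):
        mem_mask[members[i]] = 1
    c = 0.0
    b = 0.0
    for i in range(m):
        c += ev[members[i]]
        b += base[members[i]]
    cur = score_cb(c, b, c_tot, b_tot, kind)
    for _it in range(1000):
        best_s = cur
        best_mi = -1
        best_u = -1
        for mi in range(m):
            mnode = members[mi]
            if m > 1 and not _connected_without(
                members, m, mi, indptr, indices, mem_mask, visited, stack
            ):
                continue
            for u in range(n):
                if active[u] == 0 or mem_mask[u] == 1:
                    continue
                if m > 1:
                    ok = False
                    for ptr in range(indptr[u], indptr[u + 1]):
                        w = indices[ptr]
                        if mem_mask[w] == 1 and w != mnode:
                            ok = True
                            break
                    if not ok:
                        continue
                s = score_cb(
                    c - ev[mnode] + ev[u], b - base[mnode] + base[u],
                    c_tot, b_tot, kind,
                )
                if s > best_s:
                    best_s = s
                    best_mi = mi
                    best_u = u
        if best_mi < 0:
            break
        mnode = members[best_mi]
        mem_mask[mnode] = 0
        mem_mask[best_u] = 1
        members[best_mi] = best_u
        c += ev[best_u] - ev[mnode]
        b += base[best_u] - base[mnode]
        cur = best_s
    for i in range(m):
        mem_mask[members[i]] = 0
    # fresh sum for a rounding-stable final score
    c = 0.0
    b = 0.0
    for i in range(m):
        c += ev[members[i]]
        b += base[members[i]]
    return score_cb(c, b, c_tot, b_tot, kind)


@njit(cache=False)
def search_core(indptr, indices, ev, base, c_tot, b_tot, kind, max_size, active):
    """Best connected cluster (score, sorted member indices) over active nodes."""
    n = ev.shape[0]
    in_stamp = np.zeros(n, np.int64)
    adj_stamp = np.zeros(n, np.int64)
    adj_val = np.zeros(n, np.int64)
    order = np.empty(max_size, np.int64)
    members = np.empty(max_size, np.int64)
    mem_mask = np.zeros(n, np.uint8)
    visited = np.zeros(n, np.uint8)
    stack = np.empty(max_size + 1, np.int64)

    best_score = -1.0
    best_members = np.empty(0, np.int64)
    stamp = 0
    for seed in range(n):
        if active[seed] == 0:
            continue
        stamp += 1
        in_stamp[seed] = stamp
        order[0] = seed
        size = 1
        c = ev[seed]
        b = base[seed]
        for ptr in range(indptr[seed], indptr[seed + 1]):
            w = indices[ptr]
            if adj_stamp[w] != stamp:
                adj_stamp[w] = stamp
                adj_val[w] = 0
            adj_val[w] += 1
        bp_score = score_cb(c, b, c_tot, b_tot, kind)
        bp_len = 1
        while size < max_size:
            pick = -1
            pick_s = -1.0e300
            for u in range(n):
                if active[u] == 0 or in_stamp[u] == stamp:
                    continue
                if adj_stamp[u] != stamp or adj_val[u] == 0:
                    continue
                s = score_cb(c + ev[u], b + base[u], c_tot, b_tot, kind)
                if s > pick_s:
                    pick_s = s
                    pick = u
            if pick < 0:
                break
            in_stamp[pick] = stamp
            order[size] = pick
            size += 1
            c += ev[pick]
            b += base[pick]
            for ptr in range(indptr[pick], indptr[pick + 1]):
                w = indices[ptr]
                if adj_stamp[w] != stamp:
                    adj_stamp[w] = stamp
                    adj_val[w] = 0
                adj_val[w] += 1
            if pick_s > bp_score:
                bp_score = pick_s
                bp_len = size
        m = bp_len
        for i in range(m):
            members[i] = order[i]
        cand_score = _local_search(
            members, m, indptr, indices, ev, base, c_tot, b_tot, kind,
            active, mem_mask, visited, stack,
        )
        cand_sorted = np.sort(members[:m].copy())
        if cand_score > best_score or (
            cand_score == best_score and _lex_less(cand_sorted, best_members)
        ):
            best_score = cand_score
            best_members = cand_sorted
    return best_score, best_members
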