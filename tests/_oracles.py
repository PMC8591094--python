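"""Independent reference implementations used as test oracles.

Everything here is deliberately written from the textbook definitions,
separately from the package code paths it checks: brute-force BH step-up,
a loop-based dense MCL iteration, hand product-limit and log-rank
computations, and exact hypergeometric tail summation.
"""

from __future__ import annotations

import math

import numpy as np


def bh_stepup_bruteforce(p_values):
    """adj_p(i) = min over j with rank(j) >= rank(i) of p(j)*m/rank(j), cap 1.

    Ranks are assigned stably (ties keep input order). Direct double scan
    over the sorted values.
    """
    p = list(map(float, p_values))
    m = len(p)
    order = sorted(range(m), key=lambda i: (p[i], i))  # stable ranks
    adjusted_sorted = []
    for pos in range(m):
        candidates = [p[order[k]] * m / (k + 1) for k in range(pos, m)]
        adjusted_sorted.append(min(1.0, min(candidates)))
    out = [0.0] * m
    for pos, i in enumerate(order):
        out[i] = adjusted_sorted[pos]
    return out


# ---------------------------------------------------------------------------
# MCL
# ---------------------------------------------------------------------------


def mcl_reference(nodes, edges, expansion_e=2, inflation_r=2.0,
                  self_loop_weight=1.0, prune_threshold=1e-5,
                  max_iterations=200, convergence_tol=1e-8):
    """Dense-iteration MCL written as a direct transcription of the procedure.

    Same parameter semantics as the package: self-loops added, column
    normalize, then repeat {expand by matrix power, inflate entry-wise and
    renormalize, prune below threshold and renormalize} until the max entry
    change drops below tol; clusters = connected components of the
    symmetrized nonzero support, found by depth-first search.

    On graphs with exact attractor symmetry, floating-point rounding decides
    which side a tied node joins; the elementary numpy operations here apply
    them in the same order as any straightforward dense implementation, so
    "identical clustering" is well-defined for the comparison.
    """
    nodes = sorted(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for a, b in edges:
        m[idx[a], idx[b]] = 1.0
        m[idx[b], idx[a]] = 1.0
    for i in range(n):
        m[i, i] = self_loop_weight
    m = m / m.sum(axis=0)

    for _ in range(max_iterations):
        prev = m.copy()
        power = prev
        for _ in range(expansion_e - 1):
            power = power.dot(prev)
        m = power**inflation_r
        m = m / m.sum(axis=0)
        if prune_threshold > 0:
            m[m < prune_threshold] = 0.0
            sums = m.sum(axis=0)
            for j in range(n):
                if sums[j] == 0.0:
                    m[j, j] = 1.0
                    sums[j] = 1.0
            m = m / sums
        if np.abs(m - prev).max() < convergence_tol:
            break

    # connected components of the symmetrized support, depth-first
    adjacency = {v: set() for v in nodes}
    for i in range(n):
        for j in range(n):
            if i != j and (m[i, j] > 0 or m[j, i] > 0):
                adjacency[nodes[i]].add(nodes[j])
                adjacency[nodes[j]].add(nodes[i])
    seen, clusters = set(), []
    for v in nodes:
        if v in seen:
            continue
        stack, comp = [v], set()
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(adjacency[u] - comp)
        seen |= comp
        clusters.append(frozenset(comp))
    return frozenset(clusters)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


def km_by_hand(times, events):
    """Product-limit estimate at each distinct event time: S *= (1 - d/n)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    s = 1.0
    curve = {}
    for t in sorted(set(times[events == 1])):
        n_at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d / n_at_risk
        curve[float(t)] = s
    return curve


def logrank_by_hand(times1, events1, times2, events2):
    """Two-group log-rank chi-square from explicit 2x2 tables per event time."""
    t1, e1 = np.asarray(times1, float), np.asarray(events1, int)
    t2, e2 = np.asarray(times2, float), np.asarray(events2, int)
    all_times = np.concatenate([t1, t2])
    all_events = np.concatenate([e1, e2])
    observed1 = expected1 = variance = 0.0
    for t in sorted(set(all_times[all_events == 1])):
        n1 = int(np.sum(t1 >= t))
        n2 = int(np.sum(t2 >= t))
        nt = n1 + n2
        d1 = int(np.sum((t1 == t) & (e1 == 1)))
        d2 = int(np.sum((t2 == t) & (e2 == 1)))
        dt = d1 + d2
        if nt == 0 or dt == 0:
            continue
        observed1 += d1
        expected1 += dt * n1 / nt
        if nt > 1:
            variance += dt * (n1 / nt) * (n2 / nt) * (nt - dt) / (nt - 1)
    if variance == 0:
        return 0.0
    return (observed1 - expected1) ** 2 / variance


# ---------------------------------------------------------------------------
# hypergeometric
# ---------------------------------------------------------------------------


def hypergeom_tail_sum(observed, n_background, n_term, n_query):
    """P(X >= observed) by direct summation of the hypergeometric pmf."""
    total = 0.0
    upper = min(n_term, n_query)
    for k in range(observed, upper + 1):
        total += (
            math.comb(n_term, k)
            * math.comb(n_background - n_term, n_query - k)
            / math.comb(n_background, n_query)
        )
    return min(total, 1.0)
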