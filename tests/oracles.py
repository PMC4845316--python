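"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (enumeration / closed forms) and
shares no code with the package paths it checks.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def set_partitions(items):
    """Yield all partitions of ``items`` as lists of lists (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def exhaustive_best_partition(value_fn, nodes):
    """Maximize ``value_fn(partition)`` over every partition of ``nodes``."""
    best_value, best_part = -np.inf, None
    for part in set_partitions(nodes):
        v = value_fn(part)
        if v > best_value:
            best_value, best_part = v, part
    return best_value, best_part


def fisher_two_sided(table) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def fisher_greater(table) -> float:
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)
               for x in range(a, hi + 1))


def ranksum_exact_p(x, y) -> float:
    """Two-sided rank-sum p by enumerating every split of the pooled ranks.

    Handles ties through average ranks; the null enumerates all
    C(n1+n2, n1) assignments of the pooled values to group 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    order = pooled.argsort(kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        w = ranks[list(idx)].sum()
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
    return count / total


def km_by_hand(times, events):
    """Product-limit S at each distinct event time (events before censorings)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    out = []
    s = 1.0
    for t in np.unique(times):
        at_risk = (times >= t).sum()
        d = ((times == t) & events).sum()
        if d:
            s *= 1 - d / at_risk
            out.append((float(t), s))
    return out


def pam_objective(dist_values, medoids) -> float:
    return float(dist_values[:, list(medoids)].min(axis=1).sum())


def best_medoids(dist_values, k):
    n = dist_values.shape[0]
    best = (np.inf, None)
    for meds in itertools.combinations(range(n), k):
        obj = pam_objective(dist_values, meds)
        if obj < best[0] - 1e-12:
            best = (obj, meds)
    return best
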