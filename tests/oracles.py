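"""Independent brute-force reference implementations used only in tests.

Each function below recomputes a statistic from first principles
(explicit loops, enumeration) without calling the package or scipy, so
agreement with the package is a genuine cross-check.
"""

import math
from itertools import product


def midranks(values):
    """Mid-ranks (ties averaged), rank 1 = smallest."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j + 2) / 2  # ranks are 1-based
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def kruskal_h(groups):
    """Kruskal-Wallis H with tie correction, from pooled mid-ranks."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    ranks = midranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        rsum = sum(ranks[start : start + len(g)])
        h += rsum**2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    counts = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    t = sum(c**3 - c for c in counts.values())
    denom = 1.0 - t / (n**3 - n)
    return h / denom if denom > 0 else float("nan")


def signed_rank_v(d):
    """Sum of positive ranks (zeros dropped, mid-ranks on |d|)."""
    nz = [x for x in d if x != 0]
    ranks = midranks([abs(x) for x in nz])
    return sum(r for x, r in zip(nz, ranks) if x > 0)


def signed_rank_exact_p(d):
    """Exact two-sided signed-rank p by enumerating all sign assignments."""
    nz = [x for x in d if x != 0]
    ranks = midranks([abs(x) for x in nz])
    v_obs = sum(r for x, r in zip(nz, ranks) if x > 0)
    total = 2 ** len(nz)
    vs = []
    for signs in product([0, 1], repeat=len(nz)):
        vs.append(sum(r for s, r in zip(signs, ranks) if s))
    mean_v = sum(ranks) / 2
    dev = abs(v_obs - mean_v)
    extreme = sum(1 for v in vs if abs(v - mean_v) >= dev - 1e-12)
    return v_obs, extreme / total


def holm(p_values):
    """Holm step-down adjusted p-values, same order as the input."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p_values[i])
        adjusted[i] = min(1.0, running)
    return adjusted


def euclidean(p1, p2):
    return math.sqrt((p2[0] - p1[0]) ** 2 + (p2[1] - p1[1]) ** 2)


def path_length(points):
    return sum(euclidean(points[i], points[i + 1]) for i in range(len(points) - 1))


def kendall_w(rank_rows):
    """Kendall's W from a list of per-participant rank lists."""
    m = len(rank_rows)
    n = len(rank_rows[0])
    col_sums = [sum(row[j] for row in rank_rows) for j in range(n)]
    mean = sum(col_sums) / n
    s = sum((r - mean) ** 2 for r in col_sums)
    return 12.0 * s / (m**2 * (n**3 - n))
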