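"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive (enumeration, direct definitions)
and shares no code with the package paths it verifies.
"""

from itertools import combinations
from math import comb

import numpy as np


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by direct summation of the hypergeometric pmf."""
    total = comb(N, n)
    acc = 0
    for i in range(k, min(K, n) + 1):
        acc += comb(K, i) * comb(N - K, n - i)
    return acc / total


def hypergeom_tail_enumerated(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by enumerating every possible draw (N <= 15)."""
    hits = 0
    total = 0
    success = set(range(K))
    for draw in combinations(range(N), n):
        total += 1
        if len(success.intersection(draw)) >= k:
            hits += 1
    return hits / total


def bh_stepup(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values from the step-up definition."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, p[idx] * m / rank_from_top)
        q[idx] = running
    return q


def dpi_bruteforce(edges, tolerance=0.0):
    """DPI by naive enumeration of all node triples on the input graph."""
    mi = {frozenset((a, b)): m for a, b, m in edges if a != b}
    nodes = sorted({n for e in mi for n in e})
    doomed = set()
    for x, y, z in combinations(nodes, 3):
        exy, eyz, exz = (
            frozenset((x, y)),
            frozenset((y, z)),
            frozenset((x, z)),
        )
        if exy in mi and eyz in mi and exz in mi:
            triple = [(exy, mi[exy]), (eyz, mi[eyz]), (exz, mi[exz])]
            for i in range(3):
                others = [triple[j][1] for j in range(3) if j != i]
                if triple[i][1] < (1.0 - tolerance) * min(others):
                    doomed.add(triple[i][0])
    return [(a, b, m) for a, b, m in edges if a != b and frozenset((a, b)) not in doomed]


def intervals_overlap(chrom_a, start_a, end_a, chrom_b, start_b, end_b) -> bool:
    """>=1 bp overlap on the same chromosome, by direct position check."""
    if chrom_a != chrom_b:
        return False
    return any(
        start_b <= pos < end_b for pos in range(start_a, end_a)
    )


def welch_t_direct(a, b) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va = a.var(ddof=1) / len(a)
    vb = b.var(ddof=1) / len(b)
    return (b.mean() - a.mean()) / np.sqrt(va + vb)


def permutation_p_exhaustive(a, b) -> float:
    """Two-sided permutation p of the Welch t by enumerating label splits."""
    pooled = np.concatenate([a, b])
    n = len(pooled)
    obs = abs(welch_t_direct(a, b))
    hits = total = 0
    for idx in combinations(range(n), len(b)):
        mask = np.zeros(n, bool)
        mask[list(idx)] = True
        t = welch_t_direct(pooled[~mask], pooled[mask])
        if not np.isfinite(t):
            t = 0.0
        total += 1
        if abs(t) >= obs - 1e-12:
            hits += 1
    return hits / total


def mi_from_table(counts) -> float:
    """Plug-in MI (nats) from a joint count table, by the definition."""
    counts = np.asarray(counts, float)
    n = counts.sum()
    p = counts / n
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    acc = 0.0
    for i in range(p.shape[0]):
        for j in range(p.shape[1]):
            if p[i, j] > 0:
                acc += p[i, j] * np.log(p[i, j] / (px[i] * py[j]))
    return acc
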