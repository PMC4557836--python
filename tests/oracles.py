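"""Independent brute-force oracles used by the test suite.

Each function here deliberately re-derives a quantity by the most direct
route available (explicit sums of squares, per-pair record loops, exhaustive
path enumeration) so the package implementations are checked against code
that shares none of their structure.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def anova_icc_oracle(table: np.ndarray) -> float:
    """ICC(A,1) from first principles: explicit two-way sums of squares."""
    table = np.asarray(table, dtype=float)
    n, k = table.shape
    grand = table.sum() / (n * k)
    ss_rows = 0.0
    for i in range(n):
        ss_rows += k * (table[i].mean() - grand) ** 2
    ss_cols = 0.0
    for j in range(k):
        ss_cols += n * (table[:, j].mean() - grand) ** 2
    ss_tot = 0.0
    for i in range(n):
        for j in range(k):
            ss_tot += (table[i, j] - grand) ** 2
    ss_err = ss_tot - ss_rows - ss_cols
    if ss_tot == 0:
        return float("nan")
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


def pairwise_build_oracle(fiber_set, roi_table) -> np.ndarray:
    """Recompute a connectivity matrix by looping over every ROI pair and
    every record independently of the builder's aggregation."""
    n = len(roi_table)
    surf = roi_table.surface_areas
    out = np.zeros((n, n))
    keys = roi_table.keys
    for i in range(n):
        for j in range(i + 1, n):
            ki, kj = keys[i], keys[j]
            if fiber_set.method == "deterministic":
                total = 0.0
                for r in fiber_set.records:
                    if {r.roi_a, r.roi_b} == {ki, kj}:
                        total += r.count / r.length
                w = 2.0 * total / (surf[i] + surf[j]) if total else 0.0
            else:
                mass_i = 0.0   # seeded at ROI i
                mass_j = 0.0
                for r in fiber_set.records:
                    if {r.roi_a, r.roi_b} != {ki, kj}:
                        continue
                    if r.direction == "undirected":
                        mass_i += r.count
                        mass_j += r.count
                        continue
                    seed = r.roi_a if r.direction == "a_seeded" else r.roi_b
                    if seed == ki:
                        mass_i += r.count
                    else:
                        mass_j += r.count
                w = 0.5 * (mass_i + mass_j) / (surf[i] + surf[j])
            out[i, j] = out[j, i] = w
    return out


def betweenness_enum_oracle(weights: np.ndarray) -> np.ndarray:
    """Betweenness by exhaustive simple-path enumeration.

    Edge length is 1/weight; all simple paths between each ordered pair are
    enumerated, geodesics identified up to a relative tolerance, and each
    interior node credited the fraction of geodesics through it.  Result is
    normalized by 2/((n-1)(n-2)).
    """
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    adj = [[j for j in range(n) if w[i, j] > 0] for i in range(n)]
    score = np.zeros(n)

    def simple_paths(s, t):
        stack = [(s, [s])]
        while stack:
            node, path = stack.pop()
            if node == t:
                yield path
                continue
            for nb in adj[node]:
                if nb not in path:
                    stack.append((nb, path + [nb]))

    for s, t in itertools.combinations(range(n), 2):
        paths = list(simple_paths(s, t))
        if not paths:
            continue
        lengths = [sum(1.0 / w[a, b] for a, b in zip(p[:-1], p[1:])) for p in paths]
        best = min(lengths)
        geos = [p for p, L in zip(paths, lengths) if math.isclose(L, best, rel_tol=1e-9)]
        for p in geos:
            for v in p[1:-1]:
                score[v] += 1.0 / len(geos)
    if n > 2:
        score *= 2.0 / ((n - 1) * (n - 2))
    return score


def clustering_triple_oracle(weights: np.ndarray) -> np.ndarray:
    """Onnela clustering by direct evaluation of the triple sum over ordered
    neighbor pairs, with global-max weight normalization."""
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    wmax = w.max()
    out = np.zeros(n)
    if wmax == 0:
        return out
    for i in range(n):
        nbrs = [j for j in range(n) if w[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        total = 0.0
        for j in nbrs:
            for h in nbrs:
                if j == h:
                    continue
                total += ((w[i, j] / wmax) * (w[i, h] / wmax) * (w[j, h] / wmax)) ** (1 / 3)
        out[i] = total / (k * (k - 1))
    return out
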