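"""Independent reference implementations used only by the tests.

Everything here is written with explicit loops and textbook formulas
(Floyd–Warshall, hand-coded Welch t and Pearson correlation, from-scratch
recomputation of every scoring quantity per node deletion) so that the
package's vectorized code paths are checked against genuinely independent
arithmetic.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps


def floyd_warshall(node_ids, edges):
    """All-pairs shortest path lengths by the classic triple loop."""
    n = len(node_ids)
    idx = {v: i for i, v in enumerate(node_ids)}
    d = [[math.inf] * n for _ in range(n)]
    for i in range(n):
        d[i][i] = 0.0
    for u, v in edges:
        d[idx[u]][idx[v]] = 1.0
        d[idx[v]][idx[u]] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return np.array(d)


def welch(a, b):
    """Welch two-sample t and two-sided p from the defining formulas."""
    a, b = list(map(float, a)), list(map(float, b))
    n1, n2 = len(a), len(b)
    m1, m2 = sum(a) / n1, sum(b) / n2
    v1 = sum((x - m1) ** 2 for x in a) / (n1 - 1)
    v2 = sum((x - m2) ** 2 for x in b) / (n2 - 1)
    se2 = v1 / n1 + v2 / n2
    if se2 == 0:
        return 0.0, 1.0
    t = (m1 - m2) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return t, p


def pearson(x, y):
    """Pearson correlation from sums of squares."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    if sxx == 0 or syy == 0:
        return 0.0
    return sxy / math.sqrt(sxx * syy)


def _stat_from_scratch(values, case_mask, node_ids, keep, edges, alpha_L, alpha_S, D, eps):
    """Pathway statistic on the node subset ``keep``, recomputing every
    quantity (distances, marginal tests, correlations, weights, reflected
    expression, activity, group statistic) from first principles."""
    kept = [n for n in node_ids if n in keep]
    sub_edges = [(u, v) for u, v in edges if u in keep and v in keep]
    d = floyd_warshall(kept, sub_edges)
    cols = {n: [values[i][node_ids.index(n)] for i in range(len(values))] for n in kept}
    cases = [i for i, c in enumerate(case_mask) if c]
    ctrls = [i for i, c in enumerate(case_mask) if not c]

    t, p, O = {}, {}, {}
    for n in kept:
        t[n], p[n] = welch([cols[n][i] for i in cases], [cols[n][i] for i in ctrls])
        O[n] = max(cols[n])

    lnum = {n: (-math.log(max(p[n], np.finfo(float).tiny)) if p[n] < alpha_L else 0.0) for n in kept}
    lsum = sum(lnum.values())
    L = {n: (lnum[n] / lsum if lsum > 0 else 0.0) for n in kept}

    raw = {}
    for j, nj in enumerate(kept):
        s = 0.0
        if p[nj] < alpha_S:
            for k, nk in enumerate(kept):
                if k != j and d[j][k] < D and math.isfinite(d[j][k]):
                    s += abs(pearson(cols[nj], cols[nk])) / d[j][k]
        raw[nj] = s
    rsum = sum(raw.values())
    S = {n: (raw[n] / rsum if rsum > 0 else 0.0) for n in kept}

    gR = {}
    for n in kept:
        if t[n] >= 0:
            gR[n] = cols[n]
        else:
            gR[n] = [O[n] - x + eps for x in cols[n]]

    M = len(kept)
    uniform = lsum <= 0 and rsum <= 0
    T = []
    for i in range(len(values)):
        tot = 0.0
        for n in kept:
            w = (1.0 / M) if uniform else (L[n] + S[n])
            tot += gR[n][i] * w
        T.append(tot)
    stat, _ = welch([T[i] for i in cases], [T[i] for i in ctrls])
    return stat


def loo_rank_oracle(values, case_mask, node_ids, edges, alpha_L=1.0, alpha_S=1.0,
                    D=math.inf, eps=0.001):
    """From-scratch leave-one-out influence scores Q_j for every node."""
    full = _stat_from_scratch(values, case_mask, node_ids, set(node_ids), edges,
                              alpha_L, alpha_S, D, eps)
    Q = {}
    t_loo = {}
    for j in node_ids:
        keep = set(node_ids) - {j}
        t_loo[j] = _stat_from_scratch(values, case_mask, node_ids, keep, edges,
                                      alpha_L, alpha_S, D, eps)
        Q[j] = abs(full - t_loo[j])
    return full, t_loo, Q


def random_instance(rng, M=None, N=None):
    """Random connected-ish network + expression + balanced labels."""
    M = M or int(rng.integers(3, 7))
    N = N or int(rng.integers(6, 13))
    if N % 2:
        N += 1
    node_ids = [f"g{i}" for i in range(M)]
    edges = [(node_ids[i], node_ids[i + 1]) for i in range(M - 1)]  # spanning chain
    for _ in range(int(rng.integers(0, M))):
        i, j = rng.choice(M, size=2, replace=False)
        u, v = sorted((node_ids[i], node_ids[j]))
        if (u, v) not in edges:
            edges.append((u, v))
    values = rng.normal(size=(N, M))
    case_mask = np.zeros(N, dtype=bool)
    case_mask[rng.choice(N, size=N // 2, replace=False)] = True
    return node_ids, edges, values, case_mask
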