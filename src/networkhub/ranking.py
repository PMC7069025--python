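"""Leave-one-out node influence ranking.

Each node's influence Q_j = |t_all - t_(-j)| measures how much the pathway
statistic moves when the node is deleted from the network and the whole
score — path lengths, both weight normalizations, the activity vector — is
rebuilt on the remaining M-1 nodes.  Marginal statistics (t_j, p_j, O_j) and
pairwise correlations are node-local or pairwise quantities that deleting a
third node cannot change, so they are computed once and reused; everything
the deletion can actually alter is recomputed.

Nodes are ranked by descending Q.  The influential-node cutoff is the first
position in the sorted sequence where the second difference
(Q_(j+1) - Q_(j)) - (Q_(j) - Q_(j-1)) turns negative; nodes ranked strictly
before it are called influential.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .network import PathwayNetwork, path_lengths
from .scoring import (
    ExpressionMatrix,
    PhenotypeLabels,
    ScoringConfig,
    _combine_weights,
    _log_numerators,
    _normalize,
    _topology_raw,
    _welch_stat,
    _welch_t,
    correlations,
    node_tests,
    regularize,
)

logger = logging.getLogger(__name__)

__all__ = ["RankingResult", "loo_rank", "inflection_cutoff", "ttest_rank", "permutation_pvalue"]


@dataclass(frozen=True)
class RankingResult:
    """Full output of the leave-one-out ranking.

    ``order`` lists node ids by descending influence Q (ties broken by
    larger degree, then input order); ``rank`` is the matching 1-based rank.
    ``cutoff_index`` is the 1-based scree-plot inflection position or None;
    ``influential`` holds the nodes ranked strictly before it.
    """

    node_ids: tuple[str, ...]
    t_all: float
    t_loo: dict[str, float]
    Q: dict[str, float]
    order: tuple[str, ...]
    rank: dict[str, int]
    cutoff_index: int | None
    influential: tuple[str, ...]
    degree: dict[str, int]
    p_value: dict[str, float]
    t_stat: dict[str, float]
    L: dict[str, float]
    S: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        """Ranking table, one row per node in rank order."""
        rows = []
        for n in self.order:
            rows.append(
                {
                    "node_id": n,
                    "degree": self.degree[n],
                    "p_value": self.p_value[n],
                    "t_stat": self.t_stat[n],
                    "L": self.L[n],
                    "S": self.S[n],
                    "t_loo": self.t_loo[n],
                    "Q": self.Q[n],
                    "rank": self.rank[n],
                    "influential": int(n in self.influential),
                }
            )
        return pd.DataFrame(rows)

    def scree_frame(self) -> pd.DataFrame:
        """Scree-plot data: rank, sorted Q, and -log10 p per ranked node."""
        return pd.DataFrame(
            {
                "rank": [self.rank[n] for n in self.order],
                "node_id": self.order,
                "Q": [self.Q[n] for n in self.order],
                "neg_log10_p": [-np.log10(max(self.p_value[n], np.finfo(float).tiny)) for n in self.order],
            }
        )


def _bfs_all(A: np.ndarray) -> np.ndarray:
    return shortest_path(csr_matrix(A), method="D", unweighted=True, directed=False)


def _subnet_stat(
    gR: np.ndarray,
    absrho: np.ndarray,
    lnum: np.ndarray,
    p: np.ndarray,
    keep: np.ndarray,
    dist: np.ndarray,
    m1: np.ndarray,
    m2: np.ndarray,
    cfg: ScoringConfig,
) -> float:
    """Pathway statistic on the node subset ``keep`` with distances ``dist``
    (already restricted to the subset), renormalizing both weight vectors."""
    L, _ = _normalize(lnum[keep])
    raw = _topology_raw(absrho[np.ix_(keep, keep)], dist, p[keep], cfg.alpha_S, cfg.D)
    S, _ = _normalize(raw)
    w = _combine_weights(L, S, warn=False)
    return _welch_stat(gR[:, keep] @ w, m1, m2)


def loo_rank(
    expr: ExpressionMatrix,
    labels: PhenotypeLabels,
    net: PathwayNetwork,
    cfg: ScoringConfig | None = None,
) -> RankingResult:
    """Rank nodes by the perturbation of the pathway statistic under
    leave-one-out node removal.

    For the full network, t_all is computed from the activity score built on
    all M nodes.  For each node j, the M-1 node subnetwork is formed, path
    lengths and both weight normalizations are recomputed, the activity
    vector is rebuilt on the remaining columns of the regularized
    expression, and t_(-j) and Q_j = |t_all - t_(-j)| follow.
    """
    cfg = cfg or ScoringConfig()
    if expr.node_ids != net.node_ids:
        raise ValueError("expression and network must share node order")
    M = net.M
    if M < 3:
        raise ValueError("leave-one-out ranking needs at least 3 nodes")

    stats = node_tests(expr, labels)
    corr = correlations(expr)
    absrho = np.abs(corr.rho)
    lnum = _log_numerators(stats.p, cfg.alpha_L)
    gR = regularize(expr, stats, cfg).values
    m1, m2 = labels.masks(expr.sample_ids)
    A = net.adjacency()
    dist_full = _bfs_all(A)

    all_idx = np.arange(M)
    t_full = _subnet_stat(gR, absrho, lnum, stats.p, all_idx, dist_full, m1, m2, cfg)
    L_full, _ = _normalize(lnum)
    S_full, _ = _normalize(
        _topology_raw(absrho, dist_full, stats.p, cfg.alpha_S, cfg.D)
    )

    t_loo = np.empty(M)
    for j in range(M):
        keep = np.delete(all_idx, j)
        dist_sub = _bfs_all(A[np.ix_(keep, keep)])
        t_loo[j] = _subnet_stat(gR, absrho, lnum, stats.p, keep, dist_sub, m1, m2, cfg)
    Q = np.abs(t_full - t_loo)

    deg = A.sum(axis=1).astype(int)
    order_idx = sorted(range(M), key=lambda j: (-Q[j], -deg[j], j))
    order = tuple(net.node_ids[j] for j in order_idx)
    rank = {n: r + 1 for r, n in enumerate(order)}
    sorted_Q = [float(Q[j]) for j in order_idx]
    cutoff = inflection_cutoff(sorted_Q)
    influential = order[: cutoff - 1] if cutoff is not None else ()

    ids = net.node_ids
    return RankingResult(
        node_ids=ids,
        t_all=t_full,
        t_loo={n: float(t_loo[j]) for j, n in enumerate(ids)},
        Q={n: float(Q[j]) for j, n in enumerate(ids)},
        order=order,
        rank=rank,
        cutoff_index=cutoff,
        influential=tuple(influential),
        degree={n: int(deg[j]) for j, n in enumerate(ids)},
        p_value={n: float(stats.p[j]) for j, n in enumerate(ids)},
        t_stat={n: float(stats.t[j]) for j, n in enumerate(ids)},
        L={n: float(L_full[j]) for j, n in enumerate(ids)},
        S={n: float(S_full[j]) for j, n in enumerate(ids)},
    )


def inflection_cutoff(sorted_Q) -> int | None:
    """First 1-based position j (2 <= j <= len-1) in the descending influence
    sequence where (Q_(j+1) - Q_(j)) - (Q_(j) - Q_(j-1)) < 0, i.e. where the
    scree curve bends downward; nodes ranked before it count as influential.
    Returns None when the curve never bends (or fewer than 3 values)."""
    q = list(sorted_Q)
    if len(q) < 3:
        logger.warning("need at least 3 influence values for a cutoff")
        return None
    for i in range(1, len(q) - 1):
        if (q[i + 1] - q[i]) - (q[i] - q[i - 1]) < 0:
            return i + 1
    return None


def ttest_rank(
    expr: ExpressionMatrix,
    labels: PhenotypeLabels,
    net: PathwayNetwork | None = None,
) -> tuple[str, ...]:
    """Comparator ranking: nodes sorted by ascending marginal Welch p-value.

    Ties are broken by larger degree first (when a network is supplied),
    then by input node order.
    """
    stats = node_tests(expr, labels)
    if net is not None:
        if expr.node_ids != net.node_ids:
            raise ValueError("expression and network must share node order")
        deg = net.degrees()
    else:
        deg = np.zeros(expr.M, dtype=int)
    order = sorted(range(expr.M), key=lambda j: (stats.p[j], -deg[j], j))
    return tuple(expr.node_ids[j] for j in order)


def permutation_pvalue(
    expr: ExpressionMatrix,
    labels: PhenotypeLabels,
    net: PathwayNetwork,
    cfg: ScoringConfig | None = None,
    B: int = 999,
    seed: int | None = None,
) -> float:
    """Label-permutation p-value for |t_all|.

    The phenotype labels are permuted B times; each permutation recomputes
    the node tests, the direction regularization, both weight vectors and
    the activity score from scratch (pairwise correlations and path lengths
    do not involve the labels and are reused).  The p-value is
    (1 + #{b : |t_all^(b)| >= |t_all|}) / (B + 1).
    """
    cfg = cfg or ScoringConfig()
    if B < 100:
        raise ValueError("use at least B=100 permutations")
    if expr.node_ids != net.node_ids:
        raise ValueError("expression and network must share node order")
    rng = np.random.default_rng(seed)
    dist = path_lengths(net).d
    absrho = np.abs(correlations(expr).rho)
    O = expr.values.max(axis=0)
    m1, _ = labels.masks(expr.sample_ids)
    n1 = int(m1.sum())
    N = expr.N

    def stat(mask1: np.ndarray) -> float:
        mask2 = ~mask1
        t, p = _welch_t(expr.values[mask1], expr.values[mask2])
        gR = expr.values.copy()
        neg = t < 0
        if np.any(neg):
            gR[:, neg] = O[neg] - gR[:, neg] + cfg.epsilon
        L, _ = _normalize(_log_numerators(p, cfg.alpha_L))
        S, _ = _normalize(_topology_raw(absrho, dist, p, cfg.alpha_S, cfg.D))
        w = _combine_weights(L, S, warn=False)
        return _welch_stat(gR @ w, mask1, mask2)

    observed = abs(stat(m1))
    count = 0
    for _ in range(B):
        perm = np.zeros(N, dtype=bool)
        perm[rng.choice(N, size=n1, replace=False)] = True
        if abs(stat(perm)) >= observed:
            count += 1
    return (1 + count) / (B + 1)
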