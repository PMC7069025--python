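"""Pathway activity scoring.

Per-sample pathway activity T_i is a weighted sum of direction-regularized
node expression, T_i = sum_j g^R_ij (L_j + S_j), where

* L_j is the local (marginal) weight: -log p_j for nodes passing the
  differential-expression gate p_j < alpha_L, normalized to sum 1;
* S_j is the topology weight: sum over partner nodes k of |rho_jk| / d_jk,
  restricted to path lengths d_jk < D and gated on the node's own p_j <
  alpha_S, again normalized to sum 1;
* g^R reflects expression columns whose two-sample t statistic is negative
  (O_j - g_ij + epsilon with O_j the observed column maximum) so that
  negatively associated nodes do not cancel in the sum.

The group difference in mean activity, standardized by the per-group
standard errors of the mean, is the pathway statistic t_all.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps

from .network import PathDistanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "PhenotypeLabels",
    "NodeStats",
    "CorrelationMatrix",
    "WeightVectors",
    "ScoringConfig",
    "PASVector",
    "node_tests",
    "local_weights",
    "correlations",
    "topology_weights",
    "regularize",
    "pas",
    "t_all",
]

_TINY = np.finfo(float).tiny


@dataclass(frozen=True)
class ExpressionMatrix:
    """N samples x M nodes of real-valued expression.

    ``node_ids`` must match the companion network's node order exactly
    wherever the two are used together.
    """

    values: np.ndarray
    sample_ids: tuple[str, ...]
    node_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("expression must be a 2-D samples x nodes matrix")
        if v.shape != (len(self.sample_ids), len(self.node_ids)):
            raise ValueError(
                f"shape {v.shape} does not match {len(self.sample_ids)} samples "
                f"x {len(self.node_ids)} nodes"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("expression contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def N(self) -> int:
        return len(self.sample_ids)

    @property
    def M(self) -> int:
        return len(self.node_ids)

    def subset_nodes(self, node_ids) -> "ExpressionMatrix":
        idx = [self.node_ids.index(n) for n in node_ids]
        return ExpressionMatrix(
            values=self.values[:, idx],
            sample_ids=self.sample_ids,
            node_ids=tuple(node_ids),
        )


@dataclass(frozen=True)
class PhenotypeLabels:
    """Binary phenotype per sample.

    ``levels`` fixes which label is grp1 (the first entry); the sign of every
    group-difference statistic is grp1 minus grp2.  By default levels follow
    first appearance in the mapping.
    """

    group: dict[str, str]
    levels: tuple[str, str] = ()

    def __post_init__(self) -> None:
        lv = self.levels or tuple(dict.fromkeys(self.group.values()))
        if len(lv) != 2:
            raise ValueError(f"exactly two group labels required, got {lv}")
        counts = {l: sum(1 for g in self.group.values() if g == l) for l in lv}
        if min(counts.values()) < 2:
            raise ValueError(f"each group needs >= 2 samples, got {counts}")
        object.__setattr__(self, "levels", tuple(lv))

    def masks(self, sample_ids) -> tuple[np.ndarray, np.ndarray]:
        """Boolean (grp1, grp2) masks aligned to ``sample_ids``."""
        g = np.array([self.group[s] for s in sample_ids])
        return g == self.levels[0], g == self.levels[1]

    def swapped(self) -> "PhenotypeLabels":
        return replace(self, levels=(self.levels[1], self.levels[0]))


@dataclass(frozen=True)
class NodeStats:
    """Per-node marginal statistics: Welch t, two-sided p, column maximum O."""

    node_ids: tuple[str, ...]
    t: np.ndarray
    p: np.ndarray
    O: np.ndarray


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pearson correlations of node expression across the pooled samples."""

    node_ids: tuple[str, ...]
    rho: np.ndarray


@dataclass(frozen=True)
class WeightVectors:
    """Local (L) and topology (S) weight vectors over the network's nodes.

    Each vector either sums to 1 or is all zero (its gate admitted no node),
    in which case the matching flag is set and downstream scoring falls back
    accordingly.
    """

    node_ids: tuple[str, ...]
    L: np.ndarray
    S: np.ndarray
    L_all_zero: bool = False
    S_all_zero: bool = False


@dataclass(frozen=True)
class ScoringConfig:
    """Tuning knobs of the activity score.

    alpha_L : p-value gate for the local weight (default 0.05).
    alpha_S : p-value gatekeeper for the topology weight (default 1, i.e.
        every node contributes regardless of marginal significance).
    D : strict upper bound on path lengths entering S_j; ``inf`` admits all
        connected pairs.
    epsilon : offset added when reflecting a column, keeping the reflected
        maximum strictly positive.
    log_base : base used when reporting raw -log p values.  L_j itself is
        base-invariant (the base rescales numerator and denominator alike),
        so this affects reporting only.
    """

    alpha_L: float = 0.05
    alpha_S: float = 1.0
    D: float = math.inf
    epsilon: float = 0.001
    log_base: float = math.e

    def __post_init__(self) -> None:
        if not (0 < self.alpha_L <= 1):
            raise ValueError("alpha_L must be in (0, 1]")
        if not (0 < self.alpha_S <= 1):
            raise ValueError("alpha_S must be in (0, 1]")
        if not (self.D >= 1):
            raise ValueError("D must be >= 1 (or infinity)")
        if not (self.epsilon > 0):
            raise ValueError("epsilon must be positive")
        if not (self.log_base > 1):
            raise ValueError("log_base must exceed 1")


@dataclass(frozen=True)
class PASVector:
    """Per-sample pathway activity scores."""

    sample_ids: tuple[str, ...]
    T: np.ndarray


# ---------------------------------------------------------------------------
# array-level kernels shared with the leave-one-out ranking loop
# ---------------------------------------------------------------------------

def _welch_t(a: np.ndarray, b: np.ndarray, axis: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Welch two-sample t and two-sided p; degenerate columns -> t=0, p=1."""
    with np.errstate(divide="ignore", invalid="ignore"):
        res = sps.ttest_ind(a, b, axis=axis, equal_var=False)
        t = np.asarray(res.statistic, dtype=float)
        p = np.asarray(res.pvalue, dtype=float)
    bad = ~np.isfinite(t)
    if np.any(bad):
        t = np.where(bad, 0.0, t)
        p = np.where(bad, 1.0, p)
    return t, p


def _welch_stat(T: np.ndarray, m1: np.ndarray, m2: np.ndarray) -> float:
    """Standardized group-mean difference (grp1 - grp2) / sqrt(se1^2 + se2^2)."""
    a, b = T[m1], T[m2]
    se2 = a.var(ddof=1) / a.size + b.var(ddof=1) / b.size
    if se2 == 0.0:
        logger.warning("both group variances are zero; statistic set to 0")
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(se2))


def _log_numerators(p: np.ndarray, alpha_L: float) -> np.ndarray:
    """-ln p gated at p < alpha_L; numerically-zero p clamped."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0):
        logger.warning("p-values of 0 clamped to the smallest positive float")
        p = np.clip(p, _TINY, None)
    return np.where(p < alpha_L, -np.log(p), 0.0)


def _normalize(raw: np.ndarray) -> tuple[np.ndarray, bool]:
    s = raw.sum()
    if s <= 0:
        return np.zeros_like(raw), True
    return raw / s, False


def _topology_raw(
    absrho: np.ndarray, d: np.ndarray, p: np.ndarray, alpha_S: float, D: float
) -> np.ndarray:
    """Unnormalized topology sums: sum_k |rho_jk|/d_jk over 0 < d_jk < D,
    zeroed for nodes failing the p_j < alpha_S gate."""
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where((d > 0) & (d < D), absrho / d, 0.0)
    return terms.sum(axis=1) * (p < alpha_S)


def _combine_weights(L: np.ndarray, S: np.ndarray, warn: bool = True) -> np.ndarray:
    if L.sum() == 0 and S.sum() == 0:
        if warn:
            logger.warning(
                "both weight vectors are all-zero; falling back to uniform 1/M"
            )
        return np.full_like(L, 1.0 / L.size)
    return L + S


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def node_tests(expr: ExpressionMatrix, labels: PhenotypeLabels) -> NodeStats:
    """Per-node Welch t statistic (grp1 minus grp2), two-sided p, and the
    column maximum O_j over all samples.

    Nodes with zero variance in both groups get t=0, p=1 with a warning.
    """
    m1, m2 = labels.masks(expr.sample_ids)
    t, p = _welch_t(expr.values[m1], expr.values[m2])
    if np.any((t == 0.0) & (p == 1.0)):
        degenerate = expr.values.std(axis=0) == 0
        if np.any(degenerate):
            logger.warning(
                "%d node(s) with zero variance: t set to 0, p to 1",
                int(degenerate.sum()),
            )
    return NodeStats(node_ids=expr.node_ids, t=t, p=p, O=expr.values.max(axis=0))


def local_weights(stats: NodeStats, cfg: ScoringConfig) -> np.ndarray:
    """Local weight vector L: normalized -log p over nodes with p < alpha_L.

    Returns the all-zero vector when no node passes the gate (the caller can
    detect this by summing; :func:`compute_weights` records it in a flag).
    """
    num = _log_numerators(stats.p, cfg.alpha_L)
    L, all_zero = _normalize(num)
    if all_zero:
        logger.warning("no node passes alpha_L=%g; L is all zero", cfg.alpha_L)
    return L


def correlations(expr: ExpressionMatrix) -> CorrelationMatrix:
    """Pearson correlations across the pooled samples (both groups).

    Zero-variance nodes get rho = 0 against every other node; the diagonal
    stays 1.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.corrcoef(expr.values, rowvar=False)
    rho = np.atleast_2d(rho)
    if np.any(~np.isfinite(rho)):
        logger.warning("zero-variance node(s): correlations set to 0")
        rho = np.where(np.isfinite(rho), rho, 0.0)
    np.fill_diagonal(rho, 1.0)
    return CorrelationMatrix(node_ids=expr.node_ids, rho=rho)


def topology_weights(
    corr: CorrelationMatrix,
    dist: PathDistanceMatrix,
    stats: NodeStats,
    cfg: ScoringConfig,
) -> np.ndarray:
    """Topology weight vector S.

    Each node j accumulates |rho_jk| / d_jk over partners k with path length
    strictly below D; the whole sum is zeroed unless the node's own marginal
    p-value passes the alpha_S gatekeeper.  Disconnected pairs (d infinite)
    contribute nothing.  The vector is normalized to sum 1; all-zero when
    every gate closes.
    """
    if corr.node_ids != dist.node_ids or corr.node_ids != stats.node_ids:
        raise ValueError("correlation, distance and node stats must share node order")
    raw = _topology_raw(np.abs(corr.rho), dist.d, stats.p, cfg.alpha_S, cfg.D)
    S, all_zero = _normalize(raw)
    if all_zero:
        logger.warning("topology gates admit no node; S is all zero")
    return S


def compute_weights(
    corr: CorrelationMatrix,
    dist: PathDistanceMatrix,
    stats: NodeStats,
    cfg: ScoringConfig,
) -> WeightVectors:
    """Convenience: both weight vectors with their all-zero flags."""
    L = local_weights(stats, cfg)
    S = topology_weights(corr, dist, stats, cfg)
    return WeightVectors(
        node_ids=stats.node_ids,
        L=L,
        S=S,
        L_all_zero=bool(L.sum() == 0),
        S_all_zero=bool(S.sum() == 0),
    )


def regularize(
    expr: ExpressionMatrix, stats: NodeStats, cfg: ScoringConfig
) -> ExpressionMatrix:
    """Direction regularization g^R.

    Columns whose t statistic is negative are reflected about their observed
    maximum, g^R_ij = O_j - g_ij + epsilon, so that higher activity always
    points the same way; columns with t >= 0 pass through unchanged.
    """
    if expr.node_ids != stats.node_ids:
        raise ValueError("expression and node stats must share node order")
    g = expr.values.copy()
    neg = stats.t < 0
    if np.any(neg):
        g[:, neg] = stats.O[neg] - g[:, neg] + cfg.epsilon
    return ExpressionMatrix(values=g, sample_ids=expr.sample_ids, node_ids=expr.node_ids)


def pas(reg_expr: ExpressionMatrix, weights: WeightVectors) -> PASVector:
    """Pathway activity score T_i = sum_j g^R_ij (L_j + S_j).

    If both weight vectors are all-zero the score falls back to uniform
    weights 1/M (with a warning); if only one is all-zero the other alone
    carries the score.
    """
    if reg_expr.node_ids != weights.node_ids:
        raise ValueError("expression and weights must share node order")
    w = _combine_weights(weights.L, weights.S)
    return PASVector(sample_ids=reg_expr.sample_ids, T=reg_expr.values @ w)


def t_all(pas_vec: PASVector, labels: PhenotypeLabels) -> float:
    """Standardized difference in mean activity between the two groups,
    (mean_grp1 - mean_grp2) / sqrt(se_grp1^2 + se_grp2^2), where each se is
    the group standard deviation over the square root of the group size.
    Returns 0 with a warning when both group variances vanish.
    """
    m1, m2 = labels.masks(pas_vec.sample_ids)
    return _welch_stat(pas_vec.T, m1, m2)
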