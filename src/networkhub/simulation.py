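"""Simulation study: synthetic pathway, correlated expression, logit disease
model, and ranking-performance metrics.

The study emulates a 32-node pathway with two high-degree hubs (prototype of
a JAK-STAT-sized signaling network, where the central transcription-factor
node reaches degree 17).  Expression is multivariate normal with correlation
decaying in path length (rho0**d_jk), so directly interacting nodes are the
most correlated — the feature the topology weight S_j is built to exploit.
Disease status follows a logistic model logit(p_i) = beta0 + sum_j beta_j
G_ij over the causal nodes; subjects are drawn from a pool until exact
case/control quotas are met.

Four scenarios vary the causal effect sizes:

=========  ==========  =========  ==============  =============
Scenario   causal hubs  beta_hub  causal non-hubs  beta_nonhub
=========  ==========  =========  ==============  =============
A          2            1.0       8                0.1
B          2            0.5       8                0.1
C          2            0.1       8                0.1
D          0            0         0                0
=========  ==========  =========  ==============  =============

Rankings are scored by the hub ranking rate (HRR: fraction of replications
placing at least one designated hub in the top x), the false discovery rate
among the top x, and the true detection rate of causal nodes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .network import HubAnnotation, PathwayNetwork, annotate_hubs, build_network, path_lengths
from .ranking import loo_rank, ttest_rank
from .scoring import ExpressionMatrix, PhenotypeLabels, ScoringConfig

logger = logging.getLogger(__name__)

__all__ = [
    "SCENARIO_TABLE",
    "SimulationScenario",
    "SyntheticNetworkSpec",
    "EvaluationMetrics",
    "make_prototype_network",
    "simulate_expression",
    "assign_disease",
    "hub_ranking_rate",
    "chance_hrr",
    "fdr_tdr",
    "run_study",
]

#: (n_causal_hubs, beta_hub, n_causal_nonhubs, beta_nonhub) per scenario
SCENARIO_TABLE: dict[str, tuple[int, float, int, float]] = {
    "A": (2, 1.0, 8, 0.1),
    "B": (2, 0.5, 8, 0.1),
    "C": (2, 0.1, 8, 0.1),
    "D": (0, 0.0, 0, 0.0),
}


@dataclass(frozen=True)
class SyntheticNetworkSpec:
    """Shape of the synthetic pathway and its expression generator.

    M : total node count (default 32).
    hub_degrees : target degree of each designated hub, largest first; the
        defaults echo a signaling pathway whose central node has degree 17
        and whose secondary hub is well connected.
    rho0 : base of the distance-decaying target correlation rho0**d_jk.
    noise_sd : marginal standard deviation of expression.
    """

    M: int = 32
    hub_degrees: tuple[int, ...] = (17, 8)
    rho0: float = 0.4
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.rho0 < 1):
            raise ValueError("rho0 must be in [0, 1)")
        if self.M < 4:
            raise ValueError("M must be >= 4")
        if len(self.hub_degrees) < 2 or any(d < 3 for d in self.hub_degrees):
            raise ValueError("need at least 2 hubs of degree >= 3")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass(frozen=True)
class SimulationScenario:
    """One scenario of the ranking study.

    Causal node identities are resolved against a concrete network by
    :meth:`resolve`; ``designated_hub_ids`` are tracked by the HRR in every
    scenario, including the null scenario D where nothing is causal.
    """

    scenario_id: str
    n_causal_hubs: int
    beta_hub: float
    n_causal_nonhubs: int
    beta_nonhub: float
    designated_hub_ids: tuple[str, ...] = ()
    causal_hub_ids: tuple[str, ...] = ()
    causal_nonhub_ids: tuple[str, ...] = ()
    n_cases: int = 50
    n_controls: int = 50
    replications: int = 1000
    base_seed: int = 0
    beta0: float = 0.0

    @classmethod
    def from_id(cls, scenario_id: str, **kwargs) -> "SimulationScenario":
        try:
            nh, bh, nn, bn = SCENARIO_TABLE[scenario_id.upper()]
        except KeyError:
            raise ValueError(f"unknown scenario {scenario_id!r}; choose from A-D")
        return cls(
            scenario_id=scenario_id.upper(),
            n_causal_hubs=nh,
            beta_hub=bh,
            n_causal_nonhubs=nn,
            beta_nonhub=bn,
            **kwargs,
        )

    def resolve(
        self,
        net: PathwayNetwork,
        hubs: HubAnnotation,
        rng: np.random.Generator,
    ) -> "SimulationScenario":
        """Pin designated hubs (the highest-degree hub nodes) and draw the
        causal non-hub nodes uniformly among degree <= 2 nodes."""
        ranked_hubs = sorted(hubs.hubs, key=lambda n: (-hubs.degree[n], n))
        n_designated = max(self.n_causal_hubs, 2)
        designated = tuple(ranked_hubs[:n_designated])
        if len(designated) < n_designated:
            raise ValueError("network has fewer hubs than the scenario designates")
        causal_hubs = designated[: self.n_causal_hubs]
        nonhub_pool = sorted(n for n in net.node_ids if hubs.degree[n] <= 2)
        if self.n_causal_nonhubs > len(nonhub_pool):
            raise ValueError("not enough non-hub nodes for the scenario")
        causal_nonhubs = tuple(
            sorted(rng.choice(nonhub_pool, size=self.n_causal_nonhubs, replace=False))
        )
        return replace(
            self,
            designated_hub_ids=designated,
            causal_hub_ids=causal_hubs,
            causal_nonhub_ids=causal_nonhubs,
        )

    @property
    def causal_ids(self) -> tuple[str, ...]:
        return self.causal_hub_ids + self.causal_nonhub_ids

    @property
    def betas(self) -> tuple[float, ...]:
        return (self.beta_hub,) * self.n_causal_hubs + (
            self.beta_nonhub,
        ) * self.n_causal_nonhubs


@dataclass
class EvaluationMetrics:
    """Study-level metrics, each a mean over replications.

    hrr/fdr/tdr: method -> decision point x -> rate (TDR is None when the
    scenario has no causal node).
    """

    scenario_id: str
    decision_points: tuple[int, ...]
    replications: int
    hrr: dict[str, dict[int, float]]
    fdr: dict[str, dict[int, float]]
    tdr: dict[str, dict[int, float | None]]
    designated_hub_ids: tuple[str, ...] = ()
    causal_ids: tuple[str, ...] = ()
    rank_lists: dict[str, list[tuple[str, ...]]] = field(default_factory=dict)


def make_prototype_network(
    spec: SyntheticNetworkSpec | None = None, seed: int | None = None
) -> tuple[PathwayNetwork, HubAnnotation]:
    """Deterministic synthetic pathway: designated hubs of the requested
    degrees chained together, leaf nodes attached to meet each hub's degree,
    and the remaining nodes strung onto leaves as pendant chains so every
    non-hub keeps degree <= 2 and the graph stays connected.

    The construction is fully deterministic; ``seed`` is accepted for
    interface symmetry with the stochastic generators.
    """
    spec = spec or SyntheticNetworkSpec()
    n_hubs = len(spec.hub_degrees)
    hub_ids = [f"H{i + 1:02d}" for i in range(n_hubs)]
    other_ids = [f"N{i + 1:02d}" for i in range(spec.M - n_hubs)]
    edges: list[tuple[str, str]] = []
    degree: dict[str, int] = {n: 0 for n in hub_ids + other_ids}

    def add_edge(u: str, v: str) -> None:
        edges.append((u, v))
        degree[u] += 1
        degree[v] += 1

    for a, b in zip(hub_ids, hub_ids[1:]):
        add_edge(a, b)
    pool = iter(other_ids)
    for h, target in zip(hub_ids, spec.hub_degrees):
        while degree[h] < target:
            try:
                leaf = next(pool)
            except StopIteration:
                raise ValueError(
                    f"degree sequence infeasible: {spec.M} nodes cannot supply "
                    f"hub degrees {spec.hub_degrees}"
                )
            add_edge(h, leaf)
    leftovers = list(pool)
    attach_points = [n for n in other_ids if degree[n] == 1]
    if leftovers and not attach_points:
        raise ValueError("no attachment points for leftover nodes")
    k = 0
    for node in leftovers:
        while degree[attach_points[k % len(attach_points)]] >= 2:
            k += 1
        add_edge(attach_points[k % len(attach_points)], node)
        attach_points.append(node)
        k += 1

    net = build_network(edges)
    hubs = annotate_hubs(net)
    extra = hubs.hubs - set(hub_ids)
    if extra:
        raise AssertionError(f"construction produced unplanned hubs: {extra}")
    return net, hubs


def _target_correlation(net: PathwayNetwork, rho0: float) -> np.ndarray:
    """rho0**d_jk (0 for disconnected pairs), projected to the nearest
    positive semidefinite matrix with unit diagonal if needed."""
    d = path_lengths(net).d
    with np.errstate(over="ignore"):
        R = np.where(np.isfinite(d), rho0**d, 0.0)
    np.fill_diagonal(R, 1.0)
    w = np.linalg.eigvalsh(R)
    if w[0] < -1e-10:
        logger.info("target correlation not PSD (min eig %.3g); projecting", w[0])
        w, V = np.linalg.eigh(R)
        R = (V * np.clip(w, 0.0, None)) @ V.T
        s = np.sqrt(np.diag(R))
        R = R / np.outer(s, s)
        np.fill_diagonal(R, 1.0)
    return R


def _chol(R: np.ndarray) -> np.ndarray:
    jitter = 0.0
    for _ in range(6):
        try:
            return np.linalg.cholesky(R + jitter * np.eye(len(R)))
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10, 1e-12)
    raise np.linalg.LinAlgError("correlation matrix is not positive definite")


def simulate_expression(
    net: PathwayNetwork,
    spec: SyntheticNetworkSpec | None = None,
    n_pool: int = 400,
    seed: int | None = None,
    _chol_cache: np.ndarray | None = None,
) -> ExpressionMatrix:
    """Draw ``n_pool`` samples of zero-mean expression whose correlation
    between nodes j and k targets rho0**d_jk and whose marginal standard
    deviation is ``noise_sd``."""
    spec = spec or SyntheticNetworkSpec()
    C = _chol_cache if _chol_cache is not None else _chol(_target_correlation(net, spec.rho0))
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n_pool, net.M))
    X = (Z @ C.T) * spec.noise_sd
    sample_ids = tuple(f"S{i + 1:05d}" for i in range(n_pool))
    return ExpressionMatrix(values=X, sample_ids=sample_ids, node_ids=net.node_ids)


def assign_disease(
    expr: ExpressionMatrix,
    scenario: SimulationScenario,
    seed: int | None = None,
    extend_pool=None,
) -> tuple[PhenotypeLabels, ExpressionMatrix]:
    """Draw disease status from logit(p_i) = beta0 + sum_j beta_j G_ij on
    column-standardized expression, then walk the pool retaining subjects
    until exactly ``n_cases`` cases and ``n_controls`` controls are held.

    Returns the labels (levels ("case", "control"), so t statistics are
    case minus control) together with the retained expression rows.  If the
    pool runs out before the quotas fill, ``extend_pool(n)`` is called to
    fetch n more samples (the pool grows geometrically); without such a
    callback, exhaustion raises.
    """
    rng = np.random.default_rng(seed)
    causal_idx = [expr.node_ids.index(n) for n in scenario.causal_ids]
    beta = np.asarray(scenario.betas)

    kept_rows: list[np.ndarray] = []
    kept_labels: list[str] = []
    cases = controls = 0
    pool = expr
    offset = 0
    while cases < scenario.n_cases or controls < scenario.n_controls:
        if offset >= pool.N:
            grow = pool.N  # geometric growth
            if extend_pool is None:
                raise RuntimeError(
                    f"pool of {pool.N} exhausted with {cases}/{scenario.n_cases} cases "
                    f"and {controls}/{scenario.n_controls} controls; provide extend_pool"
                )
            logger.warning("subject pool exhausted; drawing %d more samples", grow)
            extra = extend_pool(grow)
            pool = ExpressionMatrix(
                values=np.vstack([pool.values, extra.values]),
                sample_ids=pool.sample_ids + tuple(f"X{offset + i:06d}" for i in range(extra.N)),
                node_ids=pool.node_ids,
            )
        # standardize the visible pool once per growth step
        mu = pool.values.mean(axis=0)
        sd = pool.values.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Z = (pool.values - mu) / sd
        eta = scenario.beta0 + (
            Z[:, causal_idx] @ beta if causal_idx else np.zeros(pool.N)
        )
        status = rng.random(pool.N - offset) < expit(eta[offset:])
        for i, is_case in enumerate(status, start=offset):
            if is_case and cases < scenario.n_cases:
                kept_rows.append(pool.values[i])
                kept_labels.append("case")
                cases += 1
            elif not is_case and controls < scenario.n_controls:
                kept_rows.append(pool.values[i])
                kept_labels.append("control")
                controls += 1
            if cases >= scenario.n_cases and controls >= scenario.n_controls:
                break
        offset = pool.N if (cases < scenario.n_cases or controls < scenario.n_controls) else offset

    n = len(kept_rows)
    sample_ids = tuple(f"P{i + 1:04d}" for i in range(n))
    retained = ExpressionMatrix(
        values=np.vstack(kept_rows), sample_ids=sample_ids, node_ids=expr.node_ids
    )
    labels = PhenotypeLabels(
        group=dict(zip(sample_ids, kept_labels)), levels=("case", "control")
    )
    return labels, retained


def hub_ranking_rate(
    rank_lists, hubs, x: int, literal_count: bool = False
) -> float:
    """Hub ranking rate at decision point x.

    Default semantics: the fraction of replications in which at least one
    designated hub appears among the top x ranked nodes — the reading whose
    chance level matches the closed form :func:`chance_hrr`.  With
    ``literal_count=True`` the per-replication count of designated hubs in
    the top x divided by x is averaged instead.
    """
    if x < 1:
        raise ValueError("x must be >= 1")
    hubs = set(hubs)
    if not hubs:
        raise ValueError("need at least one designated hub")
    vals = []
    for order in rank_lists:
        top = set(order[:x])
        hit = len(top & hubs)
        vals.append(hit / x if literal_count else float(hit > 0))
    return float(np.mean(vals))


def chance_hrr(M: int, H: int, x: int) -> float:
    """Probability that a uniformly random ranking of M nodes places at
    least one of H designated hubs in the top x: 1 - C(M-H, x) / C(M, x)."""
    if not (1 <= H <= M):
        raise ValueError("need 1 <= H <= M")
    if not (1 <= x <= M):
        raise ValueError("need 1 <= x <= M")
    if x > M - H:
        return 1.0
    return 1.0 - math.comb(M - H, x) / math.comb(M, x)


def fdr_tdr(rank_list, causal_set, x: int) -> tuple[float, float | None]:
    """Per-replication false discovery rate and true detection rate among
    the leading x nodes.  With no causal node (null scenario) every
    discovery is false (FDR = 1) and TDR is undefined (None)."""
    if x < 1:
        raise ValueError("x must be >= 1")
    causal = set(causal_set)
    top = list(rank_list[:x])
    hits = sum(1 for n in top if n in causal)
    fdr = (len(top) - hits) / x
    tdr = hits / len(causal) if causal else None
    return fdr, tdr


def run_study(
    scenario: SimulationScenario | str,
    spec: SyntheticNetworkSpec | None = None,
    methods: tuple[str, ...] = ("networkhub", "ttest"),
    reps: int | None = None,
    cfg: ScoringConfig | None = None,
    seed: int = 0,
    decision_points: tuple[int, ...] = (3,),
    n_pool: int = 400,
    collect_ranks: bool = False,
) -> EvaluationMetrics:
    """Run the full simulation study for one scenario.

    Per replication r (seeded from ``(seed, r)``): draw an expression pool,
    assign disease status and retain the case/control quota, then run each
    requested ranker and score it.  The causal non-hub nodes are drawn once
    per study from ``(seed,)``.  Metrics are means over replications.
    """
    spec = spec or SyntheticNetworkSpec()
    cfg = cfg or ScoringConfig()
    if reps is not None and reps < 1:
        raise ValueError("reps must be >= 1")
    unknown = set(methods) - {"networkhub", "ttest"}
    if unknown:
        raise ValueError(f"unknown method(s): {sorted(unknown)}")

    net, hubs = make_prototype_network(spec, seed)
    if isinstance(scenario, str):
        scenario = SimulationScenario.from_id(scenario, base_seed=seed)
    if not scenario.designated_hub_ids:
        scenario = scenario.resolve(net, hubs, np.random.default_rng([seed, 0]))
    reps = reps if reps is not None else scenario.replications

    chol = _chol(_target_correlation(net, spec.rho0))
    designated = set(scenario.designated_hub_ids)
    causal = set(scenario.causal_ids)

    hit = {m: {x: 0 for x in decision_points} for m in methods}
    fdr_sum = {m: {x: 0.0 for x in decision_points} for m in methods}
    tdr_sum = {m: {x: 0.0 for x in decision_points} for m in methods}
    ranks_out: dict[str, list[tuple[str, ...]]] = {m: [] for m in methods}

    for r in range(reps):
        rng = np.random.default_rng([seed, r + 1])
        pool = simulate_expression(
            net, spec, n_pool=n_pool, seed=rng, _chol_cache=chol
        )
        labels, exprs = assign_disease(
            expr=pool,
            scenario=scenario,
            seed=rng,
            extend_pool=lambda n: simulate_expression(
                net, spec, n_pool=n, seed=rng, _chol_cache=chol
            ),
        )
        for m in methods:
            if m == "networkhub":
                order = loo_rank(exprs, labels, net, cfg).order
            else:
                order = ttest_rank(exprs, labels, net)
            if collect_ranks:
                ranks_out[m].append(order)
            for x in decision_points:
                if set(order[:x]) & designated:
                    hit[m][x] += 1
                f, t = fdr_tdr(order, causal, x)
                fdr_sum[m][x] += f
                if t is not None:
                    tdr_sum[m][x] += t

    hrr = {m: {x: hit[m][x] / reps for x in decision_points} for m in methods}
    fdr = {m: {x: fdr_sum[m][x] / reps for x in decision_points} for m in methods}
    tdr = {
        m: {
            x: (tdr_sum[m][x] / reps if causal else None)
            for x in decision_points
        }
        for m in methods
    }
    return EvaluationMetrics(
        scenario_id=scenario.scenario_id,
        decision_points=tuple(decision_points),
        replications=reps,
        hrr=hrr,
        fdr=fdr,
        tdr=tdr,
        designated_hub_ids=scenario.designated_hub_ids,
        causal_ids=tuple(scenario.causal_ids),
        rank_lists=ranks_out if collect_ranks else {},
    )
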