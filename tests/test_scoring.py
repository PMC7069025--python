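import math

import numpy as np
import pytest

from networkhub import (
    CorrelationMatrix,
    ExpressionMatrix,
    NodeStats,
    PhenotypeLabels,
    ScoringConfig,
    WeightVectors,
    build_network,
    compute_weights,
    correlations,
    local_weights,
    node_tests,
    pas,
    path_lengths,
    regularize,
    t_all,
    topology_weights,
)

from _oracles import welch
from conftest import make_labels


def expr_of(values, prefix="s"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values=values,
        sample_ids=tuple(f"{prefix}{i}" for i in range(values.shape[0])),
        node_ids=tuple(f"g{j}" for j in range(values.shape[1])),
    )


def stats_of(t, p, O=None):
    t = np.asarray(t, float)
    return NodeStats(
        node_ids=tuple(f"g{j}" for j in range(t.size)),
        t=t,
        p=np.asarray(p, float),
        O=np.asarray(O, float) if O is not None else np.ones_like(t),
    )


class TestNodeTests:
    def test_zero_variance_degenerate_rule(self):
        _, labels = make_labels(2, 2)
        expr = expr_of([[1.0], [1.0], [1.0], [1.0]])
        st = node_tests(expr, labels)
        assert st.t[0] == 0.0 and st.p[0] == 1.0

    def test_equal_means_positive_variance(self):
        _, labels = make_labels(2, 2)
        expr = expr_of([[1.0], [3.0], [3.0], [1.0]])
        st = node_tests(expr, labels)
        assert st.t[0] == pytest.approx(0.0)
        assert st.p[0] == pytest.approx(1.0)

    def test_matches_hand_welch(self):
        _, labels = make_labels(3, 3)
        expr = expr_of([[3.0], [4.0], [5.0], [0.0], [1.0], [2.0]])
        st = node_tests(expr, labels)
        t_ref, p_ref = welch([3, 4, 5], [0, 1, 2])
        assert st.t[0] == pytest.approx(t_ref)
        assert st.p[0] == pytest.approx(p_ref)
        assert st.t[0] > 0

    def test_O_is_column_max(self):
        _, labels = make_labels(2, 2)
        expr = expr_of([[1.0, -2.0], [7.0, 0.5], [2.0, 0.0], [3.0, -1.0]])
        st = node_tests(expr, labels)
        assert np.array_equal(st.O, [7.0, 0.5])


class TestLocalWeights:
    def test_single_included_node_takes_all(self):
        L = local_weights(stats_of([1, 1], [0.01, 0.5]), ScoringConfig())
        assert np.allclose(L, [1.0, 0.0])

    def test_hand_computed_three_nodes(self):
        L = local_weights(stats_of([1, 1, 1], [0.01, 0.5, 0.04]), ScoringConfig())
        # -ln 0.01 = 4.6052, -ln 0.04 = 3.2189, sum = 7.8240
        assert L == pytest.approx([0.58859, 0.0, 0.41141], abs=1e-4)

    def test_nothing_passes_gives_all_zero(self):
        L = local_weights(stats_of([1, 1], [0.5, 0.9]), ScoringConfig())
        assert np.all(L == 0)

    def test_zero_pvalue_is_clamped_finite(self):
        L = local_weights(stats_of([1, 1], [0.0, 0.01]), ScoringConfig())
        assert np.all(np.isfinite(L)) and L.sum() == pytest.approx(1.0)

    def test_fisher_statistic_relation_when_gate_open(self):
        # with alpha_L = 1, the unnormalized numerators sum to half of
        # Fisher's combined statistic -2 * sum(ln p)
        p = np.array([0.02, 0.3, 0.77, 0.11])
        from networkhub.scoring import _log_numerators

        num = _log_numerators(p, 1.0)
        assert num.sum() == pytest.approx(0.5 * (-2 * np.log(p).sum()))


class TestCorrelations:
    def test_diagonal_and_affine_partner(self):
        rng = np.random.default_rng(0)
        g = rng.normal(size=12)
        expr = expr_of(np.column_stack([g, 2 * g + 1]))
        rho = correlations(expr).rho
        assert rho[0, 0] == pytest.approx(1.0)
        assert rho[0, 1] == pytest.approx(1.0)

    def test_independent_nodes_near_zero(self):
        rng = np.random.default_rng(1)
        expr = expr_of(rng.normal(size=(1000, 2)))
        rho = correlations(expr).rho
        assert abs(rho[0, 1]) < 0.1

    def test_zero_variance_node_gets_zero(self):
        rng = np.random.default_rng(2)
        vals = np.column_stack([np.full(8, 3.0), rng.normal(size=8)])
        rho = correlations(expr_of(vals)).rho
        assert rho[0, 1] == 0.0 and rho[0, 0] == 1.0


class TestTopologyWeights:
    @staticmethod
    def _chain_inputs():
        net = build_network([("g0", "g1"), ("g1", "g2")])
        dist = path_lengths(net)
        rho = np.array([[1.0, 0.5, 0.25], [0.5, 1.0, 0.5], [0.25, 0.5, 1.0]])
        corr = CorrelationMatrix(node_ids=net.node_ids, rho=rho)
        st = stats_of([1, 1, 1], [0.5, 0.5, 0.5])
        return corr, dist, st

    def test_hand_computed_chain(self):
        corr, dist, st = self._chain_inputs()
        S = topology_weights(corr, dist, st, ScoringConfig(alpha_S=1.0))
        # raw = (0.625, 1.0, 0.625), sum 2.25
        assert S == pytest.approx([0.27778, 0.44444, 0.27778], abs=1e-4)

    def test_strict_distance_bound_excludes_boundary(self):
        corr, dist, st = self._chain_inputs()
        S = topology_weights(corr, dist, st, ScoringConfig(alpha_S=1.0, D=2))
        # the g0-g2 pair sits at d = 2 and the bound is strict, so raw = (0.5, 1, 0.5)
        assert S == pytest.approx([0.25, 0.5, 0.25])

    def test_gatekeeper_closes_everything(self):
        corr, dist, st = self._chain_inputs()
        S = topology_weights(corr, dist, st, ScoringConfig(alpha_S=0.05))
        assert np.all(S == 0)

    def test_sign_of_correlation_is_irrelevant(self):
        corr, dist, st = self._chain_inputs()
        flipped = CorrelationMatrix(node_ids=corr.node_ids, rho=-corr.rho)
        a = topology_weights(corr, dist, st, ScoringConfig())
        b = topology_weights(flipped, dist, st, ScoringConfig())
        assert np.allclose(a, b)

    def test_widening_D_never_shrinks_inclusion(self):
        corr, dist, st = self._chain_inputs()
        from networkhub.scoring import _topology_raw

        raw2 = _topology_raw(np.abs(corr.rho), dist.d, st.p, 1.0, 2)
        raw4 = _topology_raw(np.abs(corr.rho), dist.d, st.p, 1.0, 4)
        assert np.all(raw4 >= raw2)

    def test_misaligned_nodes_rejected(self):
        corr, dist, st = self._chain_inputs()
        bad = CorrelationMatrix(node_ids=("x", "y", "z"), rho=corr.rho)
        with pytest.raises(ValueError):
            topology_weights(bad, dist, st, ScoringConfig())


class TestWeightNormalization:
    def test_both_vectors_sum_to_one_when_nondegenerate(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            M = int(rng.integers(3, 7))
            ids = [f"g{j}" for j in range(M)]
            net = build_network([(ids[i], ids[i + 1]) for i in range(M - 1)])
            _, labels = make_labels(4, 4)
            expr = ExpressionMatrix(
                values=rng.normal(size=(8, M)),
                sample_ids=tuple(labels.group),
                node_ids=net.node_ids,
            )
            st = node_tests(expr, labels)
            w = compute_weights(
                correlations(expr), path_lengths(net), st, ScoringConfig(alpha_L=1.0)
            )
            if not w.L_all_zero:
                assert abs(w.L.sum() - 1.0) < 1e-12
            if not w.S_all_zero:
                assert abs(w.S.sum() - 1.0) < 1e-12
            assert np.all(w.L >= 0) and np.all(w.S >= 0)


class TestRegularize:
    def test_nonnegative_t_passes_through(self):
        expr = expr_of([[2.0], [5.0], [3.0], [1.0]])
        out = regularize(expr, stats_of([0.7], [0.5], O=[5.0]), ScoringConfig())
        assert np.array_equal(out.values, expr.values)

    def test_reflection_formula(self):
        expr = expr_of([[2.0], [5.0], [3.0]], prefix="r")
        out = regularize(expr, stats_of([-2.0], [0.01], O=[5.0]), ScoringConfig())
        assert np.allclose(out.values[:, 0], [3.001, 0.001, 2.001])

    def test_reflected_column_has_nonnegative_t(self):
        rng = np.random.default_rng(8)
        _, labels = make_labels(5, 5)
        vals = rng.normal(size=(10, 3))
        vals[5:, 1] += 3.0  # control-high node -> negative t
        expr = expr_of(vals)
        st = node_tests(expr, labels)
        assert st.t[1] < 0
        reg = regularize(expr, st, ScoringConfig())
        st2 = node_tests(reg, labels)
        assert np.all(st2.t >= 0)


class TestPas:
    @staticmethod
    def _wv(L, S, ids):
        L, S = np.asarray(L, float), np.asarray(S, float)
        return WeightVectors(
            node_ids=ids, L=L, S=S,
            L_all_zero=bool(L.sum() == 0), S_all_zero=bool(S.sum() == 0),
        )

    def test_weight_mask(self):
        expr = expr_of([[7.0, 99.0], [1.0, 2.0], [0.0, 1.0], [2.0, 5.0]])
        v = pas(expr, self._wv([1, 0], [0, 0], expr.node_ids))
        assert v.T[0] == pytest.approx(7.0)

    def test_unit_total_weight(self):
        expr = expr_of([[2.0, 4.0], [1.0, 1.0], [0.0, 0.0], [1.0, 2.0]])
        v = pas(expr, self._wv([0.5, 0.5], [0.5, 0.5], expr.node_ids))
        assert v.T[0] == pytest.approx(6.0)

    def test_matches_double_loop(self):
        rng = np.random.default_rng(9)
        g = rng.normal(size=(4, 3))
        L = np.array([0.2, 0.3, 0.5])
        S = np.array([0.1, 0.6, 0.3])
        expr = expr_of(g)
        v = pas(expr, self._wv(L, S, expr.node_ids))
        for i in range(4):
            want = sum(g[i, j] * (L[j] + S[j]) for j in range(3))
            assert v.T[i] == pytest.approx(want)

    def test_all_zero_fallback_is_uniform(self):
        expr = expr_of([[3.0, 9.0], [1.0, 5.0], [0.0, 2.0], [4.0, 0.0]])
        v = pas(expr, self._wv([0, 0], [0, 0], expr.node_ids))
        assert np.allclose(v.T, expr.values.mean(axis=1))

    def test_linear_in_expression(self):
        rng = np.random.default_rng(10)
        g = rng.normal(size=(5, 3))
        w = self._wv([0.5, 0.2, 0.3], [0.1, 0.1, 0.8], expr_of(g).node_ids)
        a = 3.7
        T1 = pas(expr_of(g), w).T
        T2 = pas(expr_of(a * g), w).T
        assert np.allclose(T2, a * T1)


class TestTAll:
    def test_identical_groups_zero(self):
        from networkhub.scoring import PASVector

        ids, labels = make_labels(2, 2)
        v = PASVector(sample_ids=ids, T=np.array([1.0, 2.0, 1.0, 2.0]))
        assert t_all(v, labels) == pytest.approx(0.0)

    def test_hand_computed(self):
        from networkhub.scoring import PASVector

        ids, labels = make_labels(2, 2)
        v = PASVector(sample_ids=ids, T=np.array([10.0, 12.0, 1.0, 3.0]))
        assert t_all(v, labels) == pytest.approx(9 / math.sqrt(2), abs=1e-4)

    def test_swapping_groups_flips_sign(self):
        from networkhub.scoring import PASVector

        ids, labels = make_labels(3, 3)
        rng = np.random.default_rng(12)
        v = PASVector(sample_ids=ids, T=rng.normal(size=6))
        assert t_all(v, labels) == pytest.approx(-t_all(v, labels.swapped()))

    def test_degenerate_returns_zero(self):
        from networkhub.scoring import PASVector

        ids, labels = make_labels(2, 2)
        v = PASVector(sample_ids=ids, T=np.array([5.0, 5.0, 5.0, 5.0]))
        assert t_all(v, labels) == 0.0


class TestValidation:
    def test_labels_need_two_groups(self):
        with pytest.raises(ValueError):
            PhenotypeLabels(group={"a": "x", "b": "x", "c": "x", "d": "x"})

    def test_labels_need_two_per_group(self):
        with pytest.raises(ValueError):
            PhenotypeLabels(group={"a": "x", "b": "x", "c": "y"})

    def test_expression_must_be_finite(self):
        with pytest.raises(ValueError):
            ExpressionMatrix(
                values=np.array([[1.0, np.nan], [0.0, 1.0]]),
                sample_ids=("a", "b"),
                node_ids=("g0", "g1"),
            )

    def test_config_bounds(self):
        with pytest.raises(ValueError):
            ScoringConfig(alpha_L=0.0)
        with pytest.raises(ValueError):
            ScoringConfig(epsilon=0.0)
        with pytest.raises(ValueError):
            ScoringConfig(D=0.5)
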