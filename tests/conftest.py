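import numpy as np
import pytest

from networkhub import (
    ExpressionMatrix,
    PhenotypeLabels,
    ScoringConfig,
    build_network,
)


@pytest.fixture
def chain4():
    """Chain A-B-C-D with a fixed 8-sample expression table and 4/4 labels."""
    net = build_network([("A", "B"), ("B", "C"), ("C", "D")])
    rng = np.random.default_rng(42)
    base = rng.normal(size=(8, 4))
    base[:4, 0] += 2.0  # node A differs between groups
    base[:4, 2] -= 1.5  # node C differs the other way
    sample_ids = tuple(f"s{i}" for i in range(8))
    expr = ExpressionMatrix(values=base, sample_ids=sample_ids, node_ids=net.node_ids)
    labels = PhenotypeLabels(
        group={s: ("case" if i < 4 else "control") for i, s in enumerate(sample_ids)},
        levels=("case", "control"),
    )
    return net, expr, labels


@pytest.fixture
def open_cfg():
    """Config with every gate open: all nodes enter both weight systems."""
    return ScoringConfig(alpha_L=1.0, alpha_S=1.0)


def make_labels(n_case, n_control, prefix="s"):
    ids = tuple(f"{prefix}{i}" for i in range(n_case + n_control))
    return ids, PhenotypeLabels(
        group={s: ("case" if i < n_case else "control") for i, s in enumerate(ids)},
        levels=("case", "control"),
    )
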