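import numpy as np
import pytest

from d3grn.io import ExpressionMatrix, GoldStandard, RegulatorSet
from d3grn.synthetic import SyntheticNetwork, simulate_expression


@pytest.fixture
def tiny_expr(tmp_path):
    """A 3-line expression file: header G1/G2, two numeric rows."""
    path = tmp_path / "expr.tsv"
    path.write_text("G1\tG2\n1.0\t2.0\n3.0\t4.0\n")
    return path


@pytest.fixture
def expr_4x3():
    values = np.array(
        [[1.0, 2.0, 0.5], [2.0, 1.0, 0.5], [3.0, 4.0, 0.5], [4.0, 3.0, 0.5]]
    )
    return ExpressionMatrix(values, ("G1", "G2", "G3"), ("s1", "s2", "s3", "s4"))


@pytest.fixture
def four_pair_gold():
    """2 regulators x 3 genes -> 4-pair universe, gold {e1, e3}.

    With ranking e1, e2, e3, e4 the prefix sweep gives points (0.5, 1.0)
    at q=1 and (1.0, 2/3) at q=3.
    """
    return GoldStandard(
        frozenset({("G1", "G2"), ("G2", "G1")}),
        ("G1", "G2"),
        ("G1", "G2", "G3"),
    )


def two_layer_network(
    n_tfs: int,
    n_targets: int,
    in_degree: int,
    seed: int,
    noise_sd: float = 0.0,
) -> SyntheticNetwork:
    """Root TFs (no TF->TF edges) feeding non-TF targets: a noise-free
    instance where every target is an exact function of its parents."""
    rng = np.random.default_rng(seed)
    edges = []
    for t in range(n_tfs, n_tfs + n_targets):
        parents = rng.choice(n_tfs, size=in_degree, replace=False)
        for p in sorted(parents):
            w = rng.uniform(0.5, 1.5) * rng.choice((-1.0, 1.0))
            edges.append((int(p), t, float(w)))
    return SyntheticNetwork(
        n_tfs + n_targets,
        tuple(range(n_tfs)),
        tuple(edges),
        regulatory_function="linear",
        noise_sd=noise_sd,
        perturbation_sd=0.0,
    )


@pytest.fixture
def noise_free_instance():
    """20-gene noise-free linear instance plus its expression and gold."""
    net = two_layer_network(8, 12, in_degree=2, seed=11)
    expr, gold = simulate_expression(net, 60, seed=12)
    return net, expr, gold, RegulatorSet(net.regulator_indices)
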