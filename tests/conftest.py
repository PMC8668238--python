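"""Shared fixtures: small networks with strong, easily detectable links."""

from __future__ import annotations

import numpy as np
import pytest

from grasp_bn import BayesianNetwork, DAG, Variable, forward_sample, random_bn


def binary_vars(names):
    return [Variable(n, 2, ("no", "yes")) for n in names]


@pytest.fixture(scope="session")
def chain_bn() -> BayesianNetwork:
    """X -> Y -> Z with 0.9-faithful links: the canonical indirect-edge case."""
    dag = DAG(3)
    dag.add_edge(0, 1)
    dag.add_edge(1, 2)
    copy = np.array([[0.9, 0.1], [0.1, 0.9]])
    return BayesianNetwork(
        dag=dag,
        variables=binary_vars(["X", "Y", "Z"]),
        cpts=[np.array([[0.5, 0.5]]), copy, copy],
    )


@pytest.fixture(scope="session")
def vstruct_bn() -> BayesianNetwork:
    """Collider X -> Z <- Y: Z is a noisy XOR of independent X, Y."""
    dag = DAG(3)
    dag.add_edge(0, 2)
    dag.add_edge(1, 2)
    # rows: parent config code (X + 2*Y): (0,0),(1,0),(0,1),(1,1)
    xor = np.array([[0.9, 0.1], [0.1, 0.9], [0.1, 0.9], [0.9, 0.1]])
    return BayesianNetwork(
        dag=dag,
        variables=binary_vars(["X", "Y", "Z"]),
        cpts=[np.array([[0.5, 0.5]]), np.array([[0.5, 0.5]]), xor],
    )


@pytest.fixture(scope="session")
def bn12() -> BayesianNetwork:
    """12-node binary fixture: random DAG shape, noisy-threshold CPTs so
    every edge carries marginally detectable signal."""
    from grasp_bn import noisy_threshold_bn

    rng = np.random.default_rng(20240512)
    shape = random_bn(12, max_in_degree=2, arity=2, edge_prob=0.45, rng=rng)
    return noisy_threshold_bn(shape.dag)


@pytest.fixture(scope="session")
def bn12_data(bn12):
    rng = np.random.default_rng(77)
    return forward_sample(bn12, 2000, rng)


@pytest.fixture(scope="session")
def two_node_bif() -> str:
    return """\
network test {
}
variable A {
  type discrete [ 2 ] { yes, no };
}
variable B {
  type discrete [ 2 ] { yes, no };
}
probability ( A ) {
  table 0.3, 0.7;
}
probability ( B | A ) {
  ( yes ) 0.9, 0.1;
  ( no ) 0.2, 0.8;
}
"""
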