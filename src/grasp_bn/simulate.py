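"""Synthetic-data generation and continuous-data preprocessing.

Forward (ancestral) sampling from a multinomial Bayesian network provides
the benchmark datasets; random-network generation provides test fixtures
with controlled size, in-degree and conditional-probability sharpness; and
:func:`preprocess_continuous` reproduces the standard pipeline for
continuous measurements such as flow-cytometry panels — drop rows more than
a fixed number of standard deviations from any column mean, then discretize
each column into equal-frequency categories.

Benchmark replicates are seeded as (base_seed, replicate index) so every
dataset in a protocol run is individually reproducible.
"""

from __future__ import annotations

import numpy as np

from .data_model import BayesianNetwork, CategoricalDataset, DAG, Variable, topological_order

__all__ = ["forward_sample", "random_bn", "noisy_threshold_bn", "preprocess_continuous"]


def forward_sample(
    bn: BayesianNetwork, n: int, rng: np.random.Generator
) -> CategoricalDataset:
    """Draw ``n`` observations by ancestral sampling in topological order."""
    if n < 1:
        raise ValueError("n must be >= 1")
    order = topological_order(bn.dag)
    values = np.zeros((n, bn.p), dtype=np.int64)
    for i in order:
        cpt = bn.cpts[i]
        codes = bn.parent_config_codes(i, values)
        cum = np.cumsum(cpt, axis=1)
        u = rng.random(n)
        values[:, i] = (u[:, None] < cum[codes]).argmax(axis=1)
    return CategoricalDataset(bn.variables, values)


def random_bn(
    p: int,
    max_in_degree: int = 2,
    arity: int = 2,
    edge_prob: float = 0.3,
    dirichlet_conc: float = 0.5,
    rng: np.random.Generator | None = None,
) -> BayesianNetwork:
    """A random multinomial BN: uniform node order, Bernoulli edges, Dirichlet CPTs.

    Each candidate edge (earlier -> later in a uniformly random order) is
    kept with probability ``edge_prob`` subject to ``max_in_degree``; CPT
    rows are symmetric-Dirichlet draws, so small ``dirichlet_conc`` gives
    near-deterministic conditionals (strong, easily detectable edges).
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    if max_in_degree < 0:
        raise ValueError("max_in_degree must be >= 0")
    rng = np.random.default_rng() if rng is None else rng
    order = rng.permutation(p)
    dag = DAG(p)
    for bi in range(1, p):
        child = int(order[bi])
        candidates = [int(order[ai]) for ai in range(bi)]
        rng.shuffle(candidates)
        for parent in candidates:
            if len(dag.parents[child]) >= max_in_degree:
                break
            if rng.random() < edge_prob:
                dag.add_edge(parent, child)
    variables = [
        Variable(f"X{i}", arity, tuple(f"c{s}" for s in range(arity)))
        for i in range(p)
    ]
    cpts = []
    for i in range(p):
        q = arity ** len(dag.parents[i])
        rows = rng.dirichlet(np.full(arity, dirichlet_conc), size=q)
        cpts.append(rows)
    return BayesianNetwork(dag=dag, variables=variables, cpts=cpts)


def noisy_threshold_bn(dag: DAG, leak: float = 0.15, lift: float = 0.7) -> BayesianNetwork:
    """Binary BN over a given DAG with uniformly strong, detectable edges.

    Roots are fair coins; a child with k parents is active with probability
    ``leak + lift * (active parents / k)``.  Every edge shifts the child's
    conditional by lift/k, so (unlike independently drawn Dirichlet rows,
    which can coincide across parent configurations) no edge is silent and
    all are visible to marginal tests — the property benchmark fixtures
    need.
    """
    if not 0 <= leak and leak + lift <= 1:
        raise ValueError("need 0 <= leak and leak + lift <= 1")
    variables = [Variable(f"X{i}", 2, ("off", "on")) for i in range(dag.p)]
    cpts = []
    for i in range(dag.p):
        parents = sorted(dag.parents[i])
        k = len(parents)
        if k == 0:
            cpts.append(np.array([[0.5, 0.5]]))
            continue
        rows = np.zeros((2**k, 2))
        for code in range(2**k):
            active = bin(code).count("1")
            p_on = leak + lift * active / k
            rows[code] = [1 - p_on, p_on]
        cpts.append(rows)
    return BayesianNetwork(dag=dag, variables=variables, cpts=cpts)


def preprocess_continuous(
    matrix: np.ndarray, sd_threshold: float = 3.0, n_bins: int = 3
) -> CategoricalDataset:
    """Outlier removal then equal-frequency discretization.

    A single pass: column means and SDs are computed on the *full* matrix,
    every row with any entry more than ``sd_threshold`` SDs from its column
    mean is dropped, and each retained column is cut at its empirical
    quantiles into ``n_bins`` categories.  Values exactly on a bin boundary
    are assigned to the lower bin, so heavy ties at a boundary can make bin
    sizes deviate from n/n_bins by the tie multiplicity.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("matrix must be 2-D")
    n, p = matrix.shape
    if sd_threshold <= 0:
        raise ValueError("sd_threshold must be positive")
    if n <= n_bins:
        raise ValueError("need more observations than bins")
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=0)
    keep = (np.abs(matrix - mean) <= sd_threshold * np.maximum(sd, 1e-300)).all(axis=1)
    kept = matrix[keep]
    if kept.shape[0] <= n_bins:
        raise ValueError("too few rows remain after outlier filtering")
    values = np.zeros(kept.shape, dtype=np.int64)
    for j in range(p):
        col = kept[:, j]
        if np.ptp(col) == 0:
            raise ValueError(f"column {j} is constant; cannot form {n_bins} bins")
        qs = np.quantile(col, np.arange(1, n_bins) / n_bins)
        # right=True sends boundary values to the lower bin
        values[:, j] = np.digitize(col, qs, right=True)
    variables = [
        Variable(f"V{j}", n_bins, tuple(f"bin{b}" for b in range(n_bins)))
        for j in range(p)
    ]
    return CategoricalDataset(variables, values)
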