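"""Double-filtering edge screen: admission, pruning, calibration, symmetry."""

import numpy as np
import pytest

from grasp_bn import (
    CategoricalDataset,
    Variable,
    first_filter,
    forward_sample,
    random_bn,
    run_df,
    second_filter,
    skeleton_metrics,
)


def binary_data(columns):
    cols = [np.asarray(c) for c in columns]
    variables = [Variable(f"X{i}", 2, ("a", "b")) for i in range(len(cols))]
    return CategoricalDataset(variables, np.column_stack(cols))


class TestFirstFilter:
    def test_copies_become_mutual_neighbors(self):
        col = np.repeat([0, 1], 50)
        nbr = first_filter(binary_data([col, col]), alpha=0.01)
        assert nbr.neighbor_set(0) == {1}
        assert nbr.neighbor_set(1) == {0}

    def test_symmetric_relation(self, bn12, bn12_data):
        nbr = first_filter(bn12_data, alpha=0.01)
        for i in range(bn12_data.p):
            for j in nbr.neighbor_set(i):
                assert i in nbr.neighbor_set(j)

    def test_sorted_ascending_by_pvalue(self, bn12_data):
        nbr = first_filter(bn12_data, alpha=0.01)
        for lst in nbr.neighbors:
            pvals = [p for _, p in lst]
            assert pvals == sorted(pvals)

    def test_chain_admits_indirect_edge(self, chain_bn):
        """Marginal dependence propagates along X->Y->Z, so the first filter
        keeps the indirect pair {X,Z}: the reason a second filter exists."""
        hits = 0
        for seed in range(10):
            data = forward_sample(chain_bn, 10_000, np.random.default_rng(seed))
            nbr = first_filter(data, alpha=0.01)
            if 2 in nbr.neighbor_set(0):
                hits += 1
        assert hits >= 9

    def test_false_positive_calibration(self):
        """On mutually independent columns the admitted-pair fraction matches
        the per-test level (binomial band around alpha=0.01)."""
        rng = np.random.default_rng(314)
        admitted, total = 0, 0
        for _ in range(500):
            data = binary_data([rng.integers(0, 2, 1000) for _ in range(10)])
            nbr = first_filter(data, alpha=0.01)
            admitted += nbr.n_pairs
            total += 45
        assert 0.005 <= admitted / total <= 0.018

    def test_arity_one_columns_skipped(self):
        data = CategoricalDataset(
            [Variable("A", 1, ("only",)), Variable("B", 2, ("a", "b")),
             Variable("C", 2, ("a", "b"))],
            np.column_stack([np.zeros(100, int), np.repeat([0, 1], 50),
                             np.repeat([0, 1], 50)]),
        )
        nbr = first_filter(data, alpha=0.01)
        assert nbr.neighbor_set(0) == set()
        assert nbr.neighbor_set(1) == {2}


class TestSecondFilter:
    def test_chain_prunes_indirect_edge(self, chain_bn):
        """{X,Z} is removed (X indep Z | Y); the true edges survive."""
        hits = 0
        for seed in range(10):
            data = forward_sample(chain_bn, 10_000, np.random.default_rng(seed))
            sk = run_df(data, alpha=0.01)
            if sk.edges == {(0, 1), (1, 2)}:
                hits += 1
        assert hits >= 9

    def test_no_common_neighbors_keeps_first_filter_graph(self):
        """A single dependent pair has no common neighbor: no conditional
        test can fire and the skeleton equals the first-filter graph."""
        col = np.repeat([0, 1], 50)
        data = binary_data([col, col])
        nbr = first_filter(data, alpha=0.01)
        sk = second_filter(data, nbr)
        assert sk.edges == {(0, 1)}

    def test_disconnected_gives_empty_skeleton(self):
        rng = np.random.default_rng(0)
        data = binary_data([rng.integers(0, 2, 300) for _ in range(4)])
        sk = run_df(data, alpha=1e-6)
        assert sk.edges == set()

    def test_output_subset_of_first_filter(self, bn12_data):
        nbr = first_filter(bn12_data, alpha=0.01)
        first_edges = {
            (min(i, j), max(i, j))
            for i in range(bn12_data.p)
            for j in nbr.neighbor_set(i)
        }
        sk = second_filter(bn12_data, nbr)
        assert sk.edges <= first_edges

    def test_literal_variant_runs_and_differs_or_matches(self, chain_bn):
        data = forward_sample(chain_bn, 10_000, np.random.default_rng(0))
        d = run_df(data, alpha=0.01, variant="dseparation")
        l = run_df(data, alpha=0.01, variant="literal")
        assert all(isinstance(e, tuple) for e in l.edges)
        assert d.p == l.p

    def test_unknown_variant_rejected(self, chain_bn):
        data = forward_sample(chain_bn, 1000, np.random.default_rng(0))
        with pytest.raises(ValueError):
            run_df(data, alpha=0.01, variant="bogus")


class TestRunDF:
    def test_constant_dataset_gives_empty_skeleton(self):
        data = CategoricalDataset(
            [Variable(f"X{i}", 1, ("only",)) for i in range(3)],
            np.zeros((50, 3), dtype=int),
        )
        assert run_df(data, alpha=0.01).edges == set()

    def test_two_dependent_columns(self):
        col = np.repeat([0, 1], 50)
        data = binary_data([col, 1 - col])
        assert run_df(data, alpha=0.01).edges == {(0, 1)}

    def test_recall_improves_with_sample_size(self, bn12):
        """Mean skeleton recall over replicates grows from n=500 to n=5000."""
        recalls = {}
        for n in (500, 5000):
            vals = []
            for rep in range(10):
                data = forward_sample(
                    bn12, n, np.random.default_rng(1000 * n + rep)
                )
                sk = run_df(data, alpha=0.01)
                vals.append(skeleton_metrics(bn12.dag, sk).recall)
            recalls[n] = np.mean(vals)
        assert recalls[5000] >= recalls[500]

    def test_column_permutation_equivariance(self, chain_bn):
        """Relabeling the columns permutes the skeleton accordingly: the
        screen has no hidden dependence on column order."""
        data = forward_sample(chain_bn, 5000, np.random.default_rng(4))
        sk = run_df(data, alpha=0.01)
        perm = [2, 0, 1]  # column j of the new data is old column perm[j]
        permuted = CategoricalDataset(
            [data.variables[j] for j in perm], data.values[:, perm]
        )
        sk_perm = run_df(permuted, alpha=0.01)
        inv = {old: new for new, old in enumerate(perm)}
        mapped = {tuple(sorted((inv[u], inv[v]))) for u, v in sk.edges}
        assert sk_perm.edges == mapped
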