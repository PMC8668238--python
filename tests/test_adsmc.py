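"""Adaptive SMC: block selection, configuration enumeration, Boltzmann
sampling, whole-skeleton orientation, reproducibility."""

import numpy as np
import pytest

from grasp_bn import (
    DAG,
    SMCParams,
    Skeleton,
    forward_sample,
    is_acyclic,
    run_adsmc,
    run_df,
    sample_structure,
    select_best,
    skeleton_of,
)
from grasp_bn.adsmc import (
    FULL_TRIPLET,
    PAIR,
    PARTIAL_TRIPLET,
    enumerate_configurations,
    next_block,
    sample_configuration,
    sample_seed,
)
from grasp_bn.scoring import ScoreCache, ScoredNetwork


class TestNextBlock:
    def test_triangle_with_pendant(self):
        sk = Skeleton(4, [(0, 1), (0, 2), (1, 2), (0, 3)])
        block = next_block(sk, np.random.default_rng(0))
        assert block.kind == FULL_TRIPLET
        assert block.nodes == (0, 1, 2)
        assert block.outside_connections == 1

    def test_disjoint_triangles_tie_uniform(self):
        sk = Skeleton(6, [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)])
        first = sum(
            next_block(sk, np.random.default_rng(s)).nodes == (0, 1, 2)
            for s in range(400)
        )
        assert 0.4 <= first / 400 <= 0.6

    def test_path_gives_partial_triplet(self):
        sk = Skeleton(3, [(0, 1), (1, 2)])
        block = next_block(sk, np.random.default_rng(0))
        assert block.kind == PARTIAL_TRIPLET
        assert block.nodes == (0, 1, 2)
        assert block.outside_connections == 0

    def test_lone_edge_gives_pair(self):
        block = next_block(Skeleton(2, [(0, 1)]), np.random.default_rng(0))
        assert block.kind == PAIR

    def test_empty_skeleton_raises(self):
        with pytest.raises(ValueError, match="exhausted"):
            next_block(Skeleton(3), np.random.default_rng(0))

    def test_full_triplet_priority(self):
        """A triangle is always preferred over partial triplets and pairs,
        regardless of outside connections."""
        # triangle {0,1,2} heavily connected; isolated path 3-4-5
        sk = Skeleton(7, [(0, 1), (0, 2), (1, 2), (0, 6), (1, 6), (3, 4), (4, 5)])
        for s in range(20):
            assert next_block(sk, np.random.default_rng(s)).kind == FULL_TRIPLET


class TestEnumerateConfigurations:
    def make_block(self, sk):
        return next_block(sk, np.random.default_rng(0))

    def test_full_triplet_has_six(self):
        sk = Skeleton(3, [(0, 1), (0, 2), (1, 2)])
        configs = enumerate_configurations(self.make_block(sk), DAG(3))
        assert len(configs) == 6  # 2^3 minus the two directed 3-cycles

    def test_partial_triplet_has_four(self):
        sk = Skeleton(3, [(0, 1), (1, 2)])
        configs = enumerate_configurations(self.make_block(sk), DAG(3))
        assert len(configs) == 4

    def test_pair_constrained_by_existing_path(self):
        dag = DAG(3)
        dag.add_edge(0, 1)
        dag.add_edge(1, 2)
        sk = Skeleton(3, [(0, 2)])
        configs = enumerate_configurations(self.make_block(sk), dag)
        assert configs == [((0, 2),)]  # 2 -> 0 would close the cycle

    def test_dag_restored_after_enumeration(self):
        dag = DAG(3)
        dag.add_edge(0, 1)
        sk = Skeleton(3, [(1, 2), (0, 2)])
        before = dag.edges
        enumerate_configurations(next_block(sk, np.random.default_rng(0)), dag)
        assert dag.edges == before


class TestSampleConfiguration:
    def test_equal_scores_symmetric(self):
        rng = np.random.default_rng(0)
        draws = [sample_configuration([1.0, 1.0], 1.0, rng) for _ in range(10_000)]
        assert np.mean(draws) == pytest.approx(0.5, abs=0.02)

    def test_vanishing_temperature_is_greedy(self):
        """T -> 0 turns the sampler into a local greedy search."""
        rng = np.random.default_rng(1)
        draws = [
            sample_configuration([0.0, -10.0], 1e-7, rng) for _ in range(10_000)
        ]
        assert draws.count(0) == 10_000

    def test_boltzmann_odds_ratio(self):
        """Scores (0, -delta) at temperature T give empirical odds exp(delta/T)."""
        rng = np.random.default_rng(2)
        delta, temp = 1.0, 1.0
        n = 100_000
        wins = sum(
            sample_configuration([0.0, -delta], temp, rng) == 0 for _ in range(n)
        )
        odds = wins / (n - wins)
        assert odds == pytest.approx(np.exp(delta / temp), rel=0.10)

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError):
            sample_configuration([], 1.0, np.random.default_rng(0))


class TestSampleStructure:
    def params(self, **kw):
        defaults = dict(n_samples=1, temperature=0.001, seed=0)
        defaults.update(kw)
        return SMCParams(**defaults)

    def test_empty_skeleton_gives_empty_dag(self, bn12_data):
        net = sample_structure(
            bn12_data, Skeleton(bn12_data.p), self.params(),
            np.random.default_rng(0),
        )
        assert net.dag.n_edges == 0

    def test_single_edge_high_temperature_symmetric(self, chain_bn):
        """At effectively infinite temperature each direction of a lone edge
        is drawn with frequency ~1/2."""
        data = forward_sample(chain_bn, 200, np.random.default_rng(0))
        sk = Skeleton(3, [(0, 1)])
        cache = ScoreCache()
        params = self.params(temperature=1e6)
        forward = 0
        for s in range(4000):
            net = sample_structure(data, sk, params, np.random.default_rng(s), cache)
            forward += net.dag.has_edge(0, 1)
        assert forward / 4000 == pytest.approx(0.5, abs=0.03)

    def test_collider_skeleton_recovers_vstructure(self, vstruct_bn):
        """Greedy-temperature sampling on the true skeleton {X-Z, Y-Z}
        concentrates on the collider X -> Z <- Y: it is the only member of
        its equivalence class, and it alone explains the marginal
        independence of X and Y.  (A full triangle would be uninformative —
        all six orientations of a complete graph are Markov equivalent and
        score identically.)"""
        data = forward_sample(vstruct_bn, 5000, np.random.default_rng(3))
        sk = Skeleton(3, [(0, 2), (1, 2)])
        cache = ScoreCache()
        params = self.params(temperature=0.001)
        hits = 0
        for s in range(200):
            net = sample_structure(data, sk, params, np.random.default_rng(s), cache)
            if net.dag.has_edge(0, 2) and net.dag.has_edge(1, 2):
                hits += 1
        assert hits > 190  # modal (near-certain) structure is the collider

    def test_triangle_orientations_are_equivalence_class(self, vstruct_bn):
        """All six acyclic orientations of a triangle score identically, so
        the Boltzmann sampler is uniform over them at any temperature."""
        from grasp_bn.adsmc import configuration_score, enumerate_configurations

        data = forward_sample(vstruct_bn, 5000, np.random.default_rng(3))
        sk = Skeleton(3, [(0, 1), (0, 2), (1, 2)])
        block = next_block(sk, np.random.default_rng(0))
        configs = enumerate_configurations(block, DAG(3))
        scores = [configuration_score(data, block, c, DAG(3)) for c in configs]
        assert len(configs) == 6
        assert max(scores) - min(scores) < 1e-9

    def test_samples_stay_inside_skeleton_and_acyclic(self, bn12, bn12_data):
        sk = run_df(bn12_data, alpha=0.01)
        cache = ScoreCache()
        params = self.params()
        for s in range(25):
            net = sample_structure(
                bn12_data, sk, params, np.random.default_rng(s), cache
            )
            assert is_acyclic(net.dag)
            assert skeleton_of(net.dag).edges <= sk.edges
            # every skeleton edge receives exactly one direction
            assert skeleton_of(net.dag).edges == sk.edges

    def test_block_schedule_ordering(self, bn12, bn12_data):
        """Pairs are never sampled while a triplet could be formed earlier in
        the same sample's schedule (full > partial > pair priority)."""
        sk = run_df(bn12_data, alpha=0.01)
        trace: list = []
        sample_structure(
            bn12_data, sk, self.params(), np.random.default_rng(1),
            ScoreCache(), trace=trace,
        )
        # the committed kind must equal the kind next_block would choose on
        # the remaining skeleton at that step: kind (unlike the tie-broken
        # node choice) is a deterministic function of the remaining edges
        remaining = sk.copy()
        for block in trace:
            recomputed = next_block(remaining, np.random.default_rng(0))
            assert recomputed.kind == block.kind
            for u, v in block.internal_edges:
                remaining.remove_edge(u, v)


class TestRunAdsmc:
    def test_single_sample_matches_sample_structure(self, bn12_data):
        sk = run_df(bn12_data, alpha=0.01)
        params = SMCParams(n_samples=1, temperature=0.01, seed=5)
        [net] = run_adsmc(bn12_data, sk, params)
        direct = sample_structure(bn12_data, sk, params, sample_seed(5, 0))
        assert net.dag == direct.dag
        assert net.score == pytest.approx(direct.score, rel=1e-12)

    def test_determinism(self, bn12_data):
        sk = run_df(bn12_data, alpha=0.01)
        params = SMCParams(n_samples=30, temperature=0.01, seed=9)
        a = [s.score for s in run_adsmc(bn12_data, sk, params)]
        b = [s.score for s in run_adsmc(bn12_data, sk, params)]
        assert a == b

    def test_parallel_matches_serial(self, bn12_data):
        sk = run_df(bn12_data, alpha=0.01)
        serial = run_adsmc(bn12_data, sk, SMCParams(n_samples=12, seed=3))
        parallel = run_adsmc(
            bn12_data, sk, SMCParams(n_samples=12, seed=3, n_jobs=2)
        )
        assert [s.dag for s in serial] == [p.dag for p in parallel]

    def test_best_of_nested_sample_sets_is_monotone(self, bn12_data):
        sk = run_df(bn12_data, alpha=0.01)
        few = run_adsmc(bn12_data, sk, SMCParams(n_samples=10, seed=2, temperature=0.1))
        many = run_adsmc(bn12_data, sk, SMCParams(n_samples=100, seed=2, temperature=0.1))
        assert select_best(many).score >= select_best(few).score

    def test_select_best_rules(self):
        nets = [
            ScoredNetwork(DAG(1), -5.0),
            ScoredNetwork(DAG(1), -3.0),
            ScoredNetwork(DAG(1), -9.0),
        ]
        assert select_best(nets) is nets[1]
        ties = [ScoredNetwork(DAG(1), -1.0), ScoredNetwork(DAG(1), -1.0)]
        assert select_best(ties) is ties[0]
        assert select_best([nets[0]]) is nets[0]
        with pytest.raises(ValueError):
            select_best([])

    def test_fixed_order_mode_valid(self, bn12_data):
        """The fixed-upfront comparator still orients the whole skeleton."""
        sk = run_df(bn12_data, alpha=0.01)
        params = SMCParams(n_samples=5, seed=1, adaptive=False)
        for net in run_adsmc(bn12_data, sk, params):
            assert is_acyclic(net.dag)
            assert skeleton_of(net.dag).edges == sk.edges
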