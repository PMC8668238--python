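"""Stage 2 — adaptive sequential Monte Carlo structure search.

Each SMC sample grows a DAG by orienting the skeleton block by block.  A
block is a fully connected triplet (three nodes, three remaining undirected
edges), then — once no triangles remain — a partially connected triplet (two
edges), then a plain pair (one edge).  Among eligible blocks the one with
the fewest *outside connections* (remaining undirected edges incident to the
block but not internal to it) is sampled first, because weakly connected
blocks are least constrained later and sampling them early maximizes the
diversity of configurations.  Block choice is recomputed after every commit
on the *remaining* skeleton, so the schedule adapts to the partially sampled
structure; that adaptivity is the method's point and is what distinguishes
it from a fixed-upfront block decomposition.

For a chosen block, every joint orientation of its internal edges that keeps
the growing DAG acyclic is enumerated and scored by the block nodes' summed
local BIC; one configuration is drawn with Boltzmann probability

    P(config c) ∝ exp(score_c / T),

where the temperature T controls greediness: T -> 0 is local greedy search,
T -> infinity samples orientations uniformly.  Acyclicity-violating
configurations have probability zero by construction.  Samples are mutually
independent, so many are drawn (each from its own derived seed) and the
highest-scoring network is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from joblib import Parallel, delayed

from .data_model import DAG, CategoricalDataset, Skeleton, creates_cycle
from .scoring import ScoreCache, ScoredNetwork, local_bic, network_bic

__all__ = [
    "SamplingBlock",
    "SMCParams",
    "next_block",
    "enumerate_configurations",
    "configuration_score",
    "sample_configuration",
    "sample_structure",
    "run_adsmc",
    "select_best",
]

logger = logging.getLogger(__name__)

FULL_TRIPLET = "full_triplet"
PARTIAL_TRIPLET = "partial_triplet"
PAIR = "pair"


@dataclass(frozen=True)
class SamplingBlock:
    """A 2- or 3-node block with its remaining internal undirected edges."""

    nodes: tuple[int, ...]
    kind: str
    internal_edges: tuple[tuple[int, int], ...]
    outside_connections: int


@dataclass
class SMCParams:
    """Search settings for the SMC and hill-climbing stages.

    temperature 0.001 and large sample counts are the regime where the
    sampler behaves as a diversified near-greedy search; rohc_top_k=None
    refines every sample.
    """

    n_samples: int = 2000
    temperature: float = 0.001
    seed: int = 0
    rohc_rounds: int = 5
    rohc_top_k: int | None = None
    search_limit: int | None = None
    n_jobs: int = 1
    adaptive: bool = True

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.rohc_rounds < 0:
            raise ValueError("rohc_rounds must be >= 0")


def _outside(sk: Skeleton, nodes: Sequence[int], internal: int) -> int:
    return sum(sk.degree(u) for u in nodes) - 2 * internal


def _full_triplets(sk: Skeleton) -> list[SamplingBlock]:
    blocks = []
    for u, v in sorted(sk.edges):
        for w in sorted(sk.neighbors(u) & sk.neighbors(v)):
            if w > v:  # each triangle once, u < v < w
                blocks.append(
                    SamplingBlock(
                        nodes=(u, v, w),
                        kind=FULL_TRIPLET,
                        internal_edges=((u, v), (u, w), (v, w)),
                        outside_connections=_outside(sk, (u, v, w), 3),
                    )
                )
    return blocks


def _partial_triplets(sk: Skeleton) -> list[SamplingBlock]:
    blocks = []
    for center in range(sk.p):
        nbrs = sorted(sk.neighbors(center))
        for a_idx in range(len(nbrs)):
            for b_idx in range(a_idx + 1, len(nbrs)):
                a, b = nbrs[a_idx], nbrs[b_idx]
                if sk.has_edge(a, b):
                    continue  # that would be a triangle
                nodes = tuple(sorted((a, center, b)))
                edges = (tuple(sorted((a, center))), tuple(sorted((center, b))))
                blocks.append(
                    SamplingBlock(
                        nodes=nodes,
                        kind=PARTIAL_TRIPLET,
                        internal_edges=tuple(sorted(edges)),  # type: ignore[arg-type]
                        outside_connections=_outside(sk, nodes, 2),
                    )
                )
    return blocks


def _pairs(sk: Skeleton) -> list[SamplingBlock]:
    return [
        SamplingBlock(
            nodes=(u, v),
            kind=PAIR,
            internal_edges=((u, v),),
            outside_connections=_outside(sk, (u, v), 1),
        )
        for u, v in sorted(sk.edges)
    ]


def next_block(remaining: Skeleton, rng: np.random.Generator) -> SamplingBlock:
    """Least-outside-connection block: full triplets, then partial, then pairs.

    Ties among minimal blocks are broken uniformly at random.  Raises
    ValueError if the remaining skeleton has no edges left.
    """
    if remaining.n_edges == 0:
        raise ValueError("skeleton exhausted: no edges remain")
    for finder in (_full_triplets, _partial_triplets, _pairs):
        blocks = finder(remaining)
        if blocks:
            lo = min(b.outside_connections for b in blocks)
            ties = [b for b in blocks if b.outside_connections == lo]
            return ties[int(rng.integers(len(ties)))]
    raise AssertionError("unreachable: nonempty skeleton yields at least a pair")


def enumerate_configurations(
    block: SamplingBlock, dag: DAG
) -> list[tuple[tuple[int, int], ...]]:
    """All joint orientations of the block's internal edges that keep
    ``dag`` acyclic — both internal 3-cycles and cycles through previously
    committed edges are excluded.  Each configuration is a tuple of directed
    (parent, child) edges."""
    edges = block.internal_edges
    configs: list[tuple[tuple[int, int], ...]] = []
    m = len(edges)
    for mask in range(1 << m):
        directed = tuple(
            (u, v) if not (mask >> t) & 1 else (v, u)
            for t, (u, v) in enumerate(edges)
        )
        added: list[tuple[int, int]] = []
        ok = True
        for a, b in directed:
            if creates_cycle(dag, a, b):
                ok = False
                break
            dag.add_edge(a, b)
            added.append((a, b))
        for a, b in added:
            dag.remove_edge(a, b)
        if ok:
            configs.append(directed)
    return configs


def configuration_score(
    data: CategoricalDataset,
    block: SamplingBlock,
    config: tuple[tuple[int, int], ...],
    dag: DAG,
    cache: ScoreCache | None = None,
) -> float:
    """Summed local BIC of the block's nodes with the configuration applied.

    Only block nodes' families can change, because internal edges join block
    nodes; non-block families are constant across configurations and are
    omitted."""
    new_parents = {node: set(dag.parents[node]) for node in block.nodes}
    for a, b in config:
        new_parents[b].add(a)
    return sum(
        local_bic(data, node, new_parents[node], cache) for node in block.nodes
    )


def sample_configuration(
    scores: Sequence[float], temperature: float, rng: np.random.Generator
) -> int:
    """Draw an index with Boltzmann probability softmax(scores / T)."""
    if len(scores) == 0:
        raise ValueError("no configurations to sample from")
    z = np.asarray(scores, dtype=float) / temperature
    z -= z.max()  # overflow guard; softmax is shift-invariant
    w = np.exp(z)
    return int(rng.choice(len(w), p=w / w.sum()))


def _fixed_block_schedule(
    skeleton: Skeleton, rng: np.random.Generator
) -> list[SamplingBlock]:
    """Upfront block order on the original skeleton: full triplets, partial
    triplets, then pairs, each group ascending by outside connections (ties
    shuffled).  Comparator for the adaptive scheduler — covers every edge
    because trailing pair blocks enumerate all edges."""
    schedule: list[SamplingBlock] = []
    for finder in (_full_triplets, _partial_triplets):
        blocks = finder(skeleton)
        keys = rng.permutation(len(blocks))
        blocks = [blocks[i] for i in keys]
        blocks.sort(key=lambda b: b.outside_connections)
        schedule.extend(blocks)
    pairs = _pairs(skeleton)
    keys = rng.permutation(len(pairs))
    pairs = [pairs[i] for i in keys]
    pairs.sort(key=lambda b: b.outside_connections)
    schedule.extend(pairs)
    return schedule


def sample_structure(
    data: CategoricalDataset,
    skeleton: Skeleton,
    params: SMCParams,
    rng: np.random.Generator,
    cache: ScoreCache | None = None,
    trace: list | None = None,
) -> ScoredNetwork:
    """Generate one SMC sample: orient the whole skeleton block by block.

    ``trace``, if given, collects the :class:`SamplingBlock` committed at
    each step (instrumentation for scheduling diagnostics).
    """
    if skeleton.p != data.p:
        raise ValueError("skeleton size does not match dataset")
    dag = DAG(data.p)
    remaining = skeleton.copy()
    schedule = None if params.adaptive else iter(_fixed_block_schedule(skeleton, rng))
    while remaining.n_edges > 0:
        if params.adaptive:
            block = next_block(remaining, rng)
        else:
            block = next(schedule)  # type: ignore[arg-type]
            live = tuple(
                e for e in block.internal_edges if remaining.has_edge(*e)
            )
            if not live:
                continue
            block = SamplingBlock(block.nodes, block.kind, live, block.outside_connections)
        configs = enumerate_configurations(block, dag)
        # at least one orientation along a linear extension is always acyclic
        scores = [
            configuration_score(data, block, c, dag, cache) for c in configs
        ]
        chosen = configs[sample_configuration(scores, params.temperature, rng)]
        if trace is not None:
            trace.append(block)
        for a, b in chosen:
            dag.add_edge(a, b)
            remaining.remove_edge(a, b)
    return ScoredNetwork(dag=dag, score=network_bic(data, dag, cache), provenance={})


def sample_seed(base_seed: int, sample_index: int) -> np.random.Generator:
    """Deterministic per-sample generator derived from (seed, index)."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=base_seed, spawn_key=(sample_index,))
    )


def _one_sample(
    data: CategoricalDataset,
    skeleton: Skeleton,
    params: SMCParams,
    s: int,
    cache: ScoreCache | None,
) -> ScoredNetwork:
    net = sample_structure(data, skeleton, params, sample_seed(params.seed, s), cache)
    net.provenance = {"sample": s, "seed": params.seed}
    return net


def run_adsmc(
    data: CategoricalDataset,
    skeleton: Skeleton,
    params: SMCParams,
    cache: ScoreCache | None = None,
) -> list[ScoredNetwork]:
    """Draw ``params.n_samples`` independent SMC samples.

    Sample ``s`` uses a generator derived from (seed, s), so results are
    identical regardless of worker count or execution order.  The shared
    score cache is an optimization only.
    """
    if params.n_jobs != 1:
        nets = Parallel(n_jobs=params.n_jobs)(
            delayed(_one_sample)(data, skeleton, params, s, None)
            for s in range(params.n_samples)
        )
        return list(nets)
    if cache is None:
        cache = ScoreCache()
    nets = []
    best = -np.inf
    for s in range(params.n_samples):
        net = _one_sample(data, skeleton, params, s, cache)
        best = max(best, net.score)
        if (s + 1) % 1000 == 0:
            logger.info("adSMC sample %d/%d, best score %.4f", s + 1, params.n_samples, best)
        nets.append(net)
    return nets


def select_best(samples: Sequence[ScoredNetwork]) -> ScoredNetwork:
    """Highest-scoring sample; ties go to the earliest index."""
    if not samples:
        raise ValueError("no samples to select from")
    best = samples[0]
    for net in samples[1:]:
        if net.score > best.score:
            best = net
    return best
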