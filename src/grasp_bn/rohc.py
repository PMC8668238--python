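"""Stage 3 — Random Order Hill Climbing (ROHC) edge reclamation.

Edges missed by the skeleton screen can never be produced by the orientation
search, which samples only within the skeleton.  ROHC repairs this: for each
sampled network, candidate parents are visited in a fresh random permutation
and any edge X_j -> X_i that keeps the graph acyclic and strictly increases
the (decomposable) BIC is committed immediately.  Candidates are *not*
restricted to the stage-1 skeleton.  Only additions are performed — no
deletions or reversals — so the score increases monotonically.  Each full
sweep costs O(p^2) local-score evaluations, hence the evaluation budget
``search_limit`` (default 2*p^2).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .data_model import DAG, CategoricalDataset, creates_cycle
from .scoring import ScoreCache, ScoredNetwork, local_bic, network_bic

__all__ = ["rohc_refine", "refine_samples"]


def rohc_refine(
    data: CategoricalDataset,
    dag: DAG,
    rounds: int,
    rng: np.random.Generator,
    search_limit: int | None = None,
    cache: ScoreCache | None = None,
) -> ScoredNetwork:
    """Greedy-immediate edge additions in random parent order.

    Per round: draw one permutation of the nodes; for every child node in
    ascending index order, scan candidate parents in permutation order and
    add the first-improvement edges.  Stops after ``rounds`` rounds, after a
    round that adds nothing, or once ``search_limit`` candidate evaluations
    are spent.  The returned score is never below the input's.
    """
    if rounds < 0:
        raise ValueError("rounds must be >= 0")
    p = data.p
    if search_limit is None:
        search_limit = 2 * p * p
    if search_limit < 1:
        raise ValueError("search_limit must be positive")
    dag = dag.copy()
    if cache is None:
        cache = ScoreCache()
    evaluations = 0
    added: list[tuple[int, int]] = []
    for _ in range(rounds):
        perm = rng.permutation(p)
        any_added = False
        for i in range(p):
            base = local_bic(data, i, dag.parents[i], cache)
            for j in perm:
                j = int(j)
                if j == i or dag.has_edge(j, i):
                    continue
                if evaluations >= search_limit:
                    break
                evaluations += 1
                if creates_cycle(dag, j, i):
                    continue
                cand = local_bic(data, i, dag.parents[i] | {j}, cache)
                if cand > base:
                    dag.add_edge(j, i)
                    base = cand
                    any_added = True
                    added.append((j, i))
            if evaluations >= search_limit:
                break
        if not any_added or evaluations >= search_limit:
            break
    return ScoredNetwork(
        dag=dag,
        score=network_bic(data, dag, cache),
        provenance={"rohc_added": added, "rohc_evaluations": evaluations},
    )


def refine_samples(
    data: CategoricalDataset,
    samples: Sequence[ScoredNetwork],
    rounds: int,
    seed: int,
    top_k: int | None = None,
    search_limit: int | None = None,
    cache: ScoreCache | None = None,
) -> list[ScoredNetwork]:
    """Apply ROHC to the top-k samples by score (default: all samples).

    Per-sample permutations are seeded from (seed, original sample index),
    so refinement is reproducible and independent of list order.  Samples
    outside the top-k pass through unrefined; the output keeps input order.
    """
    if top_k is None or top_k >= len(samples):
        chosen = set(range(len(samples)))
    else:
        order = sorted(
            range(len(samples)), key=lambda s: (-samples[s].score, s)
        )
        chosen = set(order[:top_k])
    out: list[ScoredNetwork] = []
    for s, net in enumerate(samples):
        if s not in chosen:
            out.append(net)
            continue
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(s, 1))
        )
        refined = rohc_refine(
            data, net.dag, rounds, rng, search_limit=search_limit, cache=cache
        )
        refined.provenance = {**net.provenance, **refined.provenance, "rohc_rounds": rounds}
        # additions are strict improvements, so this cannot drop the score
        out.append(refined if refined.score >= net.score else net)
    return out
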