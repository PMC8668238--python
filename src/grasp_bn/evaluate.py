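"""Skeleton-recovery metrics and the benchmark harness.

Edge screening is scored by precision = TP/(TP+FP), recall = TP/(TP+FN) and
their harmonic mean (f-score), all over *undirected* edges: TP counts true
undirected edges identified, FP proposed non-edges, FN missed true edges.
Recall is the critical quantity for a screening stage, since an edge missed
there is invisible to the orientation search (only the hill-climbing stage
can reclaim it).  Learned structures are compared to the generating network
on the BIC scale via the ratio score(truth)/score(learned): with both scores
negative, a ratio above 1 means the learned network scores *higher* than the
truth — possible at finite n because the maximum-scoring structure need not
be the generating one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .adsmc import SMCParams, run_adsmc, select_best
from .data_model import BayesianNetwork, DAG, Skeleton, skeleton_of
from .rohc import refine_samples
from .scoring import ScoreCache, network_bic
from .simulate import forward_sample
from .skeleton_df import run_df

__all__ = [
    "SkeletonMetrics",
    "skeleton_metrics",
    "bic_ratio",
    "run_benchmark",
    "enumerate_dags",
    "exhaustive_best_score",
]


@dataclass(frozen=True)
class SkeletonMetrics:
    """Undirected-edge confusion counts and the derived rates."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    fscore: float


def skeleton_metrics(truth: DAG, estimate: Skeleton) -> SkeletonMetrics:
    """Precision/recall/f-score of an estimated skeleton against a true DAG.

    Direction is ignored: the truth is reduced to its skeleton first.  Zero
    denominators yield 0 rather than an error.
    """
    if truth.p != estimate.p:
        raise ValueError("truth and estimate are over different node counts")
    true_edges = skeleton_of(truth).edges
    est_edges = estimate.edges
    tp = len(true_edges & est_edges)
    fp = len(est_edges - true_edges)
    fn = len(true_edges - est_edges)
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    fscore = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return SkeletonMetrics(tp, fp, fn, precision, recall, fscore)


def bic_ratio(data, truth: BayesianNetwork, learned: DAG) -> float:
    """score(true structure) / score(learned structure), internal scale.

    Both scores are negative on non-degenerate data, so a ratio > 1 means
    the learned structure scores higher than the truth.
    """
    denom = network_bic(data, learned)
    if denom == 0.0:
        raise ValueError("learned network has zero score; ratio undefined")
    return network_bic(data, truth.dag) / denom


def enumerate_dags(p: int):
    """Yield every labeled DAG on ``p`` nodes.

    Each unordered node pair independently takes one of three states (absent,
    forward, backward); cyclic assignments are discarded.  Counts follow the
    labeled-DAG sequence: 543 for p=4, 29281 for p=5.  Exhaustive search only
    — feasible for p <= 5 or so.
    """
    from .data_model import is_acyclic

    pairs = [(u, v) for u in range(p) for v in range(u + 1, p)]
    m = len(pairs)
    state = [0] * m
    while True:
        dag = DAG(p)
        for (u, v), s in zip(pairs, state):
            if s == 1:
                dag.add_edge(u, v)
            elif s == 2:
                dag.add_edge(v, u)
        if is_acyclic(dag):
            yield dag
        # odometer over base-3 states
        t = 0
        while t < m and state[t] == 2:
            state[t] = 0
            t += 1
        if t == m:
            return
        state[t] += 1


def exhaustive_best_score(data, cache: ScoreCache | None = None) -> tuple[float, DAG]:
    """Global BIC optimum by brute force over all DAGs (small p only)."""
    if cache is None:
        cache = ScoreCache()
    best_score, best_dag = -float("inf"), None
    for dag in enumerate_dags(data.p):
        s = network_bic(data, dag, cache)
        if s > best_score:
            best_score, best_dag = s, dag
    return best_score, best_dag


def run_benchmark(
    bn: BayesianNetwork,
    n_list: list[int],
    replicates: int,
    alpha: float,
    params: SMCParams,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Full protocol on one network: simulate, screen, search, refine, score.

    For every observation size in ``n_list`` and every replicate: forward
    sample a dataset (seed derived from (base_seed, size index, replicate)),
    run the double-filtering screen at ``alpha`` and record skeleton
    precision/recall/f-score, then run the SMC search plus hill-climbing
    refinement and record the BIC ratio of the best network.  Returns one
    row per (n, replicate); all seeds are logged in the table.
    """
    rows = []
    for ni, n in enumerate(n_list):
        for rep in range(replicates):
            data_rng = np.random.default_rng(
                np.random.SeedSequence(entropy=base_seed, spawn_key=(ni, rep))
            )
            data = forward_sample(bn, n, data_rng)
            sk = run_df(data, alpha)
            m = skeleton_metrics(bn.dag, sk)
            run_seed = base_seed + 7919 * ni + rep
            p = SMCParams(
                n_samples=params.n_samples,
                temperature=params.temperature,
                seed=run_seed,
                rohc_rounds=params.rohc_rounds,
                rohc_top_k=params.rohc_top_k,
                search_limit=params.search_limit,
                n_jobs=params.n_jobs,
                adaptive=params.adaptive,
            )
            cache = ScoreCache()
            samples = run_adsmc(data, sk, p, cache)
            samples = refine_samples(
                data,
                samples,
                rounds=p.rohc_rounds,
                seed=run_seed,
                top_k=p.rohc_top_k,
                search_limit=p.search_limit,
                cache=cache,
            )
            best = select_best(samples)
            rows.append(
                {
                    "n": n,
                    "replicate": rep,
                    "data_seed": f"({base_seed},{ni},{rep})",
                    "run_seed": run_seed,
                    "skeleton_edges": sk.n_edges,
                    "tp": m.tp,
                    "fp": m.fp,
                    "fn": m.fn,
                    "precision": m.precision,
                    "recall": m.recall,
                    "fscore": m.fscore,
                    "best_score": best.score,
                    "bic_ratio": bic_ratio(data, bn, best.dag),
                }
            )
    return pd.DataFrame(rows)
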