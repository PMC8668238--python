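"""Decomposable BIC score for multinomial Bayesian networks.

The network score is a sum of local family scores

    local(i) = ln L_i - (k_i / 2) * ln n,
    ln L_i   = sum_{j,k} N_jk * ln(N_jk / N_j.),   0*ln 0 := 0,
    k_i      = (r_i - 1) * prod_{q in parents(i)} r_q,

where ``N_jk`` counts rows with parent configuration ``j`` and child state
``k``.  Higher is better; the classical reporting scale ln(n)*k - 2*ln(L) is
exposed as :func:`classic_bic` (= -2x the internal score).  Markov-equivalent
DAGs receive identical scores (score equivalence), and the score is
consistent: asymptotically the true structure's equivalence class attains
the maximum.

Local scores depend only on (child, parent set), so they are cached; the
cache is an optimization only — results are identical with caching disabled.
"""

from __future__ import annotations

import threading
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .data_model import DAG, CategoricalDataset

__all__ = ["ScoreCache", "ScoredNetwork", "local_bic", "network_bic", "classic_bic"]


class ScoreCache:
    """Thread-safe cache of local scores keyed by (child, sorted parents)."""

    def __init__(self) -> None:
        self._store: dict[tuple[int, tuple[int, ...]], float] = {}
        self._lock = threading.Lock()

    def get(self, key: tuple[int, tuple[int, ...]]) -> float | None:
        return self._store.get(key)

    def put(self, key: tuple[int, tuple[int, ...]], value: float) -> None:
        with self._lock:
            self._store[key] = value

    def __len__(self) -> int:
        return len(self._store)


@dataclass
class ScoredNetwork:
    """A DAG with its network BIC (internal higher-is-better scale)."""

    dag: DAG
    score: float
    provenance: dict = field(default_factory=dict)


def local_bic(
    data: CategoricalDataset,
    child: int,
    parents: Iterable[int],
    cache: ScoreCache | None = None,
) -> float:
    """BIC contribution of one family: ln L-hat minus half the penalty.

    Parent configurations never observed contribute 0 to the likelihood but
    still count toward the parameter penalty (k uses full nominal arities).
    """
    pset = tuple(sorted(parents))
    if child in pset:
        raise ValueError(f"child {child} cannot be its own parent")
    key = (child, pset)
    if cache is not None:
        hit = cache.get(key)
        if hit is not None:
            return hit
    values = data.values
    arities = data.arities
    n = data.n
    r = int(arities[child])
    q = 1
    codes = np.zeros(n, dtype=np.int64)
    for u in pset:
        codes += values[:, u] * q
        q *= int(arities[u])
    counts = np.bincount(codes * r + values[:, child], minlength=q * r).reshape(q, r)
    nj = counts.sum(axis=1, keepdims=True)
    nz = counts > 0
    ratio = np.where(nz, counts / np.maximum(nj, 1), 1.0)
    loglik = float(np.sum(counts[nz] * np.log(ratio[nz])))
    k_params = (r - 1) * q
    score = loglik - 0.5 * k_params * np.log(n)
    if cache is not None:
        cache.put(key, score)
    return score


def network_bic(
    data: CategoricalDataset, dag: DAG, cache: ScoreCache | None = None
) -> float:
    """Network score: sum of local family scores (decomposable)."""
    if dag.p != data.p:
        raise ValueError("DAG size does not match dataset")
    return sum(local_bic(data, i, dag.parents[i], cache) for i in range(dag.p))


def classic_bic(
    data: CategoricalDataset, dag: DAG, cache: ScoreCache | None = None
) -> float:
    """Classical smaller-is-better scale: ln(n)*k - 2*ln(L-hat)."""
    return -2.0 * network_bic(data, dag, cache)
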