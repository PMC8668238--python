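"""Stage 1 — Double Filtering (DF) skeleton discovery.

The first filter runs a marginal G-test on every variable pair and admits
pairs with p < alpha as mutual neighbors; this removes variables that are
not ancestors or descendants of one another.  The second filter prunes
neighbors that are not *direct* neighbors (parents or children): for every
surviving edge it conditions on common neighbors one at a time, and a single
non-significant conditional test removes the edge.  The result is intended
as a *cover* of the true skeleton — a superset of the true undirected edges
— rather than the exact skeleton; conditioning on at most one node keeps the
tests well-powered at small sample sizes.

Two readings of the second filter are provided.  The default
(``variant="dseparation"``) treats the pair {i, j} as the edge under
scrutiny and removes it when some common neighbor k renders i and j
conditionally independent given k — the d-separation-consistent rule that
prunes the indirect edge in a chain X -> Y -> Z.  The ``"literal"`` variant
instead tests i against each common neighbor k given j, and on a
non-significant result removes the *conditioning* neighbor j from i's
neighborhood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .citest import cmi_test, mi_test
from .data_model import CategoricalDataset, Skeleton

__all__ = ["NeighborTable", "first_filter", "second_filter", "run_df"]

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.01


@dataclass
class NeighborTable:
    """Per-node neighbor lists from the first filter, ascending by p-value.

    ``neighbors[i]`` is a list of (j, p_ij) with p_ij < alpha, sorted by
    p-value (ties by node index).  The relation is symmetric: j appears in
    i's list iff i appears in j's.
    """

    p: int
    alpha: float
    neighbors: list[list[tuple[int, float]]] = field(default_factory=list)

    def neighbor_set(self, i: int) -> set[int]:
        return {j for j, _ in self.neighbors[i]}

    @property
    def n_pairs(self) -> int:
        return sum(len(nbr) for nbr in self.neighbors) // 2


def first_filter(data: CategoricalDataset, alpha: float = DEFAULT_ALPHA) -> NeighborTable:
    """Marginal screen: admit pair {i, j} iff the G-test gives p < alpha.

    Arity-1 (constant-domain) columns are skipped entirely and never become
    neighbors.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    p = data.p
    testable = [i for i in range(p) if data.arities[i] >= 2]
    nbr: list[list[tuple[int, float]]] = [[] for _ in range(p)]
    for a, i in enumerate(testable):
        for j in testable[a + 1 :]:
            pval = mi_test(data, i, j).p_value
            if pval < alpha:
                nbr[i].append((j, pval))
                nbr[j].append((i, pval))
    for i in range(p):
        nbr[i].sort(key=lambda t: (t[1], t[0]))
    return NeighborTable(p=p, alpha=alpha, neighbors=nbr)


def second_filter(
    data: CategoricalDataset,
    nbr: NeighborTable,
    alpha: float | None = None,
    variant: str = "dseparation",
) -> Skeleton:
    """Conditional prune of the first-filter graph; returns the skeleton.

    Nodes are visited in ascending index order and each node's neighbors in
    ascending first-filter p-value order.  Removals are applied symmetrically
    and immediately, and every (pair, conditioner) test is run at most once.
    """
    if alpha is None:
        alpha = nbr.alpha
    if variant not in ("dseparation", "literal"):
        raise ValueError(f"unknown DF variant {variant!r}")
    sk = Skeleton(data.p)
    for i in range(data.p):
        for j, _ in nbr.neighbors[i]:
            sk.add_edge(i, j)

    tested: dict[tuple[int, int, int], float] = {}

    def cond_p(a: int, b: int, c: int) -> float:
        lo, hi = (a, b) if a < b else (b, a)
        key = (lo, hi, c)
        if key not in tested:
            tested[key] = cmi_test(data, lo, hi, c).p_value
        return tested[key]

    first = {i: nbr.neighbor_set(i) for i in range(data.p)}
    for i in range(data.p):
        for j, _ in nbr.neighbors[i]:
            if variant == "dseparation":
                if not sk.has_edge(i, j):
                    continue  # already removed from the other side
                common = first[i] & first[j]
                for k in sorted(common):
                    if cond_p(i, j, k) > alpha:
                        sk.remove_edge(i, j)
                        break
            else:  # literal reading: failing i vs k given j removes j
                if not sk.has_edge(i, j):
                    continue
                common = first[i] & first[j]
                for k in sorted(common):
                    if cond_p(i, k, j) > alpha:
                        sk.remove_edge(i, j)
                        break
    return sk


def run_df(
    data: CategoricalDataset,
    alpha: float = DEFAULT_ALPHA,
    variant: str = "dseparation",
) -> Skeleton:
    """Both filters in sequence; logs per-stage edge counts."""
    nbr = first_filter(data, alpha)
    logger.info("DF first filter: %d candidate edges", nbr.n_pairs)
    sk = second_filter(data, nbr, alpha, variant=variant)
    logger.info("DF second filter: %d edges retained", sk.n_edges)
    return sk
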