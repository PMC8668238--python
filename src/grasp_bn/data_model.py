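"""Core graph and dataset containers.

All structure-learning stages operate on three objects: a
:class:`CategoricalDataset` (an ``n x p`` matrix of category indices with
per-variable arities), an undirected :class:`Skeleton` (the search space
produced by the edge-screening stage), and a :class:`DAG` (parent sets per
node, kept acyclic by construction through :func:`creates_cycle`).  A
:class:`BayesianNetwork` couples a DAG with conditional probability tables
and is used by the simulator and the BIF reader.

Nodes are referenced by 0-based column index throughout; variable names only
appear at I/O boundaries.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Variable",
    "CategoricalDataset",
    "Skeleton",
    "DAG",
    "BayesianNetwork",
    "is_acyclic",
    "creates_cycle",
    "skeleton_of",
    "topological_order",
]


@dataclass(frozen=True)
class Variable:
    """A categorical variable: a name, an arity and ordered category labels."""

    name: str
    arity: int
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.arity < 1:
            raise ValueError(f"variable {self.name!r}: arity must be >= 1, got {self.arity}")
        if len(self.labels) != self.arity:
            raise ValueError(
                f"variable {self.name!r}: {len(self.labels)} labels for arity {self.arity}"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError(f"variable {self.name!r}: duplicate category labels")


class CategoricalDataset:
    """Observed categorical data: ``n`` rows over ``p`` variables.

    ``values[r, i]`` is the category index of variable ``i`` in observation
    ``r`` and must lie in ``[0, arity_i)``.  Missing entries are rejected at
    construction; the learner has no missing-data mechanism.
    """

    def __init__(self, variables: Sequence[Variable], values: np.ndarray):
        values = np.asarray(values)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if values.shape[1] != len(variables):
            raise ValueError(
                f"{values.shape[1]} columns for {len(variables)} variables"
            )
        if values.shape[0] < 1:
            raise ValueError("dataset must contain at least one observation")
        if not np.issubdtype(values.dtype, np.integer):
            if np.isnan(np.asarray(values, dtype=float)).any():
                raise ValueError("dataset contains missing entries")
            values = values.astype(np.int64)
        self.variables = list(variables)
        self.values = np.ascontiguousarray(values, dtype=np.int64)
        self.arities = np.array([v.arity for v in self.variables], dtype=np.int64)
        for i, v in enumerate(self.variables):
            col = self.values[:, i]
            if col.min() < 0 or col.max() >= v.arity:
                raise ValueError(
                    f"column {v.name!r}: category index outside [0, {v.arity})"
                )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def __repr__(self) -> str:
        return f"CategoricalDataset(n={self.n}, p={self.p})"


class Skeleton:
    """Undirected graph over ``p`` nodes stored as unordered index pairs."""

    def __init__(self, p: int, edges: Iterable[tuple[int, int]] = ()):
        if p < 0:
            raise ValueError("p must be nonnegative")
        self.p = p
        self._adj: list[set[int]] = [set() for _ in range(p)]
        self._edges: set[tuple[int, int]] = set()
        for u, v in edges:
            self.add_edge(u, v)

    @property
    def edges(self) -> set[tuple[int, int]]:
        """Edge set as sorted (min, max) index pairs."""
        return set(self._edges)

    def add_edge(self, u: int, v: int) -> None:
        if u == v:
            raise ValueError(f"self-pair ({u}, {v}) not allowed")
        if not (0 <= u < self.p and 0 <= v < self.p):
            raise ValueError(f"edge ({u}, {v}) outside node range [0, {self.p})")
        a, b = (u, v) if u < v else (v, u)
        self._edges.add((a, b))
        self._adj[u].add(v)
        self._adj[v].add(u)

    def remove_edge(self, u: int, v: int) -> None:
        a, b = (u, v) if u < v else (v, u)
        self._edges.discard((a, b))
        self._adj[u].discard(v)
        self._adj[v].discard(u)

    def has_edge(self, u: int, v: int) -> bool:
        a, b = (u, v) if u < v else (v, u)
        return (a, b) in self._edges

    def neighbors(self, u: int) -> set[int]:
        return set(self._adj[u])

    def degree(self, u: int) -> int:
        return len(self._adj[u])

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def copy(self) -> "Skeleton":
        return Skeleton(self.p, self._edges)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Skeleton)
            and self.p == other.p
            and self._edges == other._edges
        )

    def __iter__(self) -> Iterator[tuple[int, int]]:
        return iter(sorted(self._edges))

    def __repr__(self) -> str:
        return f"Skeleton(p={self.p}, edges={self.n_edges})"


class DAG:
    """Directed graph over ``p`` nodes as per-node parent sets.

    Acyclicity is the caller's contract: mutation helpers never check it (use
    :func:`creates_cycle` before :meth:`add_edge`), while the read-side
    operations (:func:`topological_order`) raise on cyclic input.
    """

    def __init__(self, p: int, parents: Sequence[Iterable[int]] | None = None):
        if p < 0:
            raise ValueError("p must be nonnegative")
        self.p = p
        self.parents: list[set[int]] = [set() for _ in range(p)]
        self.children: list[set[int]] = [set() for _ in range(p)]
        if parents is not None:
            if len(parents) != p:
                raise ValueError("parents must have one entry per node")
            for child, ps in enumerate(parents):
                for u in ps:
                    self.add_edge(u, child)

    def add_edge(self, u: int, v: int) -> None:
        """Add directed edge u -> v (u becomes a parent of v)."""
        if u == v:
            raise ValueError(f"self-loop ({u}, {v}) not allowed")
        if not (0 <= u < self.p and 0 <= v < self.p):
            raise ValueError(f"edge ({u}, {v}) outside node range [0, {self.p})")
        self.parents[v].add(u)
        self.children[u].add(v)

    def remove_edge(self, u: int, v: int) -> None:
        self.parents[v].discard(u)
        self.children[u].discard(v)

    def has_edge(self, u: int, v: int) -> bool:
        return u in self.parents[v]

    @property
    def edges(self) -> list[tuple[int, int]]:
        """Directed edges as (parent, child), sorted."""
        return sorted((u, v) for v in range(self.p) for u in self.parents[v])

    @property
    def n_edges(self) -> int:
        return sum(len(ps) for ps in self.parents)

    def copy(self) -> "DAG":
        new = DAG(self.p)
        new.parents = [set(s) for s in self.parents]
        new.children = [set(s) for s in self.children]
        return new

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, DAG)
            and self.p == other.p
            and self.parents == other.parents
        )

    def __repr__(self) -> str:
        return f"DAG(p={self.p}, edges={self.n_edges})"


@dataclass
class BayesianNetwork:
    """A DAG plus multinomial conditional probability tables.

    ``cpts[i]`` has shape ``(q_i, r_i)`` where ``r_i`` is node i's arity and
    ``q_i`` the product of its parents' arities; row ``j`` is the distribution
    of node i given the parent configuration with mixed-radix code ``j`` over
    the parents in ascending index order (first parent varies fastest).
    Every row must sum to 1 within 1e-9.
    """

    dag: DAG
    variables: list[Variable]
    cpts: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.dag.p != len(self.variables):
            raise ValueError("variable count does not match DAG size")
        if len(self.cpts) != self.dag.p:
            raise ValueError("one CPT required per node")
        for i, cpt in enumerate(self.cpts):
            r = self.variables[i].arity
            q = 1
            for u in sorted(self.dag.parents[i]):
                q *= self.variables[u].arity
            if cpt.shape != (q, r):
                raise ValueError(
                    f"CPT for node {i} has shape {cpt.shape}, expected {(q, r)}"
                )
            if not np.allclose(cpt.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"CPT rows for node {i} do not sum to 1")

    @property
    def p(self) -> int:
        return self.dag.p

    def parent_config_codes(self, i: int, values: np.ndarray) -> np.ndarray:
        """Mixed-radix parent-configuration code of node ``i`` for each row."""
        ps = sorted(self.dag.parents[i])
        codes = np.zeros(values.shape[0], dtype=np.int64)
        stride = 1
        for u in ps:
            codes += values[:, u] * stride
            stride *= self.variables[u].arity
        return codes


def is_acyclic(dag: DAG) -> bool:
    """True iff a topological order of ``dag`` exists (Kahn's algorithm)."""
    indeg = [len(dag.parents[v]) for v in range(dag.p)]
    stack = [v for v in range(dag.p) if indeg[v] == 0]
    seen = 0
    while stack:
        u = stack.pop()
        seen += 1
        for w in dag.children[u]:
            indeg[w] -= 1
            if indeg[w] == 0:
                stack.append(w)
    return seen == dag.p


def creates_cycle(dag: DAG, u: int, v: int) -> bool:
    """Would adding u -> v close a directed cycle?

    True iff ``u`` is reachable from ``v`` by a directed path.  The DAG is
    not modified.  Raises ValueError for a self-loop query.
    """
    if u == v:
        raise ValueError("self-loop query: u == v")
    if v == u:  # pragma: no cover - unreachable, kept for symmetry
        return True
    stack = [v]
    visited = {v}
    while stack:
        w = stack.pop()
        if w == u:
            return True
        for c in dag.children[w]:
            if c not in visited:
                visited.add(c)
                stack.append(c)
    return False


def skeleton_of(dag: DAG) -> Skeleton:
    """Drop edge directions: unordered pair {u,v} iff u->v or v->u."""
    sk = Skeleton(dag.p)
    for v in range(dag.p):
        for u in dag.parents[v]:
            sk.add_edge(u, v)
    return sk


def topological_order(dag: DAG) -> list[int]:
    """A topological order; ties broken by ascending node index.

    Raises ValueError if the graph is cyclic.
    """
    indeg = [len(dag.parents[v]) for v in range(dag.p)]
    heap = [v for v in range(dag.p) if indeg[v] == 0]
    heapq.heapify(heap)
    order: list[int] = []
    while heap:
        u = heapq.heappop(heap)
        order.append(u)
        for w in sorted(dag.children[u]):
            indeg[w] -= 1
            if indeg[w] == 0:
                heapq.heappush(heap, w)
    if len(order) != dag.p:
        raise ValueError("graph is not a DAG: no topological order exists")
    return order
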