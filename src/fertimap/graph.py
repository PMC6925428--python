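"""Census-tract sets and their adjacency structure.

The unit of analysis throughout the package is the census tract.  Every
downstream stage (ICAR fields, BYM smoothing, ecological regression) operates
on a :class:`TractSet` paired with a symmetric :class:`AdjacencyGraph`; this
module owns those two objects and the synthetic rook-lattice generator that
stands in for real tract maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

__all__ = ["TractSet", "AdjacencyGraph", "generate_lattice", "DisconnectedGraphError"]


class DisconnectedGraphError(ValueError):
    """Raised when an operation requires a connected adjacency graph.

    The sum-to-zero constraint of the intrinsic CAR prior is only well defined
    per connected component; this package rejects disconnected supports rather
    than silently applying a global constraint.
    """

    def __init__(self, components: Sequence[Sequence[int]]):
        self.components = [sorted(c) for c in components]
        sizes = ", ".join(str(len(c)) for c in self.components)
        super().__init__(
            f"adjacency graph is disconnected: {len(self.components)} components "
            f"of sizes [{sizes}]; ICAR sum-to-zero is ambiguous on disconnected "
            f"supports"
        )


@dataclass(frozen=True)
class TractSet:
    """Ordered collection of census-tract identifiers.

    Parameters
    ----------
    tract_id
        Unique identifiers; their order is the canonical tract order used by
        every array in the pipeline.
    rows, cols
        Optional grid coordinates (row-major lattice position) for synthetic
        cities; ``None`` for real geographies.
    """

    tract_id: tuple[str, ...]
    rows: np.ndarray | None = None
    cols: np.ndarray | None = None

    def __post_init__(self):
        if len(set(self.tract_id)) != len(self.tract_id):
            raise ValueError("tract identifiers must be unique")
        if len(self.tract_id) < 2:
            raise ValueError("a tract set needs at least 2 tracts")

    @property
    def n_tracts(self) -> int:
        return len(self.tract_id)

    def index_of(self, ids: Iterable[str]) -> np.ndarray:
        """Positions of ``ids`` in canonical order (error on unknown ids)."""
        lookup = {t: i for i, t in enumerate(self.tract_id)}
        try:
            return np.array([lookup[t] for t in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"unknown tract id {exc.args[0]!r}") from None


@dataclass(frozen=True)
class AdjacencyGraph:
    """Symmetric neighbour structure over ``n`` tracts (positions 0..n-1).

    Stored as an edge list with ``i < j`` per row; symmetry and absence of
    self-loops are enforced at construction.
    """

    n: int
    edges: np.ndarray = field(repr=False)  # (m, 2) int, each row i < j

    def __post_init__(self):
        e = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        if e.size and (e.min() < 0 or e.max() >= self.n):
            raise ValueError("edge references a tract outside 0..n-1")
        if np.any(e[:, 0] == e[:, 1]):
            raise ValueError("self-loops are not allowed")
        e = np.sort(e, axis=1)
        e = np.unique(e, axis=0) if e.size else e
        object.__setattr__(self, "edges", e)

    @classmethod
    def from_neighbors(cls, neighbors: Mapping[int, Iterable[int]], n: int) -> "AdjacencyGraph":
        """Build from neighbour lists; entries are symmetrised."""
        pairs = []
        for i, nbs in neighbors.items():
            for j in nbs:
                if not (0 <= j < n):
                    raise ValueError(f"neighbour id {j} of tract {i} does not exist")
                pairs.append((min(i, j), max(i, j)))
        edges = np.array(sorted(set(pairs)), dtype=int).reshape(-1, 2)
        return cls(n=n, edges=edges)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbor_lists(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.n)]
        for i, j in self.edges:
            out[i].append(j)
            out[j].append(i)
        return [sorted(v) for v in out]

    def degrees(self) -> np.ndarray:
        d = np.zeros(self.n, dtype=int)
        np.add.at(d, self.edges.ravel(), 1)
        return d

    def adjacency_matrix(self) -> sp.csr_matrix:
        """Sparse 0/1 adjacency matrix W."""
        i, j = self.edges[:, 0], self.edges[:, 1]
        data = np.ones(2 * len(self.edges))
        W = sp.coo_matrix(
            (data, (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(self.n, self.n),
        )
        return W.tocsr()

    def laplacian(self) -> np.ndarray:
        """Dense graph Laplacian D - W (the ICAR precision structure)."""
        W = self.adjacency_matrix().toarray()
        return np.diag(W.sum(axis=1)) - W

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(map(tuple, self.edges))
        return g

    def is_connected(self) -> bool:
        return nx.is_connected(self.to_networkx())

    def require_connected(self) -> None:
        g = self.to_networkx()
        if not nx.is_connected(g):
            raise DisconnectedGraphError(list(nx.connected_components(g)))

    def coloring(self) -> list[np.ndarray]:
        """Partition nodes into independent sets (no edge within a set).

        Used by the block Metropolis updates: nodes of one colour are
        conditionally independent under the ICAR prior given the rest, so a
        whole colour class can be proposed and accepted element-wise.
        """
        colors = nx.greedy_color(self.to_networkx(), strategy="largest_first")
        k = max(colors.values()) + 1 if colors else 0
        return [
            np.array(sorted(i for i, c in colors.items() if c == col), dtype=int)
            for col in range(k)
        ]


def generate_lattice(n_rows: int, n_cols: int) -> tuple[TractSet, AdjacencyGraph]:
    """Rook-adjacency grid of ``n_rows`` x ``n_cols`` synthetic tracts.

    Tract ids are assigned in row-major order (``T0000``, ``T0001``, ...);
    each tract neighbours the tracts sharing an edge with it (4-neighbour
    contiguity), mirroring contiguity-based census-tract neighbourhood files.

    Raises
    ------
    ValueError
        For a 1x1 request: the intrinsic CAR prior is undefined on a single
        tract.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("n_rows and n_cols must be >= 1")
    n = n_rows * n_cols
    if n < 2:
        raise ValueError("a 1x1 lattice has no neighbour structure; ICAR is undefined on a single tract")
    ids = tuple(f"T{i:04d}" for i in range(n))
    rr, cc = np.divmod(np.arange(n), n_cols)
    tracts = TractSet(tract_id=ids, rows=rr, cols=cc)

    pairs = []
    for r in range(n_rows):
        for c in range(n_cols):
            i = r * n_cols + c
            if c + 1 < n_cols:
                pairs.append((i, i + 1))
            if r + 1 < n_rows:
                pairs.append((i, i + n_cols))
    graph = AdjacencyGraph(n=n, edges=np.array(pairs, dtype=int))
    return tracts, graph
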