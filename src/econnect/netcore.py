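"""Network data model with explicit edge-weight semantics.

Every network carries a declaration of what its edge weights *mean*:
whether they grow with the strength of association (flow-like weights such
as interaction frequencies, shared parasites, dispersal probabilities) or
with separation (distance-like weights such as cost-distance or travel
time).  Shortest-path algorithms minimise weight sums, so flow-like weights
must be reversed before any path-based centrality is meaningful; keeping
the semantics on the object lets downstream code enforce that instead of
silently producing the longest-flow path.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "SemanticsKind",
    "EdgeSemantics",
    "EcoNetwork",
    "NetworkError",
    "read_edge_list",
    "write_edge_list",
    "read_adjacency",
    "write_adjacency",
    "read_incidence",
    "binarize",
    "unipartite_projection",
]

#: relative tolerance for treating float-parsed weights as equal
WEIGHT_RTOL = 1e-12


class NetworkError(ValueError):
    """Invalid network construction or file content."""


class SemanticsKind(str, Enum):
    BINARY = "binary"
    DISTANCE_LIKE = "distance_like"
    FLOW_LIKE = "flow_like"
    PROBABILITY = "probability"


@dataclass(frozen=True)
class EdgeSemantics:
    """Declared meaning of edge weights.

    ``probability`` semantics additionally carries an ``independence``
    declaration: the product rule for path probabilities (and hence the
    negative-log transform) is only valid when edges are independent, so
    operations that rely on it demand an explicit True here.
    """

    kind: SemanticsKind
    independence: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.kind is not SemanticsKind.PROBABILITY and self.independence is not None:
            raise NetworkError(
                "independence declaration only applies to probability semantics"
            )

    # -- convenience constructors -------------------------------------
    @classmethod
    def binary(cls) -> "EdgeSemantics":
        return cls(SemanticsKind.BINARY)

    @classmethod
    def distance_like(cls) -> "EdgeSemantics":
        return cls(SemanticsKind.DISTANCE_LIKE)

    @classmethod
    def flow_like(cls) -> "EdgeSemantics":
        return cls(SemanticsKind.FLOW_LIKE)

    @classmethod
    def probability(cls, independence: Optional[bool] = None) -> "EdgeSemantics":
        return cls(SemanticsKind.PROBABILITY, independence)

    @classmethod
    def parse(cls, text: str, independence: Optional[bool] = None) -> "EdgeSemantics":
        kind = SemanticsKind(text.replace("-", "_"))
        if kind is SemanticsKind.PROBABILITY:
            return cls(kind, independence)
        return cls(kind)

    @property
    def is_flow_proportional(self) -> bool:
        """True when larger weight means stronger association."""
        return self.kind in (SemanticsKind.FLOW_LIKE, SemanticsKind.PROBABILITY)


Edge = tuple[str, str, float]


@dataclass
class EcoNetwork:
    """Weighted or binary ecological network.

    Parameters
    ----------
    nodes
        Ordered node identifiers (opaque strings).
    edges
        ``(source, target, weight)`` triples.  For undirected networks
        each edge is stored once, canonically ordered by node position.
    directed
        Edge direction matters (e.g. carbon flow).
    semantics
        Declared weight semantics; never inferred from data.
    metadata
        Free-form provenance map; ``node_edge_definition`` holds the
        checklist description of what nodes and edges represent.
    allow_negative
        Escape hatch for the negation-pitfall demonstration; ordinary
        construction rejects negative weights.
    """

    nodes: tuple[str, ...]
    edges: list[Edge]
    directed: bool = False
    semantics: EdgeSemantics = field(default_factory=EdgeSemantics.binary)
    metadata: dict = field(default_factory=dict)
    allow_negative: bool = False
    allow_self_loops: bool = False

    def __post_init__(self) -> None:
        self.nodes = tuple(str(n) for n in self.nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise NetworkError("duplicate node identifiers")
        index = {n: i for i, n in enumerate(self.nodes)}
        seen: set[tuple[int, int]] = set()
        canon: list[Edge] = []
        for u, v, w in self.edges:
            u, v, w = str(u), str(v), float(w)
            if u not in index or v not in index:
                raise NetworkError(f"edge ({u}, {v}) references unknown node")
            if u == v and not (self.directed and self.allow_self_loops):
                raise NetworkError(f"self-loop on node {u!r} not allowed")
            if w < 0 and not self.allow_negative:
                raise NetworkError(
                    f"negative weight {w} on edge ({u}, {v}); negative weights "
                    "require the explicit allow_negative flag"
                )
            iu, iv = index[u], index[v]
            if not self.directed and iu > iv:
                u, v, iu, iv = v, u, iv, iu
            if (iu, iv) in seen:
                raise NetworkError(f"duplicate edge ({u}, {v})")
            seen.add((iu, iv))
            canon.append((u, v, w))
        self.edges = canon
        self._index = index
        self._check_semantics()

    def _check_semantics(self) -> None:
        ws = self.weights()
        kind = self.semantics.kind
        if kind is SemanticsKind.BINARY:
            if ws.size and not np.allclose(ws, 1.0, rtol=WEIGHT_RTOL, atol=0):
                raise NetworkError("binary semantics requires all weights equal 1")
        if kind is SemanticsKind.PROBABILITY:
            if ws.size and (np.any(ws <= 0) or np.any(ws > 1 + WEIGHT_RTOL)):
                raise NetworkError("probability semantics requires weights in (0, 1]")

    # -- basic accessors ----------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index(self, node: str) -> int:
        return self._index[node]

    def weights(self) -> np.ndarray:
        return np.array([w for _, _, w in self.edges], dtype=float)

    def adjacency(self) -> np.ndarray:
        """Dense weight matrix in node order; 0 means no edge."""
        a = np.zeros((self.n_nodes, self.n_nodes))
        for u, v, w in self.edges:
            i, j = self._index[u], self._index[v]
            a[i, j] = w
            if not self.directed:
                a[j, i] = w
        return a

    def adjacency_lists(self) -> list[list[tuple[int, float]]]:
        """Out-neighbour lists of ``(node_index, weight)`` pairs."""
        out: list[list[tuple[int, float]]] = [[] for _ in self.nodes]
        for u, v, w in self.edges:
            i, j = self._index[u], self._index[v]
            out[i].append((j, w))
            if not self.directed:
                out[j].append((i, w))
        return out

    # -- derivation helpers -------------------------------------------
    def with_edges(
        self, edges: Iterable[Edge], semantics: Optional[EdgeSemantics] = None, **kw
    ) -> "EcoNetwork":
        return EcoNetwork(
            nodes=self.nodes,
            edges=list(edges),
            directed=self.directed,
            semantics=semantics or self.semantics,
            metadata=dict(self.metadata),
            allow_negative=kw.get("allow_negative", self.allow_negative),
            allow_self_loops=self.allow_self_loops,
        )

    def declare_semantics(self, semantics: EdgeSemantics) -> "EcoNetwork":
        """Return a copy with a different semantics declaration.

        Deliberately available so the pitfalls (treating flow weights as
        distances) can be reproduced and demonstrated.
        """
        return self.with_edges(self.edges, semantics=semantics)

    def copy(self) -> "EcoNetwork":
        return self.with_edges(self.edges)


# ---------------------------------------------------------------------
# file I/O (delimited text; comma or tab auto-detected)
# ---------------------------------------------------------------------

def _read_table(path: Union[str, Path], index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", index_col=index_col)


def read_edge_list(
    path: Union[str, Path],
    semantics: EdgeSemantics,
    directed: bool = False,
    allow_negative: bool = False,
) -> EcoNetwork:
    """Read a ``source,target[,weight]`` delimited file.

    A missing weight column forces binary semantics with unit weights.
    Zero weights are rejected: a zero weight is "no edge", and zeros break
    the 1/a and log(1/a) transforms.
    """
    df = _read_table(path)
    cols = {c.lower().strip(): c for c in df.columns}
    if "source" not in cols or "target" not in cols:
        raise NetworkError(f"{path}: expected header columns source, target[, weight]")
    has_weight = "weight" in cols
    if not has_weight:
        semantics = EdgeSemantics.binary()

    edges: list[Edge] = []
    nodes: list[str] = []
    seen_nodes: set[str] = set()
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        u = str(getattr(row, cols["source"]))
        v = str(getattr(row, cols["target"]))
        if has_weight:
            w = float(getattr(row, cols["weight"]))
            if np.isnan(w):
                raise NetworkError(f"{path}: missing weight at line {row_no}")
            if w == 0:
                raise NetworkError(
                    f"{path}: zero weight at line {row_no} ({u}, {v}); "
                    "omit the row to express 'no edge'"
                )
            if w < 0 and not allow_negative:
                raise NetworkError(
                    f"{path}: negative weight {w} at line {row_no} ({u}, {v})"
                )
            if semantics.kind is SemanticsKind.PROBABILITY and w > 1:
                raise NetworkError(
                    f"{path}: weight {w} > 1 at line {row_no} is not a probability"
                )
        else:
            w = 1.0
        for n in (u, v):
            if n not in seen_nodes:
                seen_nodes.add(n)
                nodes.append(n)
        edges.append((u, v, w))
    return EcoNetwork(
        nodes=tuple(nodes),
        edges=edges,
        directed=directed,
        semantics=semantics,
        allow_negative=allow_negative,
    )


def write_edge_list(net: EcoNetwork, path: Union[str, Path]) -> None:
    df = pd.DataFrame(net.edges, columns=["source", "target", "weight"])
    df.to_csv(path, index=False)


def read_adjacency(path: Union[str, Path], semantics: EdgeSemantics) -> EcoNetwork:
    """Read a labelled square adjacency matrix; zero entries mean no edge.

    A symmetric matrix yields an undirected network, an asymmetric one a
    directed network.
    """
    df = _read_table(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise NetworkError(f"{path}: adjacency matrix must be square, got {df.shape}")
    if list(map(str, df.index)) != list(map(str, df.columns)):
        raise NetworkError(f"{path}: row and column labels differ")
    a = df.to_numpy(dtype=float)
    if np.isnan(a).any():
        raise NetworkError(f"{path}: NaN entries in adjacency matrix")
    labels = [str(x) for x in df.index]
    symmetric = np.allclose(a, a.T, rtol=WEIGHT_RTOL, atol=0)
    edges: list[Edge] = []
    n = len(labels)
    for i in range(n):
        for j in range(n):
            if not symmetric or j > i:
                if a[i, j] != 0:
                    edges.append((labels[i], labels[j], a[i, j]))
    return EcoNetwork(
        nodes=tuple(labels), edges=edges, directed=not symmetric, semantics=semantics
    )


def write_adjacency(net: EcoNetwork, path: Union[str, Path]) -> None:
    df = pd.DataFrame(net.adjacency(), index=net.nodes, columns=net.nodes)
    df.to_csv(path)


def read_incidence(path: Union[str, Path]) -> pd.DataFrame:
    """Read a bipartite incidence table (rows x columns of {0,1})."""
    df = _read_table(path, index_col=0)
    vals = df.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise NetworkError(f"{path}: incidence table must contain only 0/1")
    return df.astype(int)


# ---------------------------------------------------------------------
# derivations
# ---------------------------------------------------------------------

def binarize(net: EcoNetwork, justification: str = "") -> EcoNetwork:
    """Discard weights, keeping topology.

    Binarizing weighted data changes which nodes come out central, so a
    justification must travel with the result; an empty one is allowed but
    flagged for the checklist reporter.
    """
    out = net.with_edges(
        [(u, v, 1.0) for u, v, _ in net.edges],
        semantics=EdgeSemantics.binary(),
        allow_negative=False,
    )
    out.metadata["binarize_justification"] = justification
    if not justification.strip():
        out.metadata["binarize_unjustified"] = True
    return out


def unipartite_projection(incidence: pd.DataFrame) -> EcoNetwork:
    """Project a binary two-mode table onto its rows.

    The weight of edge (i, j) is the number of columns where both rows
    have a 1 (e.g. parasites shared by two host species).  Even though
    the incidence data are binary, the projection is weighted and
    flow-proportional: more shared partners means a stronger association.
    """
    b = incidence.to_numpy(dtype=float)
    if not np.isin(b, (0.0, 1.0)).all():
        raise NetworkError("incidence table must be binary (0/1)")
    shared = b @ b.T
    labels = [str(x) for x in incidence.index]
    edges: list[Edge] = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if shared[i, j] > 0:
                edges.append((labels[i], labels[j], float(shared[i, j])))
    net = EcoNetwork(
        nodes=tuple(labels),
        edges=edges,
        directed=False,
        semantics=EdgeSemantics.flow_like(),
    )
    net.metadata["node_edge_definition"] = (
        "nodes: row entities of the incidence table; "
        "edges: number of shared column entities"
    )
    return net
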