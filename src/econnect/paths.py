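"""Shortest paths, max-product probability paths, and centralities.

Distances come from Dijkstra's algorithm run per source on non-negative,
distance-like weights; a shortest-path DAG built with a float-tolerant
tie test then yields the number sigma_ij of distinct shortest paths.
Betweenness is accumulated with Brandes' dependency recursion; stress and
the pass-through tallies use the equivalent combinatorial identity
g_ij(v) = sigma_iv * sigma_vj whenever v lies on a shortest i-j path.

Flow-proportional inputs (flow_like or probability semantics) are refused
here by design: minimising a sum of flow weights traces the weakest
connections, so the caller must transform first.  Networks with negative
weights are likewise refused and routed to the Bellman-Ford-Moore based
negative-cycle detector, which demonstrates why negating flow weights is
not a usable reversal.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .netcore import EcoNetwork, SemanticsKind
from .transforms import TransformSpec

__all__ = [
    "PathResult",
    "CentralityResult",
    "NegativeCycleReport",
    "SemanticsRefusal",
    "shortest_paths",
    "max_product_path",
    "detect_negative_cycle",
    "betweenness",
    "stress",
    "closeness",
]

#: relative tolerance for treating two path lengths as equally short;
#: sigma counts depend on it, hence documented here
TIE_RTOL = 1e-9


class SemanticsRefusal(ValueError):
    """Raised when an operation is invalid for the declared semantics."""


def _tied(a: float, b: float) -> bool:
    if math.isinf(a) or math.isinf(b):
        return a == b
    return abs(a - b) <= TIE_RTOL * max(1.0, abs(a), abs(b))


def _require_distance_like(net: EcoNetwork, op: str) -> None:
    if net.semantics.kind in (SemanticsKind.FLOW_LIKE, SemanticsKind.PROBABILITY):
        raise SemanticsRefusal(
            f"{op}: weights have {net.semantics.kind.value} semantics and are "
            "proportional to information flow; minimising their sum would "
            "trace the weakest connections. Apply a reversing transform "
            "first (see transforms.recommend_transform)."
        )
    if any(w < 0 for _, _, w in net.edges):
        raise SemanticsRefusal(
            f"{op}: network has negative weights; shortest paths are not "
            "defined in the presence of negative cycles — use "
            "detect_negative_cycle instead"
        )


@dataclass
class PathResult:
    """All-pairs shortest-path distances and path counts.

    ``dist[i, j]`` is the length g_ij of the shortest path (inf when
    unreachable), ``sigma[i, j]`` the number of distinct shortest paths
    (0 when unreachable, 1 on the diagonal).
    """

    nodes: tuple[str, ...]
    dist: np.ndarray
    sigma: np.ndarray
    directed: bool

    def pass_through(self) -> np.ndarray:
        """Tallies ``g_ij(v)``: shortest i-j paths through interior node v.

        Uses the identity g_ij(v) = sigma_iv * sigma_vj when
        dist_iv + dist_vj = dist_ij, and 0 otherwise.
        """
        n = len(self.nodes)
        out = np.zeros((n, n, n))
        for v in range(n):
            via = self.dist[:, v][:, None] + self.dist[v, :][None, :]
            with np.errstate(invalid="ignore"):
                on_path = np.abs(via - self.dist) <= TIE_RTOL * np.maximum(
                    1.0, np.maximum(np.abs(via), np.abs(self.dist))
                )
            on_path &= np.isfinite(self.dist) & np.isfinite(via)
            counts = self.sigma[:, v][:, None] * self.sigma[v, :][None, :]
            g_v = np.where(on_path, counts, 0.0)
            g_v[v, :] = 0.0
            g_v[:, v] = 0.0
            np.fill_diagonal(g_v, 0.0)
            out[:, :, v] = g_v
        return out


@dataclass
class CentralityResult:
    """Per-node centrality scores plus the provenance the checklist needs."""

    measure: str  # "BC", "SC" or "CC"
    scores: dict[str, float]
    weighted: bool
    transform: Optional[TransformSpec] = None
    policy: str = ""
    all_shortest_paths: bool = True  # all minimum-length paths are counted

    def ranking(self) -> list[str]:
        """Nodes sorted by decreasing score; ties broken by identifier."""
        return sorted(self.scores, key=lambda n: (-self.scores[n], n))

    def argmax(self) -> str:
        return self.ranking()[0]


@dataclass
class NegativeCycleReport:
    """Either finite distances or a negative-cycle certificate."""

    nodes: tuple[str, ...]
    has_negative_cycle: bool
    cycle: Optional[list[str]] = None
    dist: Optional[np.ndarray] = None


# ---------------------------------------------------------------------
# single-source machinery
# ---------------------------------------------------------------------

def _edge_weight(net: EcoNetwork, w: float) -> float:
    return 1.0 if net.semantics.kind is SemanticsKind.BINARY else w


def _dijkstra(adj: list[list[tuple[int, float]]], source: int, n: int) -> np.ndarray:
    dist = np.full(n, np.inf)
    dist[source] = 0.0
    done = np.zeros(n, dtype=bool)
    heap: list[tuple[float, int]] = [(0.0, source)]
    while heap:
        d, u = heapq.heappop(heap)
        if done[u]:
            continue
        done[u] = True
        for v, w in adj[u]:
            nd = d + w
            if nd < dist[v]:
                dist[v] = nd
                heapq.heappush(heap, (nd, v))
    return dist


def _sigma_from_dist(
    adj: list[list[tuple[int, float]]], source: int, dist: np.ndarray
) -> np.ndarray:
    """Count shortest paths by sweeping nodes in order of distance.

    An edge (u, v) lies on the shortest-path DAG when
    dist[u] + w = dist[v] within the tie tolerance.
    """
    n = len(adj)
    sigma = np.zeros(n)
    sigma[source] = 1.0
    order = [v for v in np.argsort(dist, kind="stable") if np.isfinite(dist[v])]
    # in-edges of the DAG: collect per target
    preds: list[list[int]] = [[] for _ in range(n)]
    for u in range(n):
        if not np.isfinite(dist[u]):
            continue
        for v, w in adj[u]:
            if np.isfinite(dist[v]) and v != source and _tied(dist[u] + w, dist[v]):
                preds[v].append(u)
    for v in order:
        for u in preds[v]:
            sigma[v] += sigma[u]
    return sigma


def shortest_paths(net: EcoNetwork) -> PathResult:
    """All-pairs shortest paths with all-minimum-path counting.

    Requires binary or distance-like semantics and non-negative weights.
    Binary networks use unit weights.  Unreachable pairs get dist = inf
    and sigma = 0.
    """
    _require_distance_like(net, "shortest_paths")
    n = net.n_nodes
    adj = [
        [(v, _edge_weight(net, w)) for v, w in lst] for lst in net.adjacency_lists()
    ]
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for s in range(n):
        ds = _dijkstra(adj, s, n)
        dist[s] = ds
        sigma[s] = _sigma_from_dist(adj, s, ds)
    return PathResult(nodes=net.nodes, dist=dist, sigma=sigma, directed=net.directed)


# ---------------------------------------------------------------------
# max-product probability paths
# ---------------------------------------------------------------------

def max_product_path(
    net: EcoNetwork, source: str, target: str
) -> tuple[Optional[list[str]], float]:
    """Most probable path between two nodes of a probability network.

    Runs Dijkstra under the log(1/a) transform, which maps the product of
    independent edge probabilities onto a sum of distances, and returns
    the path together with the product of the original probabilities
    along it.  Refuses networks whose edges are declared non-independent:
    the product rule is invalid there and no alternative is assumed.
    Returns ``(None, 0.0)`` when the target is unreachable.
    """
    if net.semantics.kind is not SemanticsKind.PROBABILITY:
        raise SemanticsRefusal(
            "max_product_path requires probability semantics"
        )
    if net.semantics.independence is not True:
        raise SemanticsRefusal(
            "max_product_path requires edges declared as independent "
            "probabilities; the product rule is invalid otherwise"
        )
    n = net.n_nodes
    s, t = net.index(source), net.index(target)
    adj = [[(v, -math.log(w)) for v, w in lst] for lst in net.adjacency_lists()]
    raw = {}
    for u_lab, v_lab, w in net.edges:
        i, j = net.index(u_lab), net.index(v_lab)
        raw[(i, j)] = w
        if not net.directed:
            raw[(j, i)] = w

    dist = np.full(n, np.inf)
    dist[s] = 0.0
    pred = np.full(n, -1, dtype=int)
    done = np.zeros(n, dtype=bool)
    heap: list[tuple[float, int]] = [(0.0, s)]
    while heap:
        d, u = heapq.heappop(heap)
        if done[u]:
            continue
        done[u] = True
        for v, w in adj[u]:
            nd = d + w
            # strict improvement or a tie resolved to the lower-index
            # predecessor, for deterministic path reconstruction
            if nd < dist[v] and not _tied(nd, dist[v]):
                dist[v] = nd
                pred[v] = u
                heapq.heappush(heap, (nd, v))
            elif _tied(nd, dist[v]) and pred[v] > u >= 0:
                pred[v] = u
    if not np.isfinite(dist[t]):
        return None, 0.0
    path_idx = [t]
    while path_idx[-1] != s:
        path_idx.append(int(pred[path_idx[-1]]))
    path_idx.reverse()
    prob = 1.0
    for a, b in zip(path_idx, path_idx[1:]):
        prob *= raw[(a, b)]
    return [net.nodes[i] for i in path_idx], prob


# ---------------------------------------------------------------------
# negative weights: Bellman-Ford-Moore with cycle certificate
# ---------------------------------------------------------------------

def detect_negative_cycle(net: EcoNetwork) -> NegativeCycleReport:
    """Bellman-Ford-Moore per source, certifying negative cycles.

    On an all-non-negative network this reproduces Dijkstra's distances.
    With negative weights it either returns finite distances (acyclic
    reachable subgraph) or the node sequence of a reachable
    negative-weight cycle — the failure mode of the −a transform, where a
    shortest-path search would keep circling the loop forever.
    """
    n = net.n_nodes
    arcs: list[tuple[int, int, float]] = []
    for u, v, w in net.edges:
        i, j = net.index(u), net.index(v)
        arcs.append((i, j, w))
        if not net.directed:
            arcs.append((j, i, w))

    dist_all = np.full((n, n), np.inf)
    for s in range(n):
        dist = np.full(n, np.inf)
        dist[s] = 0.0
        pred = np.full(n, -1, dtype=int)
        for _ in range(n - 1):
            changed = False
            for i, j, w in arcs:
                if np.isfinite(dist[i]) and dist[i] + w < dist[j]:
                    dist[j] = dist[i] + w
                    pred[j] = i
                    changed = True
            if not changed:
                break
        # one more round: any further relaxation certifies a cycle
        for i, j, w in arcs:
            if np.isfinite(dist[i]) and dist[i] + w < dist[j]:
                cycle = _extract_cycle(pred, j, i, n)
                return NegativeCycleReport(
                    nodes=net.nodes,
                    has_negative_cycle=True,
                    cycle=[net.nodes[k] for k in cycle],
                )
        dist_all[s] = dist
    return NegativeCycleReport(
        nodes=net.nodes, has_negative_cycle=False, dist=dist_all
    )


def _extract_cycle(pred: np.ndarray, j: int, i: int, n: int) -> list[int]:
    # walk predecessors n steps to land inside the cycle, then loop once
    pred = pred.copy()
    pred[j] = i
    x = j
    for _ in range(n):
        x = int(pred[x])
    cycle = [x]
    y = int(pred[x])
    while y != x:
        cycle.append(y)
        y = int(pred[y])
    cycle.reverse()
    return cycle


# ---------------------------------------------------------------------
# centralities
# ---------------------------------------------------------------------

def _brandes_bc(net: EcoNetwork) -> np.ndarray:
    """Brandes' accumulation of betweenness over all sources.

    Counts all shortest paths; endpoints excluded; raw (unnormalized)
    sums over ordered pairs, halved afterwards for undirected networks.
    """
    n = net.n_nodes
    adj = [
        [(v, _edge_weight(net, w)) for v, w in lst] for lst in net.adjacency_lists()
    ]
    bc = np.zeros(n)
    for s in range(n):
        dist = _dijkstra(adj, s, n)
        sigma = np.zeros(n)
        sigma[s] = 1.0
        preds: list[list[int]] = [[] for _ in range(n)]
        for u in range(n):
            if not np.isfinite(dist[u]):
                continue
            for v, w in adj[u]:
                if np.isfinite(dist[v]) and v != s and _tied(dist[u] + w, dist[v]):
                    preds[v].append(u)
        order = [v for v in np.argsort(dist, kind="stable") if np.isfinite(dist[v])]
        for v in order:
            for u in preds[v]:
                sigma[v] += sigma[u]
        delta = np.zeros(n)
        for v in reversed(order):
            for u in preds[v]:
                delta[u] += sigma[u] / sigma[v] * (1.0 + delta[v])
            if v != s:
                bc[v] += delta[v]
    if not net.directed:
        bc /= 2.0
    return bc


def betweenness(net: EcoNetwork) -> CentralityResult:
    """Raw betweenness BC(v) = sum over pairs of g_ij(v) / g_ij.

    All shortest paths are counted (never one arbitrary representative),
    endpoints are excluded, and no (N−1)(N−2) normalization is applied.
    Undirected networks sum over unordered pairs, directed over ordered.
    """
    _require_distance_like(net, "betweenness")
    bc = _brandes_bc(net)
    return CentralityResult(
        measure="BC",
        scores={node: float(x) for node, x in zip(net.nodes, bc)},
        weighted=net.semantics.kind is not SemanticsKind.BINARY,
        transform=_provenance(net),
    )


def stress(net: EcoNetwork) -> CentralityResult:
    """Raw stress SC(v) = number of shortest paths through v."""
    pr = shortest_paths(net)
    g = pr.pass_through()  # g[i, j, v]
    sc = g.sum(axis=(0, 1))
    if not net.directed:
        sc /= 2.0
    return CentralityResult(
        measure="SC",
        scores={node: float(x) for node, x in zip(net.nodes, sc)},
        weighted=net.semantics.kind is not SemanticsKind.BINARY,
        transform=_provenance(net),
    )


def closeness(net: EcoNetwork, policy: str = "component") -> CentralityResult:
    """Closeness CC(v) = (N − 1) / sum_j g_vj.

    Unreachable nodes make the raw formula degenerate, so a policy must
    be chosen and is recorded in the result:

    - ``component`` (default): CC within each connected component, with
      that component's size as N;
    - ``strict``: 0 for any node with an unreachable partner.

    Directed networks use out-distances.
    """
    if policy not in ("component", "strict"):
        raise ValueError(f"unknown closeness policy {policy!r}")
    pr = shortest_paths(net)
    n = net.n_nodes
    scores = np.zeros(n)
    for v in range(n):
        reach = np.isfinite(pr.dist[v])
        n_reach = int(reach.sum())  # includes v itself
        if n_reach < n and policy == "strict":
            scores[v] = 0.0
            continue
        if n_reach <= 1:
            scores[v] = 0.0
            continue
        scores[v] = (n_reach - 1) / pr.dist[v][reach].sum()
    return CentralityResult(
        measure="CC",
        scores={node: float(x) for node, x in zip(net.nodes, scores)},
        weighted=net.semantics.kind is not SemanticsKind.BINARY,
        transform=_provenance(net),
        policy=policy,
    )


def _provenance(net: EcoNetwork) -> Optional[TransformSpec]:
    t = net.metadata.get("transform")
    return TransformSpec.from_json(t) if t else None
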