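"""Shared fixtures and independent brute-force oracles.

The oracles enumerate *all simple paths* between node pairs and derive
distances, path counts and centralities from first principles, entirely
independent of the package's Dijkstra/Brandes machinery.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from econnect import EcoNetwork, EdgeSemantics

TOL = 1e-9


# ---------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------

def _arc_weights(net: EcoNetwork) -> dict[tuple[int, int], float]:
    unit = net.semantics.kind.value == "binary"
    arcs: dict[tuple[int, int], float] = {}
    for u, v, w in net.edges:
        i, j = net.index(u), net.index(v)
        w = 1.0 if unit else w
        arcs[(i, j)] = w
        if not net.directed:
            arcs[(j, i)] = w
    return arcs


def enumerate_simple_paths(net: EcoNetwork, s: int, t: int):
    """Yield (path, length) for every simple path from s to t."""
    arcs = _arc_weights(net)
    out: dict[int, list[int]] = {}
    for (i, j) in arcs:
        out.setdefault(i, []).append(j)
    stack = [(s, [s], 0.0)]
    while stack:
        u, path, length = stack.pop()
        if u == t:
            yield path, length
            continue
        for v in out.get(u, []):
            if v not in path:
                stack.append((v, path + [v], length + arcs[(u, v)]))


def brute_force_paths(net: EcoNetwork):
    """All-pairs (dist, sigma, shortest-path lists) by exhaustive search."""
    n = net.n_nodes
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    shortest: dict[tuple[int, int], list[list[int]]] = {}
    np.fill_diagonal(dist, 0.0)
    for s in range(n):
        sigma[s, s] = 1.0
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            paths = list(enumerate_simple_paths(net, s, t))
            if not paths:
                continue
            best = min(length for _, length in paths)
            tied = [
                p for p, length in paths
                if abs(length - best) <= TOL * max(1.0, abs(best))
            ]
            dist[s, t] = best
            sigma[s, t] = len(tied)
            shortest[(s, t)] = tied
    return dist, sigma, shortest


def brute_force_centralities(net: EcoNetwork):
    """BC, SC, CC (component policy) straight from the definitions."""
    n = net.n_nodes
    dist, sigma, shortest = brute_force_paths(net)
    bc = np.zeros(n)
    sc = np.zeros(n)
    for (s, t), paths in shortest.items():
        if not net.directed and s > t:
            continue  # unordered pairs once
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / len(paths)
            sc[v] += through
    cc = np.zeros(n)
    for v in range(n):
        reach = np.isfinite(dist[v])
        k = int(reach.sum())
        if k > 1:
            cc[v] = (k - 1) / dist[v][reach].sum()
    return bc, sc, cc


def brute_force_max_product(net: EcoNetwork, s: int, t: int) -> float:
    """Maximum product of edge probabilities over all simple paths."""
    arcs = _arc_weights(net)
    best = 0.0
    for path, _ in enumerate_simple_paths(net, s, t):
        prob = math.prod(arcs[(a, b)] for a, b in zip(path, path[1:]))
        best = max(best, prob)
    return best


# ---------------------------------------------------------------------
# random test networks
# ---------------------------------------------------------------------

def random_network(rng: np.random.Generator, n_max: int = 8) -> EcoNetwork:
    """Random connected-ish network: mixed binary/weighted, mixed direction."""
    n = int(rng.integers(3, n_max + 1))
    directed = bool(rng.random() < 0.3)
    binary = bool(rng.random() < 0.4)
    nodes = tuple(f"n{i}" for i in range(n))
    edges = []
    for i in range(n):
        for j in range(n):
            if (directed and i != j) or (not directed and i < j):
                if rng.random() < 0.45:
                    w = 1.0 if binary else float(rng.uniform(0.1, 2.0))
                    edges.append((nodes[i], nodes[j], w))
    sem = EdgeSemantics.binary() if binary else EdgeSemantics.distance_like()
    return EcoNetwork(nodes=nodes, edges=edges, directed=directed, semantics=sem)


def random_probability_network(
    rng: np.random.Generator, n_max: int = 8
) -> EcoNetwork:
    n = int(rng.integers(3, n_max + 1))
    nodes = tuple(f"n{i}" for i in range(n))
    edges = [
        (nodes[i], nodes[j], float(rng.uniform(0.05, 1.0)))
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < 0.5
    ]
    return EcoNetwork(
        nodes=nodes, edges=edges, directed=False,
        semantics=EdgeSemantics.probability(independence=True),
    )


# ---------------------------------------------------------------------
# shared fixtures
# ---------------------------------------------------------------------

@pytest.fixture
def star4() -> EcoNetwork:
    """4-node star: hub c, leaves l1..l3, unit weights."""
    return EcoNetwork(
        nodes=("c", "l1", "l2", "l3"),
        edges=[("c", "l1", 1.0), ("c", "l2", 1.0), ("c", "l3", 1.0)],
        semantics=EdgeSemantics.binary(),
    )


@pytest.fixture
def cycle4() -> EcoNetwork:
    """4-cycle with unit weights."""
    return EcoNetwork(
        nodes=("a", "b", "c", "d"),
        edges=[("a", "b", 1.0), ("b", "c", 1.0), ("c", "d", 1.0),
               ("d", "a", 1.0)],
        semantics=EdgeSemantics.binary(),
    )


@pytest.fixture
def path3() -> EcoNetwork:
    """Path graph a-b-c with unit weights."""
    return EcoNetwork(
        nodes=("a", "b", "c"),
        edges=[("a", "b", 1.0), ("b", "c", 1.0)],
        semantics=EdgeSemantics.binary(),
    )
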