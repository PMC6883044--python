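"""Deterministic generators for toy networks and synthetic test data.

The toy networks reproduce the classic demonstrations of shortest-path
pitfalls — a two-route city network where flow totals and path lengths
disagree, a primate/parasite affinity network where raw and inverted
weights crown different key individuals, and a marine food web whose
carbon-flow cycle breaks negation-based weight reversal.  Edge values for
the primate and food-web toys are representative invented constants
chosen to exhibit the documented qualitative behaviour; they are not
empirical data.

The synthetic landscape generator builds elevation rasters from Gaussian
mountain "bumps" with a known patch count, standing in for real relief
data so the whole raster-to-index pipeline is testable offline.  The
random bipartite generator emulates host x parasite incidence tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .landscape import ElevationRaster
from .netcore import EcoNetwork, EdgeSemantics

__all__ = [
    "SyntheticTruth",
    "toy_cities",
    "toy_primates",
    "toy_foodchain",
    "synthetic_dem",
    "random_bipartite",
    "GENERATORS",
]


@dataclass
class SyntheticTruth:
    """Ground truth a generator knows about its own output."""

    generator: str
    seed: Optional[int] = None
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------
# toy networks
# ---------------------------------------------------------------------

CITY_NODES = ("Busan", "Chicago", "Copenhagen", "Marseille", "Almeria")

#: the two competing routes between the end cities
CITY_TWO_EDGE_PATH = ("Busan", "Chicago", "Almeria")
CITY_THREE_EDGE_PATH = ("Busan", "Copenhagen", "Marseille", "Almeria")

_CITY_VARIANTS = {
    # researcher-movement counts: two-edge total 10, three-edge total 30;
    # the per-edge split (5+5, 10+10+10) is the symmetric choice
    "flow_counts": {
        "weights": (5.0, 5.0, 10.0, 10.0, 10.0),
        "semantics": EdgeSemantics.flow_like(),
    },
    # transfer probabilities: strong three-edge route (0.9 each) vs a
    # weak two-edge one (0.1 each)
    "prob_high": {
        "weights": (0.1, 0.1, 0.9, 0.9, 0.9),
        "semantics": EdgeSemantics.probability(independence=True),
    },
    # probabilities spanning orders of magnitude near 1: 1-1e-5 on the
    # two-edge route vs 1-1e-3 on the three-edge one
    "prob_magnitudes": {
        "weights": (1 - 1e-5, 1 - 1e-5, 1 - 1e-3, 1 - 1e-3, 1 - 1e-3),
        "semantics": EdgeSemantics.probability(independence=True),
    },
}


def toy_cities(variant: str) -> tuple[EcoNetwork, SyntheticTruth]:
    """Five-city network with a two-edge and a three-edge route.

    Busan and Almeria are connected by a two-edge path through Chicago
    and a three-edge path through Copenhagen and Marseille.  The variant
    fixes the edge weights (see module docstring); in every variant the
    *three-edge* path carries the most flow, which is exactly what naive
    shortest-path runs on untransformed (or constant-shifted) weights get
    wrong.
    """
    if variant not in _CITY_VARIANTS:
        raise ValueError(
            f"unknown variant {variant!r}; choose from {sorted(_CITY_VARIANTS)}"
        )
    cfg = _CITY_VARIANTS[variant]
    w = cfg["weights"]
    edges = [
        ("Busan", "Chicago", w[0]),
        ("Chicago", "Almeria", w[1]),
        ("Busan", "Copenhagen", w[2]),
        ("Copenhagen", "Marseille", w[3]),
        ("Marseille", "Almeria", w[4]),
    ]
    net = EcoNetwork(
        nodes=CITY_NODES, edges=edges, directed=False, semantics=cfg["semantics"]
    )
    net.metadata["node_edge_definition"] = (
        "nodes: cities; edges: movement of researchers between cities "
        f"({variant} weighting)"
    )
    two = sum(w[:2])
    three = sum(w[2:])
    truth = SyntheticTruth(
        generator=f"toy_cities[{variant}]",
        truth={
            "source": "Busan",
            "target": "Almeria",
            "two_edge_path": list(CITY_TWO_EDGE_PATH),
            "three_edge_path": list(CITY_THREE_EDGE_PATH),
            "two_edge_total": two,
            "three_edge_total": three,
            # flow totals: 30 vs 10 — the three-edge route dominates
            "max_flow_path": list(CITY_THREE_EDGE_PATH),
        },
    )
    return net, truth


#: invented affinity weights (proportion of shared parasites) for the
#: four-primate toy; representative constants, not empirical data.
#: A shares many parasites with C and D, B shares few with everyone —
#: so raw weights (mistaken as distances) crown B, inverted weights A.
PRIMATE_EDGES = [
    ("A", "B", 0.15),
    ("A", "C", 0.90),
    ("A", "D", 0.80),
    ("B", "C", 0.10),
    ("B", "D", 0.10),
    ("C", "D", 0.30),
]


def toy_primates() -> tuple[EcoNetwork, SyntheticTruth]:
    """Four-primate social-affinity network (shared-parasite weights).

    Most of the strong-affinity paths run through primate A.  Running BC
    or CC directly on the raw weights instead identifies primate B —
    shortest paths then chase the *weakest* links.  After the 1/a
    reversal, A is correctly recovered as the key primate.
    """
    net = EcoNetwork(
        nodes=("A", "B", "C", "D"),
        edges=list(PRIMATE_EDGES),
        directed=False,
        semantics=EdgeSemantics.flow_like(),
    )
    net.metadata["node_edge_definition"] = (
        "nodes: primates; edges: proportion of shared parasites"
    )
    truth = SyntheticTruth(
        generator="toy_primates",
        truth={"raw_key_node": "B", "transformed_key_node": "A"},
    )
    return net, truth


#: invented carbon-flow values (arbitrary carbon units) for the marine
#: food-web toy; representative constants, not empirical data.  The
#: anchovy (2nd-order consumer) funnels both grazing chains toward both
#: top predators; the detrital loop anchovy->tuna->detritus->anchovy
#: provides the cycle that defeats negation-based weight reversal.
FOODCHAIN_EDGES = [
    ("Diatoms", "Copepods", 100.0),
    ("Flagellates", "Krill", 80.0),
    ("Copepods", "Anchovy", 60.0),
    ("Krill", "Anchovy", 50.0),
    ("Anchovy", "Tuna", 25.0),
    ("Anchovy", "Seabird", 20.0),
    ("Tuna", "Detritus", 15.0),
    ("Detritus", "Anchovy", 5.0),
]


def toy_foodchain() -> tuple[EcoNetwork, SyntheticTruth]:
    """Directed marine food web with a detrital carbon cycle.

    Carbon flow is directly proportional to connection strength, so the
    weights must be reversed before path analysis.  Negating them (-a)
    turns the detrital loop into a negative cycle on which shortest-path
    searches never converge; the 1/a reversal instead works and uniquely
    identifies the 2nd-order consumer (the anchovy) as the key node
    pivoting the carbon flow.
    """
    nodes = (
        "Diatoms", "Flagellates", "Copepods", "Krill",
        "Anchovy", "Tuna", "Seabird", "Detritus",
    )
    net = EcoNetwork(
        nodes=nodes,
        edges=list(FOODCHAIN_EDGES),
        directed=True,
        semantics=EdgeSemantics.flow_like(),
    )
    net.metadata["node_edge_definition"] = (
        "nodes: trophic compartments; edges: carbon flow (arbitrary units)"
    )
    truth = SyntheticTruth(
        generator="toy_foodchain",
        truth={
            "key_node_inverse": "Anchovy",
            "cycle_nodes": ["Anchovy", "Tuna", "Detritus"],
        },
    )
    return net, truth


# ---------------------------------------------------------------------
# synthetic landscapes
# ---------------------------------------------------------------------

#: study-condition defaults for the landscape pipeline: 15 km habitat
#: grain, a species living between 500 and 2000 m, kernel decay 0.03/km
#: and a 100 km dispersal-distance threshold
DEFAULT_CELL_SIZE = 15.0
DEFAULT_ZMIN = 500.0
DEFAULT_ZMAX = 2000.0
SEA_LEVEL = -50.0


def synthetic_dem(
    rows: int = 60,
    cols: int = 80,
    n_bumps: int = 5,
    seed: int = 0,
    cell_size: float = DEFAULT_CELL_SIZE,
    zmin: float = DEFAULT_ZMIN,
    zmax: float = DEFAULT_ZMAX,
) -> tuple[ElevationRaster, SyntheticTruth]:
    """Elevation raster of Gaussian mountain bumps on a shallow sea.

    Bump peaks lie inside the habitat band, and centres are rejection-
    sampled far enough apart that masking the band yields exactly
    ``n_bumps`` patches: every bump's elevation falls below half the
    band floor before the next bump's footprint begins, so footprints
    can never merge.  Deterministic in (all) parameters.
    """
    if n_bumps < 1:
        raise ValueError("n_bumps must be >= 1")
    rng = np.random.default_rng(seed)
    values = np.full((rows, cols), SEA_LEVEL)
    yy, xx = np.mgrid[0:rows, 0:cols]

    centers: list[tuple[float, float]] = []
    radii: list[float] = []  # cells at which a bump alone drops to zmin/2
    peaks = rng.uniform(0.6 * zmax, 0.9 * zmax, size=n_bumps)
    sigmas = rng.uniform(1.5, 3.0, size=n_bumps)
    max_attempts = 2000
    for b in range(n_bumps):
        # footprint radius where the lone bump falls to half the band floor
        r_half = sigmas[b] * np.sqrt(2 * np.log(peaks[b] / (zmin / 2)))
        placed = False
        for _ in range(max_attempts):
            cy = rng.uniform(r_half + 1, rows - r_half - 1)
            cx = rng.uniform(r_half + 1, cols - r_half - 1)
            ok = all(
                np.hypot(cy - oy, cx - ox) >= r_half + r_o + 2
                for (oy, ox), r_o in zip(centers, radii)
            )
            if ok:
                centers.append((cy, cx))
                radii.append(r_half)
                placed = True
                break
        if not placed:
            raise ValueError(
                f"cannot place {n_bumps} non-overlapping bumps on a "
                f"{rows}x{cols} grid; enlarge the grid or reduce n_bumps"
            )
        cy, cx = centers[-1]
        values = values + peaks[b] * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigmas[b] ** 2)
        )

    raster = ElevationRaster(values=values, cell_size=cell_size)
    truth = SyntheticTruth(
        generator="synthetic_dem",
        seed=seed,
        truth={
            "n_patches": n_bumps,
            "centers": centers,
            "zmin": zmin,
            "zmax": zmax,
            "cell_size": cell_size,
        },
    )
    return raster, truth


# ---------------------------------------------------------------------
# bipartite incidence
# ---------------------------------------------------------------------

def random_bipartite(
    n_rows: int, n_cols: int, fill: float, seed: int = 0
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Random binary host x parasite incidence table.

    Each cell is 1 with probability ``fill``.  The truth records every
    pairwise intersection count, computed row-set by row-set on the
    generator side, for checking the unipartite projection.
    """
    if not 0 < fill < 1:
        raise ValueError("fill must be in (0, 1)")
    rng = np.random.default_rng(seed)
    table = (rng.random((n_rows, n_cols)) < fill).astype(int)
    rows = [f"host{i + 1}" for i in range(n_rows)]
    cols = [f"parasite{j + 1}" for j in range(n_cols)]
    df = pd.DataFrame(table, index=rows, columns=cols)
    sets = {r: {c for c in cols if df.loc[r, c]} for r in rows}
    counts = {
        (rows[i], rows[j]): len(sets[rows[i]] & sets[rows[j]])
        for i in range(n_rows)
        for j in range(i + 1, n_rows)
    }
    truth = SyntheticTruth(
        generator="random_bipartite",
        seed=seed,
        truth={"intersections": counts},
    )
    return df, truth


#: registry for the CLI `fixtures` subcommand
GENERATORS = {
    "cities-flow": lambda seed: toy_cities("flow_counts"),
    "cities-prob-high": lambda seed: toy_cities("prob_high"),
    "cities-prob-magnitudes": lambda seed: toy_cities("prob_magnitudes"),
    "primates": lambda seed: toy_primates(),
    "foodchain": lambda seed: toy_foodchain(),
    "dem": lambda seed: synthetic_dem(seed=seed),
    "bipartite": lambda seed: random_bipartite(10, 15, 0.3, seed=seed),
}
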