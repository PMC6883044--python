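"""Raster-to-habitat-graph pipeline and landscape connectivity indices.

The pipeline emulates a classic landscape-connectivity workflow: an
elevation raster is coarse-grained to the organism's typical habitat
grain, cells inside the species' elevation band become habitat, connected
cells are labelled into patches, and inter-patch boundary distances feed
an exponential dispersal kernel p_ij = exp(-alpha * d_ij).  On the
resulting patch graph two whole-landscape indices are computed:

- IIC (integral index of connectivity): patch-area products discounted by
  the hop count nl_ij of the shortest path in the *binary* patch graph
  (patches adjacent when d_ij <= a dispersal-distance threshold),
  normalised by the squared landscape area.
- PC (probability of connectivity): patch-area products weighted by the
  maximum product of dispersal probabilities over all paths (the direct
  step included), normalised the same way.

Geometry is planar on the grid: these are abstract/synthetic landscapes,
not geodesic ones.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .paths import CentralityResult

__all__ = [
    "ElevationRaster",
    "PatchSet",
    "ConnectivityMatrix",
    "KernelParams",
    "TopKOverlap",
    "read_ascii_grid",
    "write_ascii_grid",
    "coarse_grain",
    "habitat_mask",
    "label_patches",
    "interpatch_distances",
    "dispersal_probabilities",
    "hop_counts",
    "iic",
    "pc",
    "compare_topk",
]


@dataclass
class ElevationRaster:
    """Rectangular elevation grid (metres) with square cells (km).

    Rows are stored north-to-south (row 0 is the top), matching the ESRI
    ASCII grid convention.
    """

    values: np.ndarray  # 2-D float array, elevation in m
    cell_size: float  # km
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    nodata: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area(self) -> float:
        """Area of one cell in km^2."""
        return self.cell_size**2

    @property
    def total_area(self) -> float:
        """Total landscape area A_L in km^2."""
        return self.values.size * self.cell_area

    def nodata_mask(self) -> np.ndarray:
        if self.nodata is None:
            return np.zeros(self.shape, dtype=bool)
        return self.values == self.nodata


@dataclass
class PatchSet:
    """Labelled habitat patches extracted from a raster.

    ``labels`` assigns 0 to non-habitat and 1..n to patches.  Areas are
    cell count times cell area; boundary cells are member cells with at
    least one non-member 4-neighbour (grid edges count as non-member).
    """

    labels: np.ndarray  # int array, 0 = background
    cell_size: float
    areas: np.ndarray  # km^2, index p-1 for patch p
    boundaries: list[np.ndarray]  # per patch, (k, 2) array of (row, col)
    total_area: float  # A_L, km^2

    @property
    def n_patches(self) -> int:
        return len(self.areas)

    def patch_ids(self) -> list[str]:
        return [str(p) for p in range(1, self.n_patches + 1)]

    def centroids(self) -> np.ndarray:
        """Per-patch mean cell coordinates (row, col), in cells."""
        out = np.zeros((self.n_patches, 2))
        for p in range(1, self.n_patches + 1):
            rows, cols = np.nonzero(self.labels == p)
            out[p - 1] = rows.mean(), cols.mean()
        return out


@dataclass
class ConnectivityMatrix:
    """Inter-patch distances and dispersal structure.

    Filled incrementally by the pipeline: ``d`` (boundary-to-boundary
    distance, km), ``p`` (dispersal probability), ``adjacency`` and
    ``nl`` (hop counts in the thresholded binary graph), ``pdot`` (max
    product probability over all paths).
    """

    d: np.ndarray
    p: Optional[np.ndarray] = None
    adjacency: Optional[np.ndarray] = None
    nl: Optional[np.ndarray] = None
    pdot: Optional[np.ndarray] = None
    threshold: Optional[float] = None


@dataclass(frozen=True)
class KernelParams:
    """Exponential dispersal kernel p = exp(-alpha * d); alpha in 1/km."""

    alpha: float = 0.03

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


# ---------------------------------------------------------------------
# raster I/O: ESRI ASCII grid
# ---------------------------------------------------------------------

def read_ascii_grid(path: Union[str, Path], cell_size_km: Optional[float] = None) -> ElevationRaster:
    """Read an ESRI ASCII grid.

    The format's ``cellsize`` is unit-less; by default it is taken to be
    km (the package's working unit), or override with ``cell_size_km``.
    """
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value"):
                header[key] = float(parts[1])
            else:
                rows.append([float(x) for x in parts])
    values = np.array(rows, dtype=float)
    ncols = int(header.get("ncols", values.shape[1]))
    nrows = int(header.get("nrows", values.shape[0]))
    if values.shape != (nrows, ncols):
        raise ValueError(
            f"{path}: data block {values.shape} does not match header "
            f"({nrows}, {ncols})"
        )
    return ElevationRaster(
        values=values,
        cell_size=cell_size_km if cell_size_km is not None else header.get("cellsize", 1.0),
        xllcorner=header.get("xllcorner", 0.0),
        yllcorner=header.get("yllcorner", 0.0),
        nodata=header.get("nodata_value"),
    )


def write_ascii_grid(raster: ElevationRaster, path: Union[str, Path]) -> None:
    nrows, ncols = raster.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {raster.xllcorner}\n")
        fh.write(f"yllcorner {raster.yllcorner}\n")
        fh.write(f"cellsize {raster.cell_size}\n")
        if raster.nodata is not None:
            fh.write(f"NODATA_value {raster.nodata}\n")
        for row in raster.values:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


# ---------------------------------------------------------------------
# pipeline steps
# ---------------------------------------------------------------------

def coarse_grain(raster: ElevationRaster, target_cell_size: float) -> ElevationRaster:
    """Block-aggregate elevation by mean to a coarser cell size.

    The target must be an integer multiple of the native cell size;
    partial blocks at the right/bottom edges average over the cells
    available.  Nodata cells are excluded from block means (a block of
    only nodata stays nodata).
    """
    if target_cell_size < raster.cell_size:
        raise ValueError("target cell size must be >= native cell size")
    factor = target_cell_size / raster.cell_size
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            "target cell size must be an integer multiple of the native one"
        )
    f = int(round(factor))
    if f == 1:
        return ElevationRaster(
            raster.values.copy(), raster.cell_size, raster.xllcorner,
            raster.yllcorner, raster.nodata,
        )
    nrows, ncols = raster.shape
    out_r = math.ceil(nrows / f)
    out_c = math.ceil(ncols / f)
    valid = ~raster.nodata_mask()
    vals = np.where(valid, raster.values, 0.0)
    out = np.zeros((out_r, out_c))
    for i in range(out_r):
        for j in range(out_c):
            block_v = vals[i * f:(i + 1) * f, j * f:(j + 1) * f]
            block_m = valid[i * f:(i + 1) * f, j * f:(j + 1) * f]
            k = block_m.sum()
            if k == 0:
                out[i, j] = raster.nodata if raster.nodata is not None else np.nan
            else:
                out[i, j] = block_v.sum() / k
    return ElevationRaster(
        out, target_cell_size, raster.xllcorner, raster.yllcorner, raster.nodata
    )


def habitat_mask(raster: ElevationRaster, zmin: float, zmax: float) -> np.ndarray:
    """Cells inside the elevation band [zmin, zmax], inclusive both ends.

    Nodata cells are never habitat.
    """
    if zmin >= zmax:
        raise ValueError("zmin must be below zmax")
    mask = (raster.values >= zmin) & (raster.values <= zmax)
    mask &= ~raster.nodata_mask()
    return mask


_STRUCTURE = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]),
    8: np.ones((3, 3), dtype=int),
}


def label_patches(
    mask: np.ndarray, cell_size: float, connectivity: int = 8
) -> PatchSet:
    """Connected-component labelling of a habitat mask into patches.

    8-connectivity (diagonals count) is the default, standard for habitat
    rasters; 4-connectivity is available.  An empty mask yields a valid
    empty PatchSet.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_STRUCTURE[connectivity])
    cell_area = cell_size**2
    areas = np.zeros(n)
    boundaries: list[np.ndarray] = []
    # a member cell is boundary if any 4-neighbour (or the grid edge) is
    # outside the patch's mask
    padded = np.pad(mask, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    for p in range(1, n + 1):
        member = labels == p
        areas[p - 1] = member.sum() * cell_area
        edge = member & ~interior
        boundaries.append(np.argwhere(edge))
    return PatchSet(
        labels=labels,
        cell_size=cell_size,
        areas=areas,
        boundaries=boundaries,
        total_area=mask.size * cell_area,
    )


def interpatch_distances(patches: PatchSet) -> ConnectivityMatrix:
    """Minimum Euclidean distance (km) between patch boundary-cell centres."""
    if patches.n_patches < 1:
        raise ValueError("need at least one patch")
    n = patches.n_patches
    pts = [b.astype(float) * patches.cell_size for b in patches.boundaries]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = cdist(pts[i], pts[j]).min()
    return ConnectivityMatrix(d=d)


def dispersal_probabilities(
    cm: ConnectivityMatrix, kernel: KernelParams
) -> ConnectivityMatrix:
    """Fill p_ij = exp(-alpha d_ij) for i != j; p_ii = 1."""
    p = np.exp(-kernel.alpha * cm.d)
    np.fill_diagonal(p, 1.0)
    cm.p = p
    return cm


def hop_counts(cm: ConnectivityMatrix, threshold: float) -> ConnectivityMatrix:
    """Binary adjacency (d_ij <= threshold) and BFS hop counts nl_ij.

    Unreachable pairs get nl = inf.
    """
    n = cm.d.shape[0]
    adj = (cm.d <= threshold) & ~np.eye(n, dtype=bool)
    nl = np.full((n, n), np.inf)
    neighbours = [np.nonzero(adj[i])[0] for i in range(n)]
    for s in range(n):
        nl[s, s] = 0.0
        frontier = [s]
        depth = 0
        while frontier:
            depth += 1
            nxt = []
            for u in frontier:
                for v in neighbours[u]:
                    if not np.isfinite(nl[s, v]):
                        nl[s, v] = depth
                        nxt.append(v)
            frontier = nxt
    cm.adjacency = adj
    cm.nl = nl
    cm.threshold = threshold
    return cm


def _max_product_matrix(p: np.ndarray) -> np.ndarray:
    """Max-product path probabilities via Dijkstra on -log p.

    The direct edge is always among the candidate paths; the diagonal
    is 1 by definition.
    """
    n = p.shape[0]
    with np.errstate(divide="ignore"):
        cost = -np.log(p)
    np.fill_diagonal(cost, np.inf)
    pdot = np.zeros((n, n))
    for s in range(n):
        dist = np.full(n, np.inf)
        dist[s] = 0.0
        done = np.zeros(n, dtype=bool)
        heap = [(0.0, s)]
        while heap:
            dd, u = heapq.heappop(heap)
            if done[u]:
                continue
            done[u] = True
            for v in range(n):
                if not done[v] and np.isfinite(cost[u, v]):
                    nd = dd + cost[u, v]
                    if nd < dist[v]:
                        dist[v] = nd
                        heapq.heappush(heap, (nd, v))
        pdot[s] = np.exp(-dist)
    np.fill_diagonal(pdot, 1.0)
    return pdot


# ---------------------------------------------------------------------
# landscape indices
# ---------------------------------------------------------------------

def iic(patches: PatchSet, cm: ConnectivityMatrix, threshold: float) -> float:
    """Integral index of connectivity.

    IIC = [sum_i sum_j a_i a_j / (1 + nl_ij)] / A_L^2 over all ordered
    pairs including i = j (nl_ii = 0); terms for mutually unreachable
    patches contribute 0.
    """
    if patches.total_area <= 0:
        raise ValueError("landscape area A_L must be positive")
    cm = hop_counts(cm, threshold)
    a = patches.areas
    with np.errstate(divide="ignore"):
        contrib = np.where(
            np.isfinite(cm.nl), np.outer(a, a) / (1.0 + cm.nl), 0.0
        )
    return float(contrib.sum() / patches.total_area**2)


def pc(patches: PatchSet, cm: ConnectivityMatrix) -> float:
    """Probability of connectivity.

    PC = [sum_i sum_j a_i a_j pdot_ij] / A_L^2 where pdot_ij is the
    maximum product of dispersal probabilities over all paths between i
    and j (the single-step path included), and pdot_ii = 1.
    """
    if patches.total_area <= 0:
        raise ValueError("landscape area A_L must be positive")
    if cm.p is None:
        raise ValueError("dispersal probabilities not filled; run "
                         "dispersal_probabilities first")
    cm.pdot = _max_product_matrix(cm.p)
    a = patches.areas
    return float((np.outer(a, a) * cm.pdot).sum() / patches.total_area**2)


# ---------------------------------------------------------------------
# binary-vs-weighted comparison
# ---------------------------------------------------------------------

@dataclass
class TopKOverlap:
    """Agreement between two rankings' top-k node sets."""

    k: int
    top_a: list[str]
    top_b: list[str]
    intersection: set[str] = field(default_factory=set)
    overlap: int = 0
    jaccard: float = 0.0


def compare_topk(
    scores_a: CentralityResult, scores_b: CentralityResult, k: int
) -> TopKOverlap:
    """Top-k set overlap between two centrality results.

    Ties are broken by node identifier (deterministic and reported via
    the ordered top lists).
    """
    if set(scores_a.scores) != set(scores_b.scores):
        raise ValueError("centrality results cover different node sets")
    n = len(scores_a.scores)
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available nodes")
    top_a = scores_a.ranking()[:k]
    top_b = scores_b.ranking()[:k]
    inter = set(top_a) & set(top_b)
    union = set(top_a) | set(top_b)
    return TopKOverlap(
        k=k,
        top_a=top_a,
        top_b=top_b,
        intersection=inter,
        overlap=len(inter),
        jaccard=len(inter) / len(union) if union else 1.0,
    )
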