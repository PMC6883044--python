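# Methods

## Edge-weight semantics and the transformation protocol

Every `EcoNetwork` carries one of four weight declarations:

| semantics       | meaning                                   | shortest paths |
|-----------------|-------------------------------------------|----------------|
| `binary`        | presence/absence, unit weights            | usable directly |
| `distance_like` | grows with separation (cost, time)        | usable directly |
| `flow_like`     | grows with association strength           | must be reversed |
| `probability`   | per-edge success probability in (0, 1]    | must be reversed; carries an `independence` flag |

The declaration is supplied by the analyst, never inferred from the
data: whether a `0.7` is a probability or a resistance is not a property
of the number. Path routines (`shortest_paths`, the centralities)
refuse flow-proportional inputs outright rather than producing
longest-flow paths.

`recommend_transform` implements the decision scheme: binary and
distance-like weights pass unchanged; independent probabilities get
`log(1/a)`, which maps the product of path probabilities onto a sum of
distances and therefore makes Dijkstra find the *most probable* path;
other flow-like weights get `1/a`. Probability networks without an
explicit independence declaration are refused, and non-independent
probabilities are refused too — the product rule is simply invalid
there, and the package does not guess an alternative.

All logarithms are natural: the base rescales every distance by the
same factor and can never change which path attains the minimum.

### Diagnostics

`check_transform_safety` is pure (never raises) and emits:

- `HOP_COUNT_BIAS` — for `C − a` and `1 − a`. These are equivalent to
  adding a constant to every edge, which biases the search toward paths
  with fewer edges. The transforms stay available (they are common
  practice and the package must be able to reproduce their failure
  modes), but always tagged.
- `MAGNITUDE_SPAN` — same kinds when max/min weight ≥ 100: with weights
  spanning orders of magnitude the complement transform mis-ranks paths
  even when it "works" locally. The ratio 100 (two decades) is the
  package's own threshold for "spanning different orders of magnitude".
- `NEGATIVE_OUTPUT` (always blocking) — any transformed weight would be
  negative, making shortest paths undefined or non-convergent.
- `NO_TRANSFORM_ON_FLOW` / `TRANSFORM_ON_DISTANCE` — identity requested
  on flow-proportional weights, or a reversing transform requested on
  weights that are already distances.

Domain guards are structural: `log(1/a)` is restricted to (0, 1]
(weights above 1 must be normalized by the caller or routed to `1/a`),
`1 − a` to [0, 1], `C − a` requires `C ≥ max a`, and
`log((1−a)/a)` is admitted only on (0, 0.5] so its output is
non-negative — the literature lists the logit form without a guard, and
restricting the domain is this package's way of keeping it safe. `−a`
is constructible only with `unsafe=True`, for demonstrating the
negative-cycle failure. `exp(−a)` is implemented without special
diagnostics; it is listed in the literature but has no documented
failure mode of its own.

## Shortest paths and centralities

Distances come from a binary-heap Dijkstra per source (unit weights for
binary networks). The number of distinct shortest paths `σ_ij` comes
from the shortest-path DAG: edge (u, v) belongs to the DAG when
`dist[u] + w ≈ dist[v]` under a relative tie tolerance of 1e-9 on path
length. The tolerance matters — `σ` is a count, and float weight sums
make exact equality meaningless — so it is fixed, documented, and the
same everywhere (including the `g_ij(v)` pass-through tallies, computed
via the identity `g_ij(v) = σ_iv σ_vj` when `d_iv + d_vj = d_ij`).

Betweenness uses Brandes' dependency accumulation; stress uses the
pass-through identity (counts are exact integers); both count **all**
shortest paths, never one arbitrary representative — the one-vs-all
choice changes results and is therefore fixed and echoed in every
`CentralityResult`. Scores are raw sums exactly as the classic formulas
state (no (N−1)(N−2) normalization), over unordered pairs for
undirected networks and ordered pairs for directed ones. Closeness on
disconnected networks needs a policy: `component` (default) computes
CC within each connected component using the component size as N;
`strict` returns 0 for any node with an unreachable partner. The policy
rides along in the result. Directed closeness uses out-distances.

Negative weights route to `detect_negative_cycle` (Bellman–Ford–Moore
per source, n−1 relaxation rounds plus one detection round); a further
relaxation yields a cycle certificate extracted by walking predecessors
n steps and looping. On non-negative inputs it reproduces Dijkstra's
distances exactly, which is tested.

`max_product_path` reconstructs one optimal path (ties resolved to the
lowest-index predecessor, deterministically) and returns the product of
the *original* probabilities along it, so no exp/log round-trip error
accumulates in the reported probability.

## Landscape pipeline

The pipeline emulates a topographic habitat analysis: coarse-grain the
elevation raster by block mean to the organism's habitat grain, mask an
elevation band, label connected habitat cells into patches, and build
the patch graph.

Parameter defaults are the emulated study conditions: 15 km cells,
habitat band 500–2000 m, kernel decay α = 0.03 km⁻¹, adjacency
threshold 100 km. Notes on each:

- **Band inclusivity**: "between 500 and 2000 m" is read as inclusive
  at both ends; cells equal to either bound are habitat.
- **Connectivity**: 8-connectivity (diagonals count) is the labelling
  default, standard for habitat rasters; 4-connectivity is an option.
  Labelling delegates to `scipy.ndimage.label`; tests check it against
  an independent flood-fill.
- **Distances** are planar Euclidean distances between boundary-cell
  centres (a boundary cell has at least one non-member 4-neighbour,
  grid edges counting as non-member). These are abstract grids, not
  geodesics; a great-circle option would only matter for real-world
  rasters and is left as future work.
- **Kernel**: `p_ij = exp(−α d_ij)`. Note that α = 0.03 km⁻¹ implies a
  *median* dispersal distance of ln 2 / 0.03 ≈ 23 km, not 100 km; the
  kernel is taken as printed and any calibration of α against a target
  dispersal distance is the caller's job.
- **Binary patch graph**: patches are adjacent when `d_ij ≤ threshold`
  (default 100 km, the dispersal distance of the emulated species).
  Hop counts `nl_ij` are BFS depths in that graph.

IIC sums `a_i a_j / (1 + nl_ij)` over **ordered** pairs including
`i = j` (`nl_ii = 0`), divides by `A_L²`; unreachable pairs contribute
0. PC uses `ṗ_ij`, the maximum product of dispersal probabilities over
all paths, computed by Dijkstra on `−log p` over the dense probability
matrix — the direct edge is always a candidate, so `ṗ_ij ≥ p_ij`, and
`ṗ_ii = 1`. `A_L` is the full raster area, so both indices live in
(0, 1].

`compare_topk` reports top-k sets, intersection and Jaccard overlap,
with ties broken deterministically by node identifier.

## Synthetic data

`synthetic_dem` places Gaussian mountain bumps (peaks drawn in
0.6–0.9 × the band ceiling, σ 1.5–3 cells) on a −50 m sea. Centres are
rejection-sampled so that each bump's footprint — out to where the lone
bump drops to *half* the band floor — clears every other footprint by
two cells; summed tails at any midpoint therefore stay below the band
floor and the banded mask yields exactly `n_bumps` patches. Parameter
combinations that cannot be packed raise rather than silently merging
patches. Everything is a pure function of the arguments (seed
included).

What the generator does *not* emulate: irregular patch shapes, nodata
holes, elevation noise, or coastline effects. Passing tests show the
pipeline arithmetic is right on landscapes with known structure, not
that any particular real region has a given patch count.

`toy_cities` uses the documented flow totals (10 on the two-edge route,
30 on the three-edge route, split symmetrically 5+5 and 10+10+10 across
edges; only path totals are asserted). The primate and food-web toys
print no canonical edge values anywhere, so their constants are
invented to realise the documented qualitative behaviour and are tested
by exhaustive enumeration: the primate weights make raw-weight BC/CC
crown primate B and 1/a-reversed BC/CC crown primate A; the food-web
flows make the anchovy (2nd-order consumer) the unique BC argmax under
1/a, while the detrital loop gives `−a` a negative cycle.

The binary-vs-weighted divergence demonstration runs the pipeline on a
12-bump landscape (70×90 cells) and compares top-5 BC and CC sets
between the thresholded binary graph and the `log(1/p)`-weighted graph;
with the α = 0.03 kernel at 15 km cells the overlap is strictly below 5
across seeds. Problem sizes throughout (n ≤ 7–8 for exhaustive-oracle
comparisons, 150 + 50 random graphs, 70×90 rasters) keep the whole
suite and the acceptance script fast while leaving the enumeration
oracles tractable.

## Reporting

Every CLI analysis writes a checklist report: (1) node/edge
definitions, (2) binary-vs-weighted plus proportionality, (3) the
transformation applied (as JSON, with rationale), (4) the centrality
formula and the all-shortest-paths statement, (5) the software version.
`validate_report` grades a report complete / complete-with-warnings /
incomplete and lists missing items. Reports are byte-reproducible for
fixed inputs and version. CLI exit codes: 0 success, 1 usage error, 2
refusal on a blocking diagnostic (or on flow-like weights left
untransformed without `--force`).

## Known limitations

- No multigraphs, temporal networks, or automatic weight normalization;
  no data-driven choice among valid transforms (there is no criterion
  that would justify one).
- Random-walk betweenness and tuning-parameter weighted centralities
  are out of scope.
- Stress and the pass-through tallies build an O(N²)–O(N³) dense
  structure; fine for the intended problem sizes (hundreds of patches),
  not for massive graphs.
- Landscape geometry is planar; no least-cost-path resistance surfaces.
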