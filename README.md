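# econnect

Shortest-path centralities and landscape connectivity indices for
ecological networks — with the edge-weight bookkeeping that makes them
mean what you think they mean.

## The problem

Shortest-path algorithms minimise the **sum of edge weights** along a
path. That is the right thing to do when weights are
*distance-proportional* (cost-distance, travel time, resistance), but
ecological edge weights are very often *flow-proportional*: interaction
frequencies, dispersal probabilities, numbers of shared parasites,
carbon flow. Run Dijkstra on those and the "shortest" paths thread
through the *weakest* connections in the network — and every centrality
built on top of them (betweenness, stress, closeness) quietly ranks the
wrong nodes. The common fixes have their own failure modes: subtracting
the weights from a constant `C − a` biases paths toward fewer hops,
`1 − a` fails when weights span orders of magnitude, and negating
weights `−a` creates negative cycles on which no shortest-path search
converges.

`econnect` makes the weight semantics an explicit, mandatory part of the
network object, applies and diagnoses the standard reversing transforms
(`1/a`, `log(1/a)`, `exp(−a)`, `1 − a`, `C − a`, `−a`,
`log((1−a)/a)`), refuses the combinations that are mathematically
unusable, and emits a five-point reporting checklist with every
analysis so the computation can be reproduced.

## What it computes

For a network with distances `g_ij`, all shortest paths counted:

- **Betweenness** `BC(v) = Σ_{i≠v≠j} g_ij(v) / g_ij` — the fraction of
  shortest paths through `v` (raw, unnormalized).
- **Stress** `SC(v) = Σ_{i≠v≠j} g_ij(v)` — the count of shortest paths
  through `v`.
- **Closeness** `CC(v) = (N−1) / Σ_j g_vj`.
- **Most-probable paths** on independent-probability networks via the
  `log(1/a)` transform, which maps products of probabilities onto sums
  of distances.
- **Negative-cycle certificates** (Bellman–Ford–Moore) demonstrating why
  `−a` is not a usable weight reversal.

For landscapes (patch areas `a_i`, landscape area `A_L`, hop counts
`nl_ij` in the thresholded patch graph, max-product dispersal
probabilities `ṗ_ij` under the kernel `p_ij = exp(−α d_ij)`):

- **IIC** `= Σ_i Σ_j [a_i a_j / (1 + nl_ij)] / A_L²`
- **PC** `= Σ_i Σ_j a_i a_j ṗ_ij / A_L²`

plus the full raster pipeline: coarse-graining, elevation-band habitat
masking, patch labelling, boundary-to-boundary distances, and a
binary-vs-weighted top-k centrality comparison.

## Worked example

The five-city toy: a two-edge route Busan–Chicago–Almería carrying 10
researchers and a three-edge route Busan–Copenhagen–Marseille–Almería
carrying 30. The three-edge route carries the most flow, but reversing
weights by subtracting from C = 100 still picks the two-edge route:

```python
from econnect import apply_transform, shortest_paths, TransformSpec
from econnect.fixtures import toy_cities

net, truth = toy_cities("flow_counts")
shifted = apply_transform(net, TransformSpec("subtract_constant", C=100))
pr = shortest_paths(shifted)
b, a = shifted.index("Busan"), shifted.index("Almeria")
print(pr.dist[b, a])                       # 190.0  (= 95 + 95, two edges)
print(3 * (100 - 10.0))                    # 270.0  (the high-flow route)
```

The shortest path measures 190 via Chicago versus 270 via Copenhagen —
the constant shift added `C` per edge, so fewer hops win regardless of
flow. The safety checker flags exactly this:

```python
from econnect import check_transform_safety
diag = check_transform_safety(net, TransformSpec("subtract_constant", C=100))
print(diag.warnings)                       # ['HOP_COUNT_BIAS']
```

Doing it right instead (`1/a` for flow-like weights, recommended
automatically) on the four-primate shared-parasite toy:

```sh
$ econnect fixtures primates --out primates.csv --quiet
$ econnect centrality primates.csv --semantics flow-like --out bc --quiet
$ head -3 bc.csv
node,score,rank
A,3.0,1
B,0.0,2
```

Primate A — the one actually sharing the most parasites — tops the
ranking; computed on raw weights it would have been B. Every run writes
a sibling `bc.report.json` covering the five checklist items (node/edge
definitions, weighting, transformation, formula, software version);
`econnect validate-report bc.report.json` audits any such report.

The landscape pipeline end to end:

```sh
$ econnect fixtures dem --seed 1 --out dem.asc --quiet
$ econnect landscape dem.asc --out ls --quiet
5 patches; IIC=0.000273524 PC=0.000275842
```

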