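"""Edge-weight transformations and their safety diagnostics.

Shortest-path algorithms minimise the sum of edge weights.  When weights
are flow-proportional (interaction frequency, dispersal probability,
shared parasites) they must first be reversed into distance-like weights.
Several reversing functions circulate in the graph-theoretical literature
— 1/a, log(1/a), exp(−a), 1−a, C−a, −a, log((1−a)/a) — but they are not
interchangeable: subtracting from a constant biases paths toward fewer
hops, negation creates negative cycles, and log of values above 1 creates
negative edges.  This module applies the transforms and diagnoses each of
those pitfalls, refusing only where the output would be mathematically
unusable (negative weights) and warning otherwise, so the pitfalls can be
demonstrated, not merely forbidden.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .netcore import EcoNetwork, EdgeSemantics, SemanticsKind

__all__ = [
    "TransformSpec",
    "TransformDiagnostics",
    "TransformError",
    "apply_transform",
    "check_transform_safety",
    "recommend_transform",
    "HOP_COUNT_BIAS",
    "MAGNITUDE_SPAN",
    "NEGATIVE_OUTPUT",
    "NO_TRANSFORM_ON_FLOW",
    "TRANSFORM_ON_DISTANCE",
]

KINDS = (
    "identity",
    "inverse",
    "neg_log",
    "exp_neg",
    "complement",
    "subtract_constant",
    "negate",
    "logit_inverse",
)

# kinds that turn flow-proportional weights into distance-like ones
REVERSING_KINDS = frozenset(KINDS) - {"identity"}

# warning codes
HOP_COUNT_BIAS = "HOP_COUNT_BIAS"
MAGNITUDE_SPAN = "MAGNITUDE_SPAN"
NEGATIVE_OUTPUT = "NEGATIVE_OUTPUT"
NO_TRANSFORM_ON_FLOW = "NO_TRANSFORM_ON_FLOW"
TRANSFORM_ON_DISTANCE = "TRANSFORM_ON_DISTANCE"

#: max/min weight ratio above which constant-style transforms distort
MAGNITUDE_SPAN_RATIO = 100.0


class TransformError(ValueError):
    """Transform invalid for the given weights or semantics."""


@dataclass(frozen=True)
class TransformSpec:
    """A declared edge-weight transformation.

    ``C`` applies only to ``subtract_constant`` (w' = C − a) and must
    dominate every weight.  ``negate`` is the known-broken −a transform
    and must be constructed with ``unsafe=True``.  Logarithms are natural
    throughout: the base only rescales distances and never changes which
    path is shortest.
    """

    kind: str
    C: Optional[float] = None
    unsafe: bool = False
    rationale: str = ""

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise TransformError(f"unknown transform kind {self.kind!r}")
        if self.kind == "subtract_constant" and self.C is None:
            raise TransformError("subtract_constant requires the constant C")
        if self.kind != "subtract_constant" and self.C is not None:
            raise TransformError(f"C is meaningless for kind {self.kind!r}")
        if self.kind == "negate" and not self.unsafe:
            raise TransformError(
                "negate (−a) produces negative weights and is only "
                "constructible with unsafe=True"
            )

    def to_json(self) -> str:
        d: dict = {"kind": self.kind}
        if self.C is not None:
            d["C"] = self.C
        if self.unsafe:
            d["unsafe"] = True
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "TransformSpec":
        d = json.loads(text)
        return cls(kind=d["kind"], C=d.get("C"), unsafe=d.get("unsafe", False))


@dataclass
class TransformDiagnostics:
    """Outcome of a safety check; NEGATIVE_OUTPUT is always blocking."""

    warnings: list[str] = field(default_factory=list)
    blocking: bool = False

    def __post_init__(self) -> None:
        if NEGATIVE_OUTPUT in self.warnings:
            self.blocking = True


def _transformed_weights(ws: np.ndarray, spec: TransformSpec) -> np.ndarray:
    k = spec.kind
    if k == "identity":
        return ws.copy()
    if k == "inverse":
        if np.any(ws <= 0):
            raise TransformError("inverse (1/a) requires strictly positive weights")
        return 1.0 / ws
    if k == "neg_log":
        if np.any(ws <= 0):
            raise TransformError("neg_log (log(1/a)) requires weights > 0")
        if np.any(ws > 1):
            raise TransformError(
                "neg_log on weights above 1 yields negative edges; one must "
                "avoid the use of negative edges — normalize to (0, 1] or "
                "use the inverse transform"
            )
        return -np.log(ws)
    if k == "exp_neg":
        return np.exp(-ws)
    if k == "complement":
        if np.any(ws > 1):
            raise TransformError(
                "complement (1 − a) on weights above 1 yields negative edges"
            )
        return 1.0 - ws
    if k == "subtract_constant":
        assert spec.C is not None
        if ws.size and spec.C < ws.max():
            raise TransformError(
                f"subtract_constant requires C >= max weight ({ws.max()}), got C={spec.C}"
            )
        return spec.C - ws
    if k == "negate":
        return -ws
    if k == "logit_inverse":
        # log((1−a)/a), restricted to a in (0, 0.5] so outputs stay >= 0
        if np.any(ws <= 0) or np.any(ws > 0.5):
            raise TransformError(
                "logit_inverse is restricted to weights in (0, 0.5] so the "
                "output is non-negative"
            )
        return np.log((1.0 - ws) / ws)
    raise TransformError(f"unknown transform kind {k!r}")  # pragma: no cover


def apply_transform(net: EcoNetwork, spec: TransformSpec) -> EcoNetwork:
    """Return a new network with transformed weights.

    The result carries ``distance_like`` semantics (identity keeps the
    original declaration) and records the transform in its metadata.  The
    input network is never mutated.
    """
    ws = net.weights()
    new_ws = _transformed_weights(ws, spec)
    edges = [(u, v, w) for (u, v, _), w in zip(net.edges, new_ws)]
    if spec.kind == "identity":
        semantics = net.semantics
    else:
        semantics = EdgeSemantics.distance_like()
    out = net.with_edges(
        edges, semantics=semantics, allow_negative=(spec.kind == "negate")
    )
    out.metadata["transform"] = spec.to_json()
    return out


def check_transform_safety(net: EcoNetwork, spec: TransformSpec) -> TransformDiagnostics:
    """Diagnose known pitfalls of applying ``spec`` to ``net``.

    Pure diagnostics — never raises.  Warnings:

    - ``HOP_COUNT_BIAS``: constant-style transforms (C − a, 1 − a) add a
      constant to every edge, biasing shortest paths toward fewer hops.
    - ``MAGNITUDE_SPAN``: weights spanning >= 2 orders of magnitude make
      constant-style transforms unreliable even when hop counts agree.
    - ``NEGATIVE_OUTPUT`` (blocking): some transformed weight would be
      negative, so shortest paths are undefined or non-convergent.
    - ``NO_TRANSFORM_ON_FLOW``: identity on flow-proportional weights —
      the shortest-path algorithm would trace the *weakest* connections.
    - ``TRANSFORM_ON_DISTANCE``: a reversing transform requested on
      weights that are already distance-like.
    """
    warnings: list[str] = []
    ws = net.weights()
    kind = spec.kind

    if kind in ("subtract_constant", "complement"):
        warnings.append(HOP_COUNT_BIAS)
        if ws.size and np.all(ws > 0) and ws.max() / ws.min() >= MAGNITUDE_SPAN_RATIO:
            warnings.append(MAGNITUDE_SPAN)

    negative_out = False
    if ws.size:
        if kind == "negate" and np.any(ws > 0):
            negative_out = True
        elif kind == "neg_log" and np.any(ws > 1):
            negative_out = True
        elif kind == "complement" and np.any(ws > 1):
            negative_out = True
        elif kind == "subtract_constant" and spec.C is not None and ws.max() > spec.C:
            negative_out = True
        elif kind == "logit_inverse" and np.any(ws > 0.5):
            negative_out = True
        elif kind == "identity" and np.any(ws < 0):
            negative_out = True
    if negative_out:
        warnings.append(NEGATIVE_OUTPUT)

    if kind == "identity" and net.semantics.is_flow_proportional:
        warnings.append(NO_TRANSFORM_ON_FLOW)
    if kind in REVERSING_KINDS and net.semantics.kind is SemanticsKind.DISTANCE_LIKE:
        warnings.append(TRANSFORM_ON_DISTANCE)

    return TransformDiagnostics(warnings=warnings)


def recommend_transform(net: EcoNetwork) -> TransformSpec:
    """Recommend a transform from the declared semantics.

    binary and distance-like weights need none; independent probabilities
    get log(1/a), which turns the product of path probabilities into a sum
    of distances; other flow-proportional weights get 1/a.  The decision
    trace is recorded in ``rationale`` for the checklist report.
    """
    kind = net.semantics.kind
    if kind is SemanticsKind.BINARY:
        return TransformSpec(
            "identity", rationale="binary edges: unit weights are already distances"
        )
    if kind is SemanticsKind.DISTANCE_LIKE:
        return TransformSpec(
            "identity",
            rationale="weights are inversely proportional to information flow; "
            "no transformation required",
        )
    if kind is SemanticsKind.PROBABILITY:
        if net.semantics.independence is None:
            raise TransformError(
                "probability semantics requires an explicit independence "
                "declaration before a transform can be recommended"
            )
        if net.semantics.independence:
            return TransformSpec(
                "neg_log",
                rationale="independent probability edges: log(1/a) turns the "
                "product of path probabilities into a sum of distances",
            )
        raise TransformError(
            "non-independent probability edges invalidate the product rule; "
            "no shortest-path transform can be recommended"
        )
    # flow_like
    return TransformSpec(
        "inverse",
        rationale="flow-proportional weights: 1/a makes strong associations short",
    )
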