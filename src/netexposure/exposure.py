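"""The network exposure model.

A node's exposure to an attribute is the fraction of its network ties that
lead to nodes exhibiting the attribute: E_i = (attribute-bearing neighbors) /
degree(i), with E_i = 0 for isolated nodes so that exposure is total (every
node is either exposed or unexposed).  A node bearing the attribute itself
still has its exposure defined by its neighbors only.  An optional edge
weight generalizes the tie counts to weighted sums; the headline analysis is
unweighted because recommendation edges carry no meaningful weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping

from .graph_core import RecNetwork, Stance, Source, VideoNode

__all__ = [
    "ExposureResult",
    "ExposureSummary",
    "node_exposure",
    "network_exposure",
    "exposure_summary",
    "exposed_flags",
    "parse_predicate",
    "PREDICATES",
]

Predicate = Callable[[VideoNode], bool]

#: Named node predicates used throughout the analysis.  ``health`` means
#: health content unrelated to vaccines; ``nonvaccine`` is its complement of
#: ``vaccine``.
PREDICATES: dict[str, Predicate] = {
    "vaccine": lambda n: n.vaccine_related,
    "nonvaccine": lambda n: not n.vaccine_related,
    "provaccine": lambda n: n.stance is Stance.PRO,
    "antivaccine": lambda n: n.stance is Stance.ANTI,
    "autism": lambda n: n.autism and not n.vaccine_related,
    "health": lambda n: n.health_related and not n.vaccine_related,
    "health_accurate": lambda n: n.health_related
    and not n.health_misinformation
    and not n.vaccine_related,
    "health_misinfo": lambda n: n.health_misinformation and not n.vaccine_related,
}


def parse_predicate(spec: str) -> tuple[str, Predicate]:
    """Resolve a predicate from a name or a ``field=value`` expression.

    ``stance=anti`` tests the stance enum, ``vaccine_related=true`` a boolean
    flag, ``source=consumer`` the source enum.  Bare names look up
    :data:`PREDICATES`.
    """
    spec = spec.strip()
    if "=" not in spec:
        try:
            return spec, PREDICATES[spec]
        except KeyError:
            raise ValueError(
                f"unknown predicate {spec!r}; known: {sorted(PREDICATES)}"
            ) from None
    field_name, _, value = spec.partition("=")
    field_name = field_name.strip()
    value = value.strip()
    if field_name == "stance":
        want = Stance(value)
        return spec, lambda n: n.stance is want
    if field_name == "source":
        want_src = Source(value)
        return spec, lambda n: n.source is want_src
    if field_name in (
        "vaccine_related",
        "autism",
        "health_related",
        "health_misinformation",
    ):
        want_bool = value.lower() in ("true", "1", "yes")
        return spec, lambda n: getattr(n, field_name) == want_bool
    raise ValueError(f"cannot build predicate from {spec!r}")


@dataclass(frozen=True)
class ExposureResult:
    """Per-node exposure values for one attribute over one network."""

    attribute: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.values.items() if not 0.0 <= v <= 1.0}
        if bad:
            raise ValueError(f"exposure values outside [0, 1]: {bad}")


@dataclass(frozen=True)
class ExposureSummary:
    """Distributional summary of an exposure vector.

    ``sd`` uses the sample (n-1) denominator.  ``range_over_exposed`` is the
    (min, max) of E_i over exposed nodes (E_i > 0) and is None when no node
    is exposed.
    """

    mean: float
    sd: float
    n: int
    n_exposed: int
    pct_exposed: float
    range_over_exposed: tuple[float, float] | None


def node_exposure(
    network: RecNetwork,
    node_id: str,
    attribute: Predicate | str,
    *,
    weight: str | None = None,
) -> float:
    """Exposure of one node: fraction of its ties leading to attribute nodes.

    With ``weight`` set, ties are weighted by that edge attribute (missing
    weights count as 1).  Isolated nodes have exposure 0.
    """
    if node_id not in network.graph:
        raise KeyError(f"unknown node id {node_id!r}")
    if isinstance(attribute, str):
        _, pred = parse_predicate(attribute)
    else:
        pred = attribute
    g = network.graph
    if weight is None:
        neighbors = list(g.neighbors(node_id))
        if not neighbors:
            return 0.0
        hits = sum(1 for nb in neighbors if pred(network.node(nb)))
        return hits / len(neighbors)
    total = 0.0
    hits_w = 0.0
    for nb in g.neighbors(node_id):
        w = float(g.edges[node_id, nb].get(weight, 1.0))
        total += w
        if pred(network.node(nb)):
            hits_w += w
    return hits_w / total if total > 0 else 0.0


def network_exposure(
    network: RecNetwork,
    attribute: Predicate | str,
    *,
    name: str | None = None,
    weight: str | None = None,
) -> ExposureResult:
    """Exposure of every node in the network to one attribute."""
    if isinstance(attribute, str):
        label, pred = parse_predicate(attribute)
    else:
        label, pred = name or getattr(attribute, "__name__", "attribute"), attribute
    flags = {nid: pred(network.node(nid)) for nid in network.graph.nodes}
    values = {}
    for nid in network.graph.nodes:
        if weight is None:
            neighbors = list(network.graph.neighbors(nid))
            values[nid] = (
                sum(1 for nb in neighbors if flags[nb]) / len(neighbors)
                if neighbors
                else 0.0
            )
        else:
            values[nid] = node_exposure(network, nid, pred, weight=weight)
    return ExposureResult(attribute=name or label, values=values)


def exposure_summary(result: ExposureResult) -> ExposureSummary:
    """Mean, SD, exposed count/percentage, and range over exposed nodes."""
    values = list(result.values.values())
    n = len(values)
    if n == 0:
        raise ValueError("cannot summarize an empty exposure mapping")
    mean = sum(values) / n
    if n > 1:
        var = sum((v - mean) ** 2 for v in values) / (n - 1)
    else:
        var = 0.0
    exposed = [v for v in values if v > 0.0]
    return ExposureSummary(
        mean=mean,
        sd=math.sqrt(var),
        n=n,
        n_exposed=len(exposed),
        pct_exposed=100.0 * len(exposed) / n,
        range_over_exposed=(min(exposed), max(exposed)) if exposed else None,
    )


def exposed_flags(result: ExposureResult) -> dict[str, bool]:
    """Binary exposed/unexposed status: exposed iff E_i > 0.

    This flag is the case status for the odds-ratio analysis.
    """
    return {nid: v > 0.0 for nid, v in result.values.items()}
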