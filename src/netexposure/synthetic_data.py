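"""Synthetic annotated recommendation networks with the crawl's structure.

The generator emulates a breadth-first recommendation crawl: a set of start
videos (search hits or curated seeds), a fixed branching factor (the handful
of recommendations a viewer actually sees on one screen), a fixed number of
depth levels, and deduplication.  Deduplication is modeled by re-attachment:
each generated recommendation points, with probability ``reattach_prob``, to
an already generated video chosen uniformly at random instead of a new one.
Re-attachment is the simplest stand-in for the platform's covisitation-driven
recommendation overlap, which is proprietary and unobservable; it reproduces
the shrinkage from the theoretical maximum crawl size down to the observed
network sizes, and it is the only source of cycles and triangles.

Content categories propagate first-order along recommendation links: a new
video's category is drawn from a row-stochastic transition matrix conditioned
on its parent's category.  This matches the granularity of the downstream
exposure analysis, which is itself first-order over edges.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .graph_core import (
    RecNetwork,
    RecommendationEdge,
    Source,
    Stance,
    VideoNode,
    build_network,
)

__all__ = [
    "CATEGORIES",
    "CrawlSimConfig",
    "SimResult",
    "simulate_crawl",
    "preset_scenario",
    "PRESET_NAMES",
    "node_for_category",
]

#: The mutually exclusive content categories implied by the annotation scheme.
CATEGORIES = (
    "provaccine",
    "antivaccine",
    "autism",
    "health_accurate",
    "health_misinformation",
    "other",
)

_ATOL = 1e-9


def _check_dist(vec: Sequence[float], what: str) -> tuple[float, ...]:
    v = tuple(float(x) for x in vec)
    if len(v) != len(CATEGORIES):
        raise ValueError(f"{what} must have {len(CATEGORIES)} entries")
    if any(x < 0 for x in v):
        raise ValueError(f"{what} has negative entries")
    if abs(sum(v) - 1.0) > _ATOL:
        raise ValueError(f"{what} must sum to 1 (got {sum(v)})")
    return v


# Default uploader-source mix per category: vaccine content in search results
# skews to institutional uploaders, antivaccine and misinformation content to
# consumer channels — the qualitative pattern of the annotated source table.
_SOURCES = tuple(s.value for s in Source)


def _source_vec(**weights: float) -> tuple[float, ...]:
    v = [weights.get(s, 0.0) for s in _SOURCES]
    tot = sum(v)
    return tuple(x / tot for x in v)


DEFAULT_SOURCE_DIST: dict[str, tuple[float, ...]] = {
    "provaccine": _source_vec(government=0.45, academic_hospital=0.25, news=0.2, consumer=0.05, pharma_forprofit=0.02, professional=0.03),
    "antivaccine": _source_vec(consumer=0.6, news=0.3, other=0.1),
    "autism": _source_vec(consumer=0.5, news=0.3, academic_hospital=0.2),
    "health_accurate": _source_vec(academic_hospital=0.3, news=0.35, consumer=0.3, government=0.05),
    "health_misinformation": _source_vec(consumer=0.7, news=0.2, other=0.1),
    "other": _source_vec(consumer=0.5, news=0.4, other=0.1),
}


@dataclass(frozen=True)
class CrawlSimConfig:
    """Parameters of a synthetic snowball crawl.

    ``n_seeds`` start videos expand for ``depth`` levels, each fetched video
    contributing ``branching`` recommendations.  ``category_transition`` is a
    row-stochastic matrix over :data:`CATEGORIES` giving P(child category |
    parent category); ``seed_category_dist`` draws the start videos'
    categories.  ``reattach_prob`` is the probability that a recommendation
    points to an already generated video.
    """

    n_seeds: int
    branching: int = 6
    depth: int = 3
    reattach_prob: float = 0.0
    category_transition: tuple[tuple[float, ...], ...] = ()
    seed_category_dist: tuple[float, ...] = ()
    source_dist: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SOURCE_DIST)
    )
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")
        if self.branching < 1:
            raise ValueError("branching must be >= 1")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if not 0.0 <= self.reattach_prob <= 1.0:
            raise ValueError("reattach_prob must be in [0, 1]")
        H = self.category_transition or _uniform_transition()
        object.__setattr__(
            self,
            "category_transition",
            tuple(_check_dist(row, f"category_transition row {i}") for i, row in enumerate(H)),
        )
        if len(self.category_transition) != len(CATEGORIES):
            raise ValueError("category_transition must be square over CATEGORIES")
        seed = self.seed_category_dist or tuple(
            1.0 / len(CATEGORIES) for _ in CATEGORIES
        )
        object.__setattr__(self, "seed_category_dist", _check_dist(seed, "seed_category_dist"))
        for cat in CATEGORIES:
            if cat not in self.source_dist:
                raise ValueError(f"source_dist missing category {cat}")

    # -- JSON round-trip ---------------------------------------------------
    def to_json(self) -> str:
        d = {
            "n_seeds": self.n_seeds,
            "branching": self.branching,
            "depth": self.depth,
            "reattach_prob": self.reattach_prob,
            "category_transition": [list(r) for r in self.category_transition],
            "seed_category_dist": list(self.seed_category_dist),
            "source_dist": {k: list(v) for k, v in self.source_dist.items()},
            "rng_seed": self.rng_seed,
        }
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CrawlSimConfig":
        d = json.loads(text)
        d["category_transition"] = tuple(tuple(r) for r in d.get("category_transition", ()))
        d["seed_category_dist"] = tuple(d.get("seed_category_dist", ()))
        if "source_dist" in d:
            d["source_dist"] = {k: tuple(v) for k, v in d["source_dist"].items()}
        return cls(**d)


def _uniform_transition() -> tuple[tuple[float, ...], ...]:
    k = len(CATEGORIES)
    return tuple(tuple(1.0 / k for _ in range(k)) for _ in range(k))


@dataclass
class SimResult:
    """A simulated network plus the ground truth that generated it."""

    network: RecNetwork
    truth: dict[str, str]
    records: list[RecommendationEdge]
    config: CrawlSimConfig

    def __post_init__(self) -> None:
        missing = set(self.network.node_ids()) - set(self.truth)
        if missing:
            raise ValueError(f"truth does not cover nodes: {sorted(missing)[:5]}")


def node_for_category(node_id: str, category: str, source: Source) -> VideoNode:
    """Annotation flags implied by a ground-truth content category."""
    if category == "provaccine":
        return VideoNode(node_id, vaccine_related=True, stance=Stance.PRO, source=source)
    if category == "antivaccine":
        return VideoNode(node_id, vaccine_related=True, stance=Stance.ANTI, source=source)
    if category == "autism":
        return VideoNode(node_id, autism=True, source=source)
    if category == "health_accurate":
        return VideoNode(node_id, health_related=True, source=source)
    if category == "health_misinformation":
        return VideoNode(
            node_id, health_related=True, health_misinformation=True, source=source
        )
    if category == "other":
        return VideoNode(node_id, source=source)
    raise ValueError(f"unknown category {category!r}")


def simulate_crawl(config: CrawlSimConfig, rng_seed: int | None = None) -> SimResult:
    """Run the breadth-first crawl simulation.

    Level 0 consists of ``n_seeds`` start videos with categories drawn from
    ``seed_category_dist``.  Every video fetched at level k < depth emits
    ``branching`` recommendations; each independently re-attaches to a
    uniformly chosen existing video with probability ``reattach_prob`` and
    otherwise creates a new video whose category is drawn from the transition
    matrix row of its parent.  The output network is cleaned to a simple
    undirected graph.  Fully reproducible from the RNG seed.
    """
    rng = np.random.default_rng(config.rng_seed if rng_seed is None else rng_seed)
    H = np.asarray(config.category_transition)
    seed_dist = np.asarray(config.seed_category_dist)
    n_cat = len(CATEGORIES)

    ids: list[str] = []
    categories: list[int] = []

    def new_node(cat_idx: int) -> int:
        idx = len(ids)
        ids.append(f"v{idx:05d}")
        categories.append(int(cat_idx))
        return idx

    for cat in rng.choice(n_cat, size=config.n_seeds, p=seed_dist):
        new_node(cat)
    seed_ids = list(ids)

    records: list[RecommendationEdge] = []
    frontier = list(range(config.n_seeds))
    for level in range(config.depth):
        next_frontier: list[int] = []
        for parent in frontier:
            for _ in range(config.branching):
                if rng.random() < config.reattach_prob and len(ids) > 1:
                    target = int(rng.integers(len(ids)))
                else:
                    cat = int(rng.choice(n_cat, p=H[categories[parent]]))
                    target = new_node(cat)
                    next_frontier.append(target)
                records.append(
                    RecommendationEdge(ids[parent], ids[target], depth=level + 1)
                )
        frontier = next_frontier

    annotations = []
    for idx, nid in enumerate(ids):
        cat = CATEGORIES[categories[idx]]
        src_vec = np.asarray(config.source_dist[cat])
        source = Source(_SOURCES[int(rng.choice(len(_SOURCES), p=src_vec))])
        annotations.append(node_for_category(nid, cat, source))

    network = build_network(
        records, annotations, seed_ids=seed_ids, provenance="synthetic"
    )
    truth = {nid: CATEGORIES[categories[i]] for i, nid in enumerate(ids)}
    return SimResult(network=network, truth=truth, records=records, config=config)


# ---------------------------------------------------------------------------
# Presets: the four study networks
# ---------------------------------------------------------------------------

# Observed category composition (counts) of each collected network.  Order:
# provaccine, antivaccine, autism, health_accurate, health_misinformation,
# other; the "other" count closes each column to the network's node count.
_COMPOSITIONS: dict[str, tuple[int, tuple[int, ...]]] = {
    # name: (n_nodes_observed, category counts)
    "provaccine_search": (283, (38, 3, 6, 99, 1, 136)),
    "antivaccine_search": (354, (35, 5, 21, 139, 3, 151)),
    "conspiracy_seed": (483, (34, 36, 13, 157, 110, 133)),
    "expert_seed": (551, (15, 25, 22, 172, 144, 173)),
}

_PRESET_SEEDS = {
    "provaccine_search": 6,
    "antivaccine_search": 6,
    "conspiracy_seed": 16,
    "expert_seed": 8,
}

PRESET_NAMES = tuple(_COMPOSITIONS)

#: Homophily weight: each transition row is lam * (stay in parent's category)
#: + (1 - lam) * (draw from the network's overall composition).  The overall
#: composition is then the exact stationary distribution of the chain.
_HOMOPHILY = 0.2

_ANTI_IDX = CATEGORIES.index("antivaccine")


def _solve_reattach_prob(n_seeds: int, branching: int, depth: int, target_nodes: int) -> float:
    """Re-attachment probability whose expected crawl size matches a target.

    With independent re-attachment, expected new nodes per level shrink
    geometrically with ratio branching*(1-rho), so the expected total is
    n_seeds * sum_k (branching*(1-rho))^k for k = 0..depth.
    """

    def expected(rho: float) -> float:
        x = branching * (1.0 - rho)
        return n_seeds * sum(x**k for k in range(depth + 1))

    if expected(0.0) <= target_nodes:
        return 0.0
    return float(brentq(lambda r: expected(r) - target_nodes, 0.0, 1.0, xtol=1e-12))


def preset_scenario(name: str) -> CrawlSimConfig:
    """Configuration emulating one of the four collected networks.

    The transition matrix is a homophily mixture whose stationary category
    composition equals the named network's observed composition; the
    re-attachment probability is solved so the expected crawl size matches
    the observed node count.  Search presets draw their start videos from the
    network composition (search hits); seed presets start from antivaccine
    videos (curated antivaccine playlists).
    """
    if name not in _COMPOSITIONS:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    n_nodes, counts = _COMPOSITIONS[name]
    assert sum(counts) == n_nodes
    pi = tuple(c / n_nodes for c in counts)
    k = len(CATEGORIES)
    H = tuple(
        tuple(
            _HOMOPHILY * (1.0 if i == j else 0.0) + (1.0 - _HOMOPHILY) * pi[j]
            for j in range(k)
        )
        for i in range(k)
    )
    n_seeds = _PRESET_SEEDS[name]
    if name.endswith("_seed"):
        seed_dist = tuple(1.0 if j == _ANTI_IDX else 0.0 for j in range(k))
    else:
        seed_dist = pi
    rho = _solve_reattach_prob(n_seeds, 6, 3, n_nodes)
    return CrawlSimConfig(
        n_seeds=n_seeds,
        branching=6,
        depth=3,
        reattach_prob=rho,
        category_transition=H,
        seed_category_dist=seed_dist,
    )
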