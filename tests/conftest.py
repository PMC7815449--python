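import numpy as np
import pytest

from netexposure import (
    RecommendationEdge,
    Source,
    Stance,
    VideoNode,
    build_network,
)


def make_annotated_network(edges, anti_ids=(), extra_ids=(), seed_ids=()):
    """Build a small network where ``anti_ids`` carry the antivaccine flag."""
    ids = {e[0] for e in edges} | {e[1] for e in edges} | set(extra_ids) | set(anti_ids)
    annotations = [
        VideoNode(
            i,
            vaccine_related=i in anti_ids,
            stance=Stance.ANTI if i in anti_ids else Stance.NONE,
        )
        for i in sorted(ids)
    ]
    records = [RecommendationEdge(u, v) for u, v in edges]
    return build_network(records, annotations, seed_ids=seed_ids)


def random_annotated_network(rng, n_nodes=30, edge_prob=0.1, anti_prob=0.3):
    """Erdos-Renyi style annotated network for property tests."""
    ids = [f"n{i}" for i in range(n_nodes)]
    edges = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                edges.append((ids[i], ids[j]))
    anti = {i for i in ids if rng.random() < anti_prob}
    sources = list(Source)
    annotations = [
        VideoNode(
            i,
            vaccine_related=i in anti,
            stance=Stance.ANTI if i in anti else Stance.NONE,
            autism=bool(rng.random() < 0.1) and i not in anti,
            source=sources[int(rng.integers(len(sources)))],
            views=int(rng.integers(1000)),
        )
        for i in ids
    ]
    records = [RecommendationEdge(u, v, depth=int(rng.integers(4))) for u, v in edges]
    return build_network(records, annotations, seed_ids=ids[:2], provenance="synthetic")


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
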