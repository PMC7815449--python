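"""Annotated recommendation networks: domain types, construction, and I/O.

A recommendation network is an undirected simple graph whose nodes are
annotated videos.  Raw crawl output is a list of directed recommendation
records (parent video -> recommended video, tagged with the crawl depth at
which it was fetched); analysis is performed on the cleaned undirected graph,
so reciprocal and parallel records collapse to a single edge and self-loops
are dropped.  Videos flagged as non-English (``language_excluded``) are
removed, together with their incident edges, before any analysis.

Supported on-disk formats: GraphML, GEXF, and a CSV pair (edge list +
node-attribute table).  Round-tripping through any of them preserves node
ids, edges, and attribute spellings exactly.
"""

from __future__ import annotations

import csv
import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Stance",
    "Source",
    "VideoNode",
    "RecommendationEdge",
    "RecNetwork",
    "build_network",
    "recode_stance",
    "read_network",
    "write_network",
    "NetworkFormatError",
    "MissingAnnotationError",
]


class Stance(str, enum.Enum):
    """Stance of a vaccine-related video; ``NONE`` iff the video is not
    vaccine-related."""

    PRO = "pro"
    ANTI = "anti"
    NONE = "none"


class Source(str, enum.Enum):
    """Uploader category of a video."""

    GOVERNMENT = "government"
    ACADEMIC_HOSPITAL = "academic_hospital"
    PHARMA_FORPROFIT = "pharma_forprofit"
    CONSUMER = "consumer"
    NEWS = "news"
    PROFESSIONAL = "professional"
    OTHER = "other"
    UNKNOWN = "unknown"


class NetworkFormatError(ValueError):
    """Raised when a network file cannot be parsed."""


class MissingAnnotationError(KeyError):
    """Raised in strict mode when an edge references an unannotated id."""


@dataclass(frozen=True)
class VideoNode:
    """A single annotated video.

    Annotation flags mirror the coding scheme: whether the video is about
    vaccines (and if so its stance), whether a non-vaccine video is about
    autism, whether it carries other health content and whether that content
    is misinformation.  ``views``/``likes`` are optional platform metadata.
    """

    id: str
    vaccine_related: bool = False
    stance: Stance = Stance.NONE
    autism: bool = False
    health_related: bool = False
    health_misinformation: bool = False
    source: Source = Source.UNKNOWN
    language_excluded: bool = False
    views: int | None = None
    likes: int | None = None

    def __post_init__(self) -> None:
        if self.stance is not Stance.NONE and not self.vaccine_related:
            raise ValueError(
                f"node {self.id!r}: stance={self.stance.value} requires "
                "vaccine_related=True"
            )
        if self.health_misinformation and not self.health_related:
            raise ValueError(
                f"node {self.id!r}: health_misinformation requires "
                "health_related=True"
            )
        for name in ("views", "likes"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"node {self.id!r}: {name} must be >= 0")

    def to_attrs(self) -> dict:
        """Flat attribute dict (enums as strings), for graph storage."""
        d = {
            "vaccine_related": self.vaccine_related,
            "stance": self.stance.value,
            "autism": self.autism,
            "health_related": self.health_related,
            "health_misinformation": self.health_misinformation,
            "source": self.source.value,
            "language_excluded": self.language_excluded,
        }
        if self.views is not None:
            d["views"] = int(self.views)
        if self.likes is not None:
            d["likes"] = int(self.likes)
        return d


_BOOL_FIELDS = (
    "vaccine_related",
    "autism",
    "health_related",
    "health_misinformation",
    "language_excluded",
)


def _parse_bool(value, *, default: bool = False) -> bool:
    if isinstance(value, bool):
        return value
    if value is None or value == "":
        return default
    s = str(value).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValueError(f"unparseable boolean {value!r}")


def node_from_attrs(node_id: str, attrs: Mapping, *, strict: bool = False) -> VideoNode:
    """Build a :class:`VideoNode` from a flat attribute mapping.

    Unknown or malformed values default to unknown/False with a logged
    warning unless ``strict`` is set, so partially annotated files remain
    loadable.  The health_related flag is repaired (set True) when
    health_misinformation is set, rather than rejecting the row.
    """
    kw: dict = {"id": str(node_id)}
    for name in _BOOL_FIELDS:
        raw = attrs.get(name)
        try:
            kw[name] = _parse_bool(raw)
        except ValueError:
            if strict:
                raise
            logger.warning("node %s: bad %s=%r, defaulting to False", node_id, name, raw)
            kw[name] = False
    raw_stance = attrs.get("stance", Stance.NONE)
    try:
        kw["stance"] = Stance(raw_stance if isinstance(raw_stance, Stance) else str(raw_stance))
    except ValueError:
        if strict:
            raise
        logger.warning("node %s: unknown stance %r, defaulting to none", node_id, raw_stance)
        kw["stance"] = Stance.NONE
    raw_source = attrs.get("source", Source.UNKNOWN)
    try:
        kw["source"] = Source(raw_source if isinstance(raw_source, Source) else str(raw_source))
    except ValueError:
        if strict:
            raise
        logger.warning("node %s: unknown source %r, defaulting to unknown", node_id, raw_source)
        kw["source"] = Source.UNKNOWN
    for name in ("views", "likes"):
        raw = attrs.get(name)
        if raw in (None, ""):
            kw[name] = None
        else:
            kw[name] = int(raw)
    if kw["stance"] is not Stance.NONE and not kw["vaccine_related"]:
        if strict:
            raise ValueError(f"node {node_id}: stance without vaccine_related")
        logger.warning("node %s: stance set on non-vaccine video, repairing", node_id)
        kw["vaccine_related"] = True
    if kw["health_misinformation"] and not kw["health_related"]:
        if strict:
            raise ValueError(f"node {node_id}: health_misinformation without health_related")
        logger.warning("node %s: misinformation implies health_related, repairing", node_id)
        kw["health_related"] = True
    return VideoNode(**kw)


@dataclass(frozen=True)
class RecommendationEdge:
    """One directed recommendation record from a crawl.

    ``depth`` is the crawl level at which the recommendation was fetched; it
    is retained on the cleaned edge for provenance only.
    """

    src: str
    dst: str
    depth: int = 0

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")


@dataclass
class RecNetwork:
    """An undirected simple graph of annotated videos.

    Wraps a :class:`networkx.Graph` whose node data hold the flat
    :class:`VideoNode` attributes (plus any extra columns carried through
    from input files).  ``seed_ids`` marks crawl start videos.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    seed_ids: frozenset[str] = frozenset()
    provenance: str = "file"

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node(self, node_id: str) -> VideoNode:
        return node_from_attrs(node_id, self.graph.nodes[node_id])

    def nodes(self) -> Iterator[VideoNode]:
        for nid in self.graph.nodes:
            yield self.node(nid)

    def node_ids(self) -> list[str]:
        return list(self.graph.nodes)

    def neighbors(self, node_id: str) -> list[str]:
        return list(self.graph.neighbors(node_id))

    def degree(self, node_id: str) -> int:
        return self.graph.degree[node_id]

    def attribute_table(self) -> pd.DataFrame:
        """Node-attribute table, one row per node, indexed by id."""
        rows = []
        for node in self.nodes():
            d = {"id": node.id, **node.to_attrs()}
            rows.append(d)
        df = pd.DataFrame(rows)
        if not df.empty:
            df = df.set_index("id")
        return df

    def with_nodes(self, new_nodes: Iterable[VideoNode]) -> "RecNetwork":
        """Copy of the network with the given nodes' annotations replaced."""
        g = self.graph.copy()
        for node in new_nodes:
            if node.id not in g:
                raise KeyError(node.id)
            extras = {
                k: v for k, v in g.nodes[node.id].items() if k not in _KNOWN_ATTRS
            }
            g.nodes[node.id].clear()
            g.nodes[node.id].update(node.to_attrs())
            g.nodes[node.id].update(extras)
        return RecNetwork(graph=g, seed_ids=self.seed_ids, provenance=self.provenance)


_KNOWN_ATTRS = frozenset(
    {
        "vaccine_related",
        "stance",
        "autism",
        "health_related",
        "health_misinformation",
        "source",
        "language_excluded",
        "views",
        "likes",
    }
)


def build_network(
    records: Iterable[RecommendationEdge],
    annotations: Iterable[VideoNode] | Mapping[str, VideoNode],
    *,
    seed_ids: Iterable[str] = (),
    provenance: str = "file",
    strict: bool = False,
) -> RecNetwork:
    """Assemble a cleaned undirected network from crawl records + annotations.

    Duplicated video ids merge into a single node; reciprocal and parallel
    directed records collapse to one undirected edge (the multiplicity is
    kept as ``weight`` metadata and the smallest depth is retained);
    self-loops are dropped; ``language_excluded`` nodes are removed together
    with their incident edges.  Annotated videos that appear in no record
    become isolated nodes.

    In strict mode an edge endpoint without an annotation row raises
    :class:`MissingAnnotationError` naming the id; otherwise a default
    (all-False) annotation is filled in with a warning.
    """
    if isinstance(annotations, Mapping):
        ann = dict(annotations)
    else:
        ann = {}
        for node in annotations:
            if node.id in ann:
                logger.warning("duplicate annotation for %s; keeping first", node.id)
                continue
            ann[node.id] = node

    g = nx.Graph()
    excluded = {nid for nid, node in ann.items() if node.language_excluded}
    for nid, node in ann.items():
        if nid not in excluded:
            g.add_node(nid, **node.to_attrs())

    n_self_loops = 0
    for rec in records:
        for endpoint in (rec.src, rec.dst):
            if endpoint not in ann:
                if strict:
                    raise MissingAnnotationError(
                        f"edge record references unannotated id {endpoint!r}"
                    )
                logger.warning("no annotation for %s; using defaults", endpoint)
                ann[endpoint] = VideoNode(id=endpoint)
                g.add_node(endpoint, **ann[endpoint].to_attrs())
        if rec.src == rec.dst:
            n_self_loops += 1
            continue
        if rec.src in excluded or rec.dst in excluded:
            continue
        if g.has_edge(rec.src, rec.dst):
            data = g.edges[rec.src, rec.dst]
            data["weight"] += 1
            data["depth"] = min(data["depth"], rec.depth)
        else:
            g.add_edge(rec.src, rec.dst, weight=1, depth=rec.depth)
    if n_self_loops:
        logger.warning("dropped %d self-loop record(s)", n_self_loops)

    seeds = frozenset(str(s) for s in seed_ids) - excluded
    return RecNetwork(graph=g, seed_ids=seeds, provenance=provenance)


def recode_stance(node: VideoNode, misinformation: bool | None = None) -> VideoNode:
    """Recode a video's stance from its raw misinformation coding.

    Vaccine-related videos that contain misinformation are recoded as
    antivaccine; other vaccine-related videos as provaccine; videos unrelated
    to vaccines keep stance ``none`` and their health flags untouched.
    ``misinformation`` is the raw "contains misinformation" code; when
    omitted, an existing antivaccine stance or the node's
    ``health_misinformation`` flag counts as the raw signal, so recoding
    already-recoded data is the identity.
    """
    if misinformation is None:
        misinformation = node.health_misinformation or node.stance is Stance.ANTI
    if not node.vaccine_related:
        return replace(node, stance=Stance.NONE)
    return replace(node, stance=Stance.ANTI if misinformation else Stance.PRO)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FORMATS = ("graphml", "gexf", "edgelist_csv")


def _csv_paths(path: str | Path) -> tuple[Path, Path]:
    """The CSV dialect is a pair of files derived from a base path."""
    base = Path(path)
    if base.suffix == ".csv":
        base = base.with_suffix("")
    return base.with_suffix(".edges.csv"), base.with_suffix(".nodes.csv")


def _serialize_value(v):
    if isinstance(v, enum.Enum):
        return v.value
    if isinstance(v, bool):
        return "true" if v else "false"
    return v


def write_network(network: RecNetwork, path: str | Path, format: str) -> None:
    """Write a network to GraphML, GEXF, or the CSV edge-list/node-table pair.

    Booleans are serialized as ``true``/``false``; enum spellings are written
    verbatim; unknown extra node attributes are carried through.
    """
    if format not in _FORMATS:
        raise ValueError(f"unsupported format {format!r}; choose from {_FORMATS}")
    path = Path(path)
    if format == "edgelist_csv":
        edges_path, nodes_path = _csv_paths(path)
        extra_cols: list[str] = []
        for _, data in network.graph.nodes(data=True):
            for k in data:
                if k not in _KNOWN_ATTRS and k not in extra_cols and k != "is_seed":
                    extra_cols.append(k)
        header = [
            "id",
            "vaccine_related",
            "stance",
            "autism",
            "health_related",
            "health_misinformation",
            "source",
            "language_excluded",
            "views",
            "likes",
            "is_seed",
        ] + extra_cols
        with nodes_path.open("w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(header)
            for nid in network.graph.nodes:
                data = network.graph.nodes[nid]
                node = node_from_attrs(nid, data)
                attrs = node.to_attrs()
                row = [nid]
                for col in header[1:]:
                    if col == "is_seed":
                        row.append("true" if nid in network.seed_ids else "false")
                    elif col in ("views", "likes"):
                        v = attrs.get(col)
                        row.append("" if v is None else v)
                    elif col in _KNOWN_ATTRS:
                        row.append(_serialize_value(attrs[col]))
                    else:
                        row.append(_serialize_value(data.get(col, "")))
                w.writerow(row)
        with edges_path.open("w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["src", "dst", "depth", "weight"])
            for u, v, data in network.graph.edges(data=True):
                w.writerow([u, v, data.get("depth", 0), data.get("weight", 1)])
        return

    g = nx.Graph()
    g.graph["provenance"] = network.provenance
    for nid, data in network.graph.nodes(data=True):
        out = {k: _flatten_for_xml(v) for k, v in data.items() if v is not None}
        out["is_seed"] = nid in network.seed_ids
        g.add_node(nid, **out)
    for u, v, data in network.graph.edges(data=True):
        g.add_edge(u, v, **{k: w for k, w in data.items() if w is not None})
    if format == "graphml":
        nx.write_graphml(g, path)
    else:
        nx.write_gexf(g, path)


def _flatten_for_xml(v):
    if isinstance(v, enum.Enum):
        return v.value
    return v


def read_network(path: str | Path, format: str, *, strict: bool = False) -> RecNetwork:
    """Read a network written by :func:`write_network`.

    Applies the same cleaning contract as :func:`build_network`: self-loops
    are dropped with a warning, parallel edges cannot occur in these formats,
    and ``language_excluded`` nodes are removed.
    """
    if format not in _FORMATS:
        raise ValueError(f"unsupported format {format!r}; choose from {_FORMATS}")
    path = Path(path)

    if format == "edgelist_csv":
        edges_path, nodes_path = _csv_paths(path)
        annotations: dict[str, VideoNode] = {}
        seeds: list[str] = []
        extras: dict[str, dict] = {}
        try:
            with nodes_path.open(newline="", encoding="utf-8") as fh:
                reader = csv.DictReader(fh)
                if reader.fieldnames is None or "id" not in reader.fieldnames:
                    raise NetworkFormatError(f"{nodes_path}: missing 'id' column")
                for lineno, row in enumerate(reader, start=2):
                    nid = row["id"]
                    if not nid:
                        raise NetworkFormatError(f"{nodes_path}:{lineno}: empty id")
                    annotations[nid] = node_from_attrs(nid, row, strict=strict)
                    if _parse_bool(row.get("is_seed", "false")):
                        seeds.append(nid)
                    extras[nid] = {
                        k: v
                        for k, v in row.items()
                        if k not in _KNOWN_ATTRS and k not in ("id", "is_seed")
                    }
        except csv.Error as exc:
            raise NetworkFormatError(f"{nodes_path}: {exc}") from exc
        records: list[RecommendationEdge] = []
        try:
            with edges_path.open(newline="", encoding="utf-8") as fh:
                reader = csv.DictReader(fh)
                if reader.fieldnames is None or not {"src", "dst"} <= set(reader.fieldnames):
                    raise NetworkFormatError(f"{edges_path}: missing src/dst columns")
                for lineno, row in enumerate(reader, start=2):
                    depth = int(row.get("depth") or 0)
                    records.append(RecommendationEdge(row["src"], row["dst"], depth))
        except csv.Error as exc:
            raise NetworkFormatError(f"{edges_path}: {exc}") from exc
        net = build_network(
            records, annotations, seed_ids=seeds, provenance="file", strict=strict
        )
        for nid, extra in extras.items():
            if nid in net.graph:
                for k, v in extra.items():
                    if v not in (None, ""):
                        net.graph.nodes[nid][k] = v
        return net

    try:
        if format == "graphml":
            g = nx.read_graphml(path)
        else:
            g = nx.read_gexf(path)
    except Exception as exc:  # networkx raises several parse error types
        raise NetworkFormatError(f"{path}: {exc}") from exc

    if g.is_directed():
        g = g.to_undirected()
    loops = list(nx.selfloop_edges(g))
    if loops:
        logger.warning("dropped %d self-loop(s) while reading %s", len(loops), path)
        g.remove_edges_from(loops)

    annotations = {}
    seeds = []
    for nid, data in g.nodes(data=True):
        annotations[str(nid)] = node_from_attrs(str(nid), data, strict=strict)
        if _parse_bool(data.get("is_seed", False)):
            seeds.append(str(nid))
    records = [
        RecommendationEdge(str(u), str(v), int(d.get("depth", 0)))
        for u, v, d in g.edges(data=True)
    ]
    net = build_network(
        records, annotations, seed_ids=seeds, provenance="file", strict=strict
    )
    # carry unknown attributes and edge weights through untouched
    for nid, data in g.nodes(data=True):
        nid = str(nid)
        if nid not in net.graph:
            continue
        for k, v in data.items():
            if k not in _KNOWN_ATTRS and k not in ("is_seed", "label"):
                net.graph.nodes[nid][k] = v
    for u, v, data in g.edges(data=True):
        u, v = str(u), str(v)
        if net.graph.has_edge(u, v) and "weight" in data:
            net.graph.edges[u, v]["weight"] = int(data["weight"])
    return net
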