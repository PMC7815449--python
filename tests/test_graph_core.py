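import networkx as nx
import pytest

from netexposure import (
    RecommendationEdge,
    Source,
    Stance,
    VideoNode,
    build_network,
    read_network,
    recode_stance,
    write_network,
)
from netexposure.graph_core import MissingAnnotationError

from conftest import random_annotated_network


def ann(*ids, **kw):
    return [VideoNode(i, **kw) for i in ids]


class TestBuildNetwork:
    def test_reciprocal_and_parallel_records_collapse(self):
        records = [
            RecommendationEdge("a", "b"),
            RecommendationEdge("b", "a"),
            RecommendationEdge("a", "b"),
        ]
        net = build_network(records, ann("a", "b"))
        assert net.n_nodes == 2
        assert net.n_edges == 1
        assert net.graph.edges["a", "b"]["weight"] == 3

    def test_empty_records_give_empty_network(self):
        net = build_network([], [])
        assert net.n_nodes == 0
        assert net.n_edges == 0

    def test_node_count_equals_distinct_ids(self, rng):
        # many raw records repeating the same ids merge into unique nodes
        ids = [f"v{i}" for i in range(60)]
        records = []
        for _ in range(815):
            u, v = rng.choice(60, size=2, replace=False)
            records.append(RecommendationEdge(ids[u], ids[v]))
        net = build_network(records, ann(*ids))
        used = {r.src for r in records} | {r.dst for r in records}
        assert net.n_nodes == len(set(ids) | used)

    def test_self_loops_dropped(self):
        records = [RecommendationEdge("a", "a"), RecommendationEdge("a", "b")]
        net = build_network(records, ann("a", "b"))
        assert net.n_edges == 1
        assert not list(nx.selfloop_edges(net.graph))

    def test_language_excluded_removed_with_incident_edges(self):
        annotations = ann("a", "b") + [VideoNode("x", language_excluded=True)]
        records = [RecommendationEdge("a", "x"), RecommendationEdge("a", "b")]
        net = build_network(records, annotations)
        assert set(net.node_ids()) == {"a", "b"}
        assert net.n_edges == 1

    def test_strict_mode_rejects_unannotated_endpoint(self):
        with pytest.raises(MissingAnnotationError, match="ghost"):
            build_network([RecommendationEdge("a", "ghost")], ann("a"), strict=True)

    def test_lenient_mode_defaults_unannotated_endpoint(self):
        net = build_network([RecommendationEdge("a", "ghost")], ann("a"))
        assert net.node("ghost").vaccine_related is False

    def test_idempotence(self, rng):
        net = random_annotated_network(rng)
        records = [
            RecommendationEdge(u, v, d.get("depth", 0))
            for u, v, d in net.graph.edges(data=True)
        ]
        rebuilt = build_network(records, list(net.nodes()), seed_ids=net.seed_ids)
        assert set(rebuilt.node_ids()) == set(net.node_ids())
        assert {frozenset(e) for e in rebuilt.graph.edges} == {
            frozenset(e) for e in net.graph.edges
        }


class TestVideoNode:
    def test_stance_requires_vaccine_related(self):
        with pytest.raises(ValueError, match="vaccine_related"):
            VideoNode("x", vaccine_related=False, stance=Stance.PRO)

    def test_misinformation_requires_health_related(self):
        with pytest.raises(ValueError, match="health_related"):
            VideoNode("x", health_misinformation=True, health_related=False)

    def test_negative_views_rejected(self):
        with pytest.raises(ValueError, match="views"):
            VideoNode("x", views=-1)


class TestRecodeStance:
    @pytest.mark.parametrize(
        "vaccine_related,misinformation,expected",
        [
            (True, True, Stance.ANTI),
            (True, False, Stance.PRO),
            (False, True, Stance.NONE),
            (False, False, Stance.NONE),
        ],
    )
    def test_recode_rule(self, vaccine_related, misinformation, expected):
        node = VideoNode("x", vaccine_related=vaccine_related)
        out = recode_stance(node, misinformation=misinformation)
        assert out.stance is expected

    def test_health_flags_untouched(self):
        node = VideoNode("x", health_related=True, health_misinformation=True)
        out = recode_stance(node, misinformation=True)
        assert out.stance is Stance.NONE
        assert out.health_related and out.health_misinformation

    def test_recode_is_idempotent(self):
        # already-recoded antivaccine labels survive a second recode pass
        anti = VideoNode("x", vaccine_related=True, stance=Stance.ANTI)
        pro = VideoNode("y", vaccine_related=True, stance=Stance.PRO)
        assert recode_stance(anti).stance is Stance.ANTI
        assert recode_stance(pro).stance is Stance.PRO

    def test_default_flag_is_node_misinformation(self):
        node = VideoNode(
            "x", vaccine_related=True, health_related=True, health_misinformation=True
        )
        assert recode_stance(node).stance is Stance.ANTI


class TestRoundTrip:
    @pytest.mark.parametrize("format", ["graphml", "gexf", "edgelist_csv"])
    def test_empty_network_round_trips(self, tmp_path, format):
        net = build_network([], [])
        path = tmp_path / f"empty.{format}"
        write_network(net, path, format)
        back = read_network(path, format)
        assert back.n_nodes == 0 and back.n_edges == 0

    @pytest.mark.parametrize("format", ["graphml", "gexf", "edgelist_csv"])
    @pytest.mark.parametrize("trial", range(3))
    def test_random_network_round_trips(self, tmp_path, format, trial):
        import numpy as np

        rng = np.random.default_rng(100 + trial)
        net = random_annotated_network(rng, n_nodes=50, edge_prob=0.06)
        path = tmp_path / f"net_{trial}.{format}"
        write_network(net, path, format)
        back = read_network(path, format)
        assert set(back.node_ids()) == set(net.node_ids())
        assert {frozenset(e) for e in back.graph.edges} == {
            frozenset(e) for e in net.graph.edges
        }
        assert back.seed_ids == net.seed_ids
        for node in net.nodes():
            got = back.node(node.id)
            assert got == node, f"attribute mismatch for {node.id} in {format}"

    def test_graphml_self_loop_dropped_with_warning(self, tmp_path, caplog):
        g = nx.Graph()
        g.add_edge("a", "a")
        g.add_edge("a", "b")
        path = tmp_path / "loop.graphml"
        nx.write_graphml(g, path)
        with caplog.at_level("WARNING"):
            net = read_network(path, "graphml")
        assert net.n_edges == 1
        assert any("self-loop" in r.message for r in caplog.records)

    def test_unknown_attribute_columns_carried_through(self, tmp_path):
        net = build_network(
            [RecommendationEdge("a", "b")], ann("a", "b")
        )
        net.graph.nodes["a"]["channel"] = "some-channel"
        for format in ("graphml", "edgelist_csv"):
            path = tmp_path / f"extra.{format}"
            write_network(net, path, format)
            back = read_network(path, format)
            assert back.graph.nodes["a"]["channel"] == "some-channel"

    def test_malformed_file_raises_parse_error(self, tmp_path):
        from netexposure.graph_core import NetworkFormatError

        bad = tmp_path / "bad.graphml"
        bad.write_text("<graphml><unclosed>")
        with pytest.raises(NetworkFormatError):
            read_network(bad, "graphml")

    def test_enum_spellings_preserved(self, tmp_path):
        net = build_network(
            [RecommendationEdge("a", "b")],
            [
                VideoNode("a", vaccine_related=True, stance=Stance.ANTI,
                          source=Source.ACADEMIC_HOSPITAL),
                VideoNode("b", source=Source.PHARMA_FORPROFIT),
            ],
        )
        path = tmp_path / "enum.nodes.csv"
        write_network(net, path, "edgelist_csv")
        text = path.read_text()
        assert "academic_hospital" in text and "pharma_forprofit" in text
        assert "anti" in text
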