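"""Curation, pathway membership and directed shortest-path crosstalk."""

import math
import random

import numpy as np
import pytest
from scipy.sparse.csgraph import floyd_warshall

from ginet.crosstalk import (
    CurationList,
    CurationRemoval,
    apply_curation,
    bipartite_table,
    edge_weight,
    pathway_members,
    shortest_paths_between,
)
from ginet.gin_assembler import GIN, GinEdge, merge_metapathways
from ginet.kgml_io import KgmlEntry, KgmlRelation, PathwayDoc
from ginet.metapath_builder import build_metapathway, intermediate_id

from conftest import random_gin


def triplet_gin(upstream, downstream, species="syn"):
    itm = intermediate_id([downstream], upstream)
    return GIN(
        species,
        frozenset(
            {
                GinEdge(upstream, itm, 2, "activation"),
                GinEdge(downstream, itm, 3, "neutral"),
                GinEdge(itm, downstream, 4, "neutral"),
            }
        ),
    )


class TestEdgeWeight:
    @pytest.mark.parametrize("n, expected", [(2, 1.0), (3, (2 / 3) ** 2),
                                             (4, 0.25), (8, 0.0625)])
    def test_formula(self, n, expected):
        assert edge_weight(n) == pytest.approx(expected)

    def test_strictly_decreasing_and_bounded(self):
        weights = [edge_weight(n) for n in range(2, 40)]
        assert all(a > b for a, b in zip(weights, weights[1:]))
        assert all(0 < w <= 1 for w in weights)

    def test_rejects_degenerate_path(self):
        with pytest.raises(ValueError):
            edge_weight(1)


class TestCuration:
    def test_empty_list_is_identity(self, fixture_gin):
        assert apply_curation(fixture_gin, CurationList()) == fixture_gin

    def test_direct_pair_removal_takes_triplet(self):
        gin = triplet_gin("cpd:C90055", "syn:0077")  # ligand -> receptor artifact
        cur = CurationList((CurationRemoval("cpd:C90055", "syn:0077", "artifact"),))
        assert apply_curation(gin, cur).edges == frozenset()

    def test_unmatched_removal_warns_not_raises(self, fixture_gin, caplog):
        cur = CurationList((CurationRemoval("nope:1", "nope:2"),))
        with caplog.at_level("WARNING", logger="ginet.crosstalk"):
            out = apply_curation(fixture_gin, cur)
        assert out == fixture_gin
        assert any("matched no edges" in r.message for r in caplog.records)

    def test_bridge_removal_disconnects_downstream(self):
        gin = GIN(
            "syn",
            frozenset(
                {
                    GinEdge("a", "b", 2, "neutral"),
                    GinEdge("b", "c", 2, "neutral"),
                }
            ),
        )
        before = shortest_paths_between(gin, {"a"}, {"c"})
        assert before.pairs[0].distance == 3
        cut = apply_curation(gin, CurationList((CurationRemoval("b", "c"),)))
        after = shortest_paths_between(cut, {"a"}, {"c"})
        assert math.isinf(after.pairs[0].distance)

    def test_removal_never_decreases_distances(self):
        rng = random.Random(13)
        gin = random_gin(rng, n_nodes=30, n_edges=80)
        nodes = sorted(gin.nodes)
        set_a, set_b = set(nodes[:5]), set(nodes[-5:])
        before = {
            (p.node_a, p.node_b, p.direction): p.distance
            for p in shortest_paths_between(gin, set_a, set_b).pairs
        }
        victim = sorted(gin.edges)[0]
        cur = CurationList((CurationRemoval(victim.source, victim.target),))
        after = shortest_paths_between(apply_curation(gin, cur), set_a, set_b)
        for p in after.pairs:
            assert p.distance >= before[(p.node_a, p.node_b, p.direction)]


class TestPathwayMembers:
    def test_genes_and_compounds_of_fixture(self, fig1c_doc):
        members = pathway_members(fig1c_doc)
        assert members == {
            "syn:9001", "syn:9002", "syn:9003", "cpd:C99906", "cpd:C99907",
        }

    def test_group_contributes_constituent_genes(self):
        entries = [
            KgmlEntry(1, "gene", ("syn:0001",)),
            KgmlEntry(2, "gene", ("syn:0002", "syn:0003")),
            KgmlEntry(3, "group", (), component_refs=(1, 2)),
            KgmlEntry(4, "map", ("path:syn00999",)),
        ]
        doc = PathwayDoc("syn00001", "syn", entries={e.entry_id: e for e in entries})
        assert pathway_members(doc) == {"syn:0001", "syn:0002", "syn:0003"}

    def test_empty_doc(self):
        assert pathway_members(PathwayDoc("syn00001", "syn")) == set()


class TestShortestPaths:
    def test_adjacent_pair_distance_two(self):
        gin = GIN("syn", frozenset({GinEdge("a", "b", 2, "neutral")}))
        result = shortest_paths_between(gin, {"a"}, {"b"})
        forward = next(p for p in result.pairs if p.direction == "a_to_b")
        backward = next(p for p in result.pairs if p.direction == "b_to_a")
        assert forward.distance == 2 and forward.path == ("a", "b")
        assert forward.weight == 1.0
        assert math.isinf(backward.distance) and backward.path is None

    def test_shared_nodes_excluded_and_reported(self):
        gin = GIN("syn", frozenset({GinEdge("a", "b", 2, "neutral")}))
        result = shortest_paths_between(gin, {"a", "s"}, {"b", "s"})
        assert result.shared_nodes == ("s",)
        assert {p.node_a for p in result.pairs} == {"a"}

    def test_lexicographic_tie_break(self):
        edges = frozenset(
            {
                GinEdge("a", "m2", 2, "neutral"),
                GinEdge("a", "m1", 2, "neutral"),
                GinEdge("m1", "b", 2, "neutral"),
                GinEdge("m2", "b", 2, "neutral"),
            }
        )
        result = shortest_paths_between(GIN("syn", edges), {"a"}, {"b"})
        forward = next(p for p in result.pairs if p.direction == "a_to_b")
        assert forward.path == ("a", "m1", "b")

    def test_distances_match_floyd_warshall_oracle(self):
        rng = random.Random(21)
        for _ in range(10):
            gin = random_gin(rng, n_nodes=rng.randint(20, 120),
                             n_edges=rng.randint(30, 260))
            nodes = sorted(gin.nodes)
            index = {n: i for i, n in enumerate(nodes)}
            adj = np.zeros((len(nodes), len(nodes)))
            for e in gin.edges:
                adj[index[e.source], index[e.target]] = 1
            dist = floyd_warshall(adj, directed=True)
            set_a, set_b = set(nodes[:6]), set(nodes[-6:])
            result = shortest_paths_between(gin, set_a, set_b)
            for p in result.pairs:
                src, dst = (
                    (p.node_a, p.node_b)
                    if p.direction == "a_to_b"
                    else (p.node_b, p.node_a)
                )
                oracle_edges = dist[index[src], index[dst]]
                if np.isinf(oracle_edges):
                    assert math.isinf(p.distance)
                else:
                    assert p.distance == oracle_edges + 1  # nodes = edges + 1

    def test_retained_paths_are_minimal_per_direction(self):
        rng = random.Random(34)
        gin = random_gin(rng, n_nodes=40, n_edges=120)
        nodes = sorted(gin.nodes)
        result = shortest_paths_between(gin, set(nodes[:6]), set(nodes[-6:]))
        for direction in ("a_to_b", "b_to_a"):
            reachable = [
                p.distance
                for p in result.pairs
                if p.direction == direction and p.reachable
            ]
            retained = result.retained[direction]
            if reachable:
                assert retained.distance == min(reachable)
            else:
                assert retained is None


class TestPlantedCrosstalkPair:
    def test_manifest_paths_recovered(self, crosstalk_pair):
        docs, manifest, gin = crosstalk_pair
        doc_a = docs[manifest["pathway_a"]]
        doc_b = docs[manifest["pathway_b"]]
        result = shortest_paths_between(
            gin, pathway_members(doc_a), pathway_members(doc_b)
        )
        assert list(result.shared_nodes) == manifest["shared"]
        for direction in ("a_to_b", "b_to_a"):
            expected = manifest["retained"][direction]
            got = result.retained[direction]
            assert list(got.path) == expected["path"]
            assert got.distance == expected["n_nodes"]
            assert got.weight == pytest.approx(expected["weight"])

    def test_curation_disconnects_artifact_pair(self, crosstalk_pair):
        docs, manifest, gin = crosstalk_pair
        removal = manifest["artifact"]["removal"]
        cur = CurationList(
            (CurationRemoval(removal["source"], removal["target"],
                             removal["reason"]),)
        )
        curated = apply_curation(gin, cur)
        doc_a = docs[manifest["pathway_a"]]
        doc_b = docs[manifest["pathway_b"]]
        result = shortest_paths_between(
            curated, pathway_members(doc_a), pathway_members(doc_b)
        )
        pa, pb = manifest["artifact"]["pair"]
        pair = next(
            p
            for p in result.pairs
            if (p.node_a, p.node_b, p.direction) == (pa, pb, "a_to_b")
        )
        assert math.isinf(pair.distance)
        # the genuine bridge still carries the retained path
        retained = result.retained["a_to_b"]
        assert list(retained.path) == manifest["bridges"]["a_to_b"]["path"]


class TestBipartiteTable:
    def test_single_reachable_pair_row(self):
        gin = GIN(
            "syn",
            frozenset({GinEdge("a", "m", 2, "neutral"), GinEdge("m", "b", 2, "neutral")}),
        )
        table = bipartite_table(shortest_paths_between(gin, {"a"}, {"b"}))
        assert len(table) == 1
        row = table.iloc[0]
        assert (row.node_a, row.node_b, row.direction, row.distance) == (
            "a", "b", "a_to_b", 3,
        )
        assert row.weight == pytest.approx((2 / 3) ** 2)

    def test_unreachable_pairs_give_empty_table(self):
        gin = GIN("syn", frozenset({GinEdge("a", "x", 2, "neutral"),
                                    GinEdge("y", "b", 2, "neutral")}))
        table = bipartite_table(shortest_paths_between(gin, {"a"}, {"b"}))
        assert table.empty

    def test_no_intermediate_endpoints_in_real_pipeline(self, crosstalk_pair):
        docs, manifest, gin = crosstalk_pair
        result = shortest_paths_between(
            gin,
            pathway_members(docs[manifest["pathway_a"]]),
            pathway_members(docs[manifest["pathway_b"]]),
        )
        table = bipartite_table(result)
        assert not table.empty
        assert not table.node_a.str.startswith("ITM[").any()
        assert not table.node_b.str.startswith("ITM[").any()
        assert ((table.weight > 0) & (table.weight <= 1)).all()


def test_fig4_style_out_path_through_compound_conversion():
    """A metabolite converted by an enzyme reaches a receptor's cascade.

    Mirrors the published worked example's shape: pathway A's compound is
    converted into a second compound, which activates a receptor that
    sits in pathway B — all through intermediates in the merged GIN.
    """
    entries_a = [
        KgmlEntry(1, "compound", ("cpd:C00026",)),
        KgmlEntry(2, "compound", ("cpd:C00025",)),
        KgmlEntry(3, "gene", ("hsa:2746",), reaction_ref="rn:R00243"),
    ]
    from ginet.kgml_io import KgmlReaction

    doc_a = PathwayDoc(
        "hsa00020", "hsa",
        entries={e.entry_id: e for e in entries_a},
        reactions=(KgmlReaction("rn:R00243", "irreversible", (1,), (2,), (3,)),),
    )
    entries_b = [
        KgmlEntry(1, "compound", ("cpd:C00025",)),
        KgmlEntry(2, "gene", ("hsa:2911",)),
        KgmlEntry(3, "gene", ("hsa:5594",)),
    ]
    doc_b = PathwayDoc(
        "hsa04010", "hsa",
        entries={e.entry_id: e for e in entries_b},
        relations=(
            KgmlRelation(1, 2, "PCrel", ("activation",), "PCrel"),
            KgmlRelation(2, 3, "PPrel", ("activation",), "PPrel"),
        ),
    )
    gin = merge_metapathways([build_metapathway(doc_a), build_metapathway(doc_b)])
    result = shortest_paths_between(
        gin, pathway_members(doc_a), pathway_members(doc_b)
    )
    retained = result.retained["a_to_b"]
    assert retained is not None
    # glutamate is shared, so the retained route starts at 2-oxoglutarate
    assert retained.path[0] == "cpd:C00026"
    assert retained.path[-1] in {"hsa:2911", "hsa:5594"}
    assert "cpd:C00025" in retained.path
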