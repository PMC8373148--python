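"""Pathway overlay semantics: edge classes, node colouring, neighbourhoods."""

import numpy as np
import pytest

from disconet import (
    CoexpressionNetwork,
    PathwayCollection,
    PathwayGraph,
    expand_complexes,
    classify_edges,
    color_nodes,
    coexpression_neighbors,
    neighborhood_enrichment,
)
from disconet.datatypes import degtable
from disconet.overlay import covered_proteins


@pytest.fixture
def mixed_complex_pathway():
    """A small mixed protein/complex pathway diagram."""
    kinds = {"P1": "protein", "P2": "protein", "P3": "protein",
             "CXA": "complex", "CXB": "complex"}
    members = {"CXA": frozenset({"M1", "M2"}),
               "CXB": frozenset({"M3", "M4", "M5"})}
    edges = [
        ("P1", "P2", "interaction"),
        ("P2", "CXA", "interaction"),
        ("CXA", "CXB", "interaction"),
        ("P3", "CXB", "interaction"),
        ("M1", "CXA", "membership"),
        ("M2", "CXA", "membership"),
    ]
    return PathwayGraph(kinds, members, edges)


def network(pairs, label="d"):
    return CoexpressionNetwork(
        label=label, universe_size=50,
        edges={tuple(sorted(p)): 0.8 for p in pairs})


class TestExpansion:
    def test_protein_and_complex_expansion(self, mixed_complex_pathway):
        exp = expand_complexes(mixed_complex_pathway)
        assert exp["P1"] == frozenset({"P1"})
        assert exp["CXB"] == frozenset({"M3", "M4", "M5"})

    def test_unique_protein_count_by_brute_force(self, mixed_complex_pathway):
        proteins = covered_proteins(mixed_complex_pathway)
        expected = {"P1", "P2", "P3", "M1", "M2", "M3", "M4", "M5"}
        assert proteins == expected

    def test_empty_complex_rejected(self):
        with pytest.raises(ValueError, match="members"):
            PathwayGraph({"C": "complex"}, {"C": frozenset()}, [])


class TestClassifyEdges:
    def test_disease_only_match(self, mixed_complex_pathway):
        overlay = classify_edges(mixed_complex_pathway,
                                 network([("P1", "P2")]), network([]))
        assert overlay["P1"]["P2"]["edge_class"] == "pathway∩disease"

    def test_no_networks_all_pathway_only(self, mixed_complex_pathway):
        overlay = classify_edges(mixed_complex_pathway, None, None)
        classes = {d["edge_class"]
                   for a, b, d in overlay.edges(data=True)
                   if d["edge_class"] != "membership"}
        assert classes == {"pathway-only"}

    def test_complex_edge_matches_via_any_member_pair(self, mixed_complex_pathway):
        # a single member pair across CXA x CXB suffices
        overlay = classify_edges(mixed_complex_pathway,
                                 network([("M2", "M4")]), None)
        assert overlay["CXA"]["CXB"]["edge_class"] == "pathway∩disease"

    def test_four_planted_matches_counted_exactly(self, mixed_complex_pathway):
        disease = network([("P1", "P2"), ("P2", "M1"), ("M1", "M3"),
                           ("P3", "M5")])
        normal = network([("P1", "P2")], label="normal")
        overlay = classify_edges(mixed_complex_pathway, disease, normal)
        classes = {(a, b): d["edge_class"]
                   for a, b, d in overlay.edges(data=True)}
        get = lambda x, y: classes.get((x, y), classes.get((y, x)))
        assert get("P1", "P2") == "pathway∩both"
        assert get("P2", "CXA") == "pathway∩disease"
        assert get("CXA", "CXB") == "pathway∩disease"
        assert get("P3", "CXB") == "pathway∩disease"
        n_matched = sum(1 for c in classes.values()
                        if c.startswith("pathway∩"))
        assert n_matched == 4

    def test_membership_edges_pass_through(self, mixed_complex_pathway):
        overlay = classify_edges(mixed_complex_pathway, network([]), None)
        assert overlay["M1"]["CXA"]["edge_class"] == "membership"

    def test_coexpression_only_restricted_to_covered_proteins(
            self, mixed_complex_pathway):
        disease = network([("P1", "M5"), ("Z1", "Z2")])
        overlay = classify_edges(mixed_complex_pathway, disease, None)
        # P1-M5 is a within-pathway correlation matching no drawn
        # interaction; Z1-Z2 lies outside the pathway's protein cover
        assert overlay.has_edge("P1", "M5")
        assert overlay["M5"]["P1"]["edge_class"] == "coexpression-only"
        assert not overlay.has_edge("Z1", "Z2")
        # a member pair covered by the CXA-CXB interaction is not
        # duplicated as a coexpression-only edge
        covered = classify_edges(mixed_complex_pathway, network([("M1", "M5")]),
                                 None)
        assert not covered.has_edge("M1", "M5")

    def test_partition_over_pathway_edges(self, mixed_complex_pathway, rng):
        proteins = sorted(covered_proteins(mixed_complex_pathway))
        for trial in range(10):
            local = np.random.default_rng(trial)
            pick = lambda: {tuple(sorted(local.choice(proteins, 2,
                                                      replace=False)))
                            for _ in range(4)}
            overlay = classify_edges(mixed_complex_pathway,
                                     network(pick()), network(pick()))
            for a, b, etype in mixed_complex_pathway.edges:
                if etype == "interaction":
                    cls = overlay[a][b]["edge_class"]
                    assert cls in {"pathway∩both", "pathway∩disease",
                                   "pathway∩normal", "pathway-only"}

    def test_removing_normal_only_downgrades_normal_classes(
            self, mixed_complex_pathway, rng):
        disease = network([("P1", "P2"), ("M1", "M3")])
        normal = network([("P1", "P2"), ("P3", "M4")], label="normal")
        with_normal = classify_edges(mixed_complex_pathway, disease, normal)
        without = classify_edges(mixed_complex_pathway, disease, None)
        moves = {"pathway∩both": "pathway∩disease",
                 "pathway∩normal": "pathway-only"}
        for a, b, etype in mixed_complex_pathway.edges:
            before = with_normal[a][b]["edge_class"]
            after = without[a][b]["edge_class"]
            assert after == moves.get(before, before)


class TestColorNodes:
    def _degs(self, spec):
        genes = list(spec)
        lfc = np.array([spec[g][0] for g in genes], float)
        adj = np.array([spec[g][1] for g in genes], float)
        return degtable(lfc, adj, adj, genes)

    def test_complex_consensus_rules(self, mixed_complex_pathway):
        overlay = classify_edges(mixed_complex_pathway, None, None)
        # all CXA members up, CXB mixed
        degs = self._degs({"M1": (1.0, 0.01), "M2": (2.0, 0.2),
                           "M3": (1.0, 0.01), "M4": (-1.0, 0.01),
                           "M5": (1.0, 0.01),
                           "P1": (1.5, 0.001), "P2": (-0.5, 0.3),
                           "P3": (0.0, 0.9)})
        colored = color_nodes(overlay, degs)
        assert colored.nodes["CXA"]["complex_consensus"] == "up"
        assert colored.nodes["CXB"]["complex_consensus"] == "mixed"
        assert colored.nodes["P1"]["de_direction"] == "up"
        assert colored.nodes["P1"]["de_significant"] is True
        assert colored.nodes["P2"]["de_significant"] is False
        assert colored.nodes["P3"]["de_direction"] == "none"

    def test_absent_member_gives_unknown(self, mixed_complex_pathway):
        overlay = classify_edges(mixed_complex_pathway, None, None)
        degs = self._degs({"M1": (1.0, 0.01)})  # M2 absent
        colored = color_nodes(overlay, degs)
        assert colored.nodes["CXA"]["complex_consensus"] == "unknown"

    def test_absent_protein_stays_neutral(self, mixed_complex_pathway):
        overlay = classify_edges(mixed_complex_pathway, None, None)
        colored = color_nodes(overlay, self._degs({"M1": (1.0, 0.01),
                                                   "M2": (1.0, 0.01),
                                                   "M3": (1.0, 0.01),
                                                   "M4": (1.0, 0.01),
                                                   "M5": (1.0, 0.01)}))
        assert colored.nodes["P1"]["de_direction"] == "none"
        assert colored.nodes["P1"]["de_significant"] is False

    def test_brute_force_member_scan(self, mixed_complex_pathway, rng):
        overlay = classify_edges(mixed_complex_pathway, None, None)
        proteins = sorted(covered_proteins(mixed_complex_pathway))
        for trial in range(10):
            local = np.random.default_rng(trial)
            present = [p for p in proteins if local.random() > 0.3]
            spec = {p: (float(local.choice([-1.0, 1.0])),
                        float(local.uniform(0, 0.1))) for p in present}
            colored = color_nodes(overlay, self._degs(spec))
            for cx, members in mixed_complex_pathway.members.items():
                expected = "unknown" if any(m not in spec for m in members) \
                    else ("up" if all(spec[m][0] > 0 for m in members)
                          else "down" if all(spec[m][0] < 0 for m in members)
                          else "mixed")
                assert colored.nodes[cx]["complex_consensus"] == expected


class TestNeighborhood:
    def test_neighbor_sets(self):
        star = network([("hub", f"s{i}") for i in range(4)])
        assert coexpression_neighbors(star, "hub") == \
            {"s0", "s1", "s2", "s3"}
        assert coexpression_neighbors(star, "isolated") == set()

    def test_enrichment_matches_two_step_pipeline(self):
        from disconet.similarity import enrich as direct_enrich
        net = network([("hub", "A"), ("hub", "B"), ("hub", "C")])
        pathways = PathwayCollection({"PW1": frozenset({"A", "B", "C"}),
                                      "PW2": frozenset({"X", "Y"})})
        universe = {"hub", "A", "B", "C", "X", "Y"} \
            | {f"bg{i}" for i in range(20)}
        table = neighborhood_enrichment(net, "hub", pathways, universe)
        expected = direct_enrich({"A", "B", "C"}, pathways, universe)
        assert np.allclose(table["p"], expected["p"])
        assert table.iloc[0]["pathway"] == "PW1"
        assert table[table["pathway"] == "PW1"]["overlap"].iloc[0] == 3

    def test_no_neighbors_empty_table(self):
        net = network([("A", "B")])
        pathways = PathwayCollection({"PW": frozenset({"A"})})
        table = neighborhood_enrichment(net, "absent", pathways, {"A", "B"})
        assert table.empty
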