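"""Tie extraction, network construction, symmetrization, and matrices."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from sociosurvey.networks import (
    DegenerateNetworkError,
    NetworkError,
    adjacency_matrix,
    build_one_mode,
    build_two_mode,
    extract_ties,
    filter_by_level,
    from_adjacency_matrix,
    from_incidence_matrix,
    incidence_matrix,
    project_persons,
    reciprocity,
    symmetrize,
)
from sociosurvey.responses import ResponseSet, RespondentResponse
from sociosurvey.survey import Person, Roster, generated_item_id

from conftest import make_roster, net_from_edges
from _oracles import brute_symmetrize_any, brute_symmetrize_mutual, random_connected_digraph


def _rs(answers_by_person: dict) -> ResponseSet:
    return ResponseSet(
        questionnaire_id="study", wave="wave1",
        responses=tuple(
            RespondentResponse(person_id=p, wave="wave1", answers=a)
            for p, a in answers_by_person.items()
        ),
    )


class TestExtractTies:
    def test_best_friend_answer_becomes_max_weight_tie(self, friend_template):
        rs = _rs({"p1": {generated_item_id("friend", "p2"): "3"}})
        ties = extract_ties(rs, friend_template)
        assert len(ties) == 1
        assert ties[0].weight == friend_template.scale.max_weight

    def test_unanswered_and_absent_levels_give_no_ties(self, friend_template):
        rs = _rs({"p1": {generated_item_id("friend", "p2"): "0"}, "p2": {}})
        assert extract_ties(rs, friend_template) == []

    def test_exhaustive_enumeration_of_answered_items(self, friend_template):
        # 3 egos x 2 alters, all above the absent level -> 6 ties
        answers = {
            ego: {generated_item_id("friend", alter): "2"
                  for alter in ("x", "y")}
            for ego in ("a", "b", "c")
        }
        ties = extract_ties(_rs(answers), friend_template)
        assert len(ties) == 6
        assert {(t.ego_id, t.alter_id) for t in ties} == set(
            itertools.product(("a", "b", "c"), ("x", "y"))
        )

    def test_template_must_belong_to_questionnaire(self, friend_template, questionnaire10):
        other = friend_template.__class__(
            id="enemy", prompt="{alter}?", relation_label="enmity",
            mode="one_mode", roster_ref="class",
        )
        with pytest.raises(Exception, match="not part of questionnaire"):
            extract_ties(_rs({}), other, questionnaire10)


class TestBuildOneMode:
    def test_isolates_preserved(self, roster10):
        net = build_one_mode([], roster10)
        assert net.graph.number_of_nodes() == 10
        assert net.graph.number_of_edges() == 0

    def test_directed_pair(self, friend_template, roster10):
        rs = _rs({"p1": {generated_item_id("friend", "p2"): "2"},
                  "p2": {generated_item_id("friend", "p1"): "1"}})
        net = build_one_mode(extract_ties(rs, friend_template), roster10)
        assert net.graph.has_edge("p1", "p2") and net.graph.has_edge("p2", "p1")
        assert net.graph["p1"]["p2"]["weight"] == 2.0

    def test_star_in_degree(self, roster10):
        from sociosurvey.networks import TieRecord
        ties = [TieRecord(ego_id=f"p{i}", alter_id="p1", relation_label="friendship", weight=1.0)
                for i in range(2, 11)]
        net = build_one_mode(ties, roster10)
        assert net.graph.in_degree("p1") == 9

    def test_unknown_person_rejected(self, roster10):
        from sociosurvey.networks import TieRecord
        with pytest.raises(NetworkError, match="not on the roster"):
            build_one_mode([TieRecord("p1", "ghost", "friendship", 1.0)], roster10)

    def test_attributes_attached(self, roster10):
        net = build_one_mode([], roster10, attributes={"p1": {"audit_total": 12}})
        assert net.graph.nodes["p1"]["audit_total"] == 12


class TestFilterByLevel:
    def test_minimum_level_is_identity(self):
        net = net_from_edges([("a", "b", 1), ("b", "c", 3)], nodes="abc")
        kept = filter_by_level(net, 1.0)
        assert set(kept.graph.edges) == set(net.graph.edges)

    def test_above_maximum_empties_edges_keeps_nodes(self):
        net = net_from_edges([("a", "b", 3)], nodes="abc")
        kept = filter_by_level(net, 4.0)
        assert kept.graph.number_of_edges() == 0
        assert kept.graph.number_of_nodes() == 3

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(7)
        g = random_connected_digraph(rng, 8, 0.3)
        net = net_from_edges([(u, v, d["weight"]) for u, v, d in g.edges(data=True)],
                             nodes=range(8))
        for level in (1.0, 2.0, 3.0):
            kept = filter_by_level(net, level)
            expected = {(u, v) for u, v, d in g.edges(data=True) if d["weight"] >= level}
            assert set(kept.graph.edges) == expected

    def test_monotone_in_level(self):
        net = net_from_edges([("a", "b", 1), ("b", "c", 2), ("c", "a", 3)])
        e1 = set(filter_by_level(net, 2.0).graph.edges)
        e2 = set(filter_by_level(net, 3.0).graph.edges)
        assert e2 <= e1


class TestSymmetrize:
    def test_one_way_tie_dropped_under_mutual(self):
        net = net_from_edges([("a", "b")], nodes="ab")
        assert symmetrize(net, "mutual").graph.number_of_edges() == 0

    def test_mutual_dyad_kept(self):
        net = net_from_edges([("a", "b", 1), ("b", "a", 3)])
        sym = symmetrize(net, "mutual", weight_rule="min")
        assert sym.graph["a"]["b"]["weight"] == 1.0
        sym_max = symmetrize(net, "mutual", weight_rule="max")
        assert sym_max.graph["a"]["b"]["weight"] == 3.0

    def test_matches_pairwise_oracle_on_random_digraphs(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            g = random_connected_digraph(rng, 10, 0.25)
            net = net_from_edges([(u, v, d["weight"]) for u, v, d in g.edges(data=True)],
                                 nodes=range(10))
            mutual = {tuple(sorted(e)) for e in symmetrize(net, "mutual").graph.edges}
            any_ = {tuple(sorted(e)) for e in symmetrize(net, "any").graph.edges}
            assert mutual == brute_symmetrize_mutual(g)
            assert any_ == brute_symmetrize_any(g)
            assert mutual <= any_


class TestReciprocity:
    def test_all_mutual_is_one(self):
        net = net_from_edges([("a", "b"), ("b", "a"), ("b", "c"), ("c", "b")])
        assert reciprocity(net) == 1.0

    def test_tournament_is_zero(self):
        net = net_from_edges([("a", "b"), ("b", "c"), ("a", "c")])
        assert reciprocity(net) == 0.0

    def test_two_of_three_reciprocated(self):
        net = net_from_edges([("a", "b"), ("b", "a"), ("a", "c")])
        assert reciprocity(net) == pytest.approx(2 / 3)

    def test_edgeless_is_signaled(self):
        net = net_from_edges([], nodes="ab")
        with pytest.raises(DegenerateNetworkError):
            reciprocity(net)


class TestTwoMode:
    @pytest.fixture
    def venues(self):
        return Roster(id="venues", members=(
            Person(id="v1", display_name="Bar One"),
            Person(id="v2", display_name="Plaza"),
        ))

    def test_full_incidence(self, venues):
        from sociosurvey.networks import TieRecord
        persons = make_roster(2)
        ties = [TieRecord(p.id, v.id, "venue", 1.0)
                for p in persons.members for v in venues.members]
        net = build_two_mode(ties, persons, venues)
        assert net.graph.number_of_edges() == 4

    def test_empty_ties_keep_bipartite_node_sets(self, venues):
        net = build_two_mode([], make_roster(3), venues)
        assert net.graph.number_of_nodes() == 5
        assert net.graph.number_of_edges() == 0

    def test_projection_matches_pairwise_intersection(self, venues):
        from sociosurvey.networks import TieRecord
        persons = make_roster(4)
        ties = [TieRecord("p1", "v1", "venue", 1.0), TieRecord("p2", "v1", "venue", 1.0),
                TieRecord("p3", "v2", "venue", 1.0), TieRecord("p2", "v2", "venue", 1.0)]
        net = build_two_mode(ties, persons, venues)
        proj = project_persons(net)
        # brute force: persons share an edge iff their venue sets intersect
        venues_of = {"p1": {"v1"}, "p2": {"v1", "v2"}, "p3": {"v2"}, "p4": set()}
        expected = {
            tuple(sorted((a, b)))
            for a, b in itertools.combinations(venues_of, 2)
            if venues_of[a] & venues_of[b]
        }
        assert {tuple(sorted(e)) for e in proj.graph.edges} == expected
        assert proj.graph["p1"]["p2"]["weight"] == 1.0

    def test_person_to_person_tie_rejected(self, venues):
        from sociosurvey.networks import TieRecord
        with pytest.raises(NetworkError, match="person -> entity"):
            build_two_mode([TieRecord("p1", "p2", "venue", 1.0)], make_roster(2), venues)


class TestMatrixRoundTrip:
    def test_one_mode_round_trip_exact(self):
        rng = np.random.default_rng(3)
        g = random_connected_digraph(rng, 6, 0.3)
        net = net_from_edges([(u, v, d["weight"]) for u, v, d in g.edges(data=True)],
                             nodes=[str(i) for i in range(6)], relation="friendship")
        back = from_adjacency_matrix(adjacency_matrix(net))
        assert set(back.graph.edges) == {(str(u), str(v)) for u, v in net.graph.edges}
        for u, v, d in net.graph.edges(data=True):
            assert back.graph[str(u)][str(v)]["weight"] == d["weight"]

    def test_adjacency_is_square_roster_sized(self, roster10):
        net = build_one_mode([], roster10)
        m = adjacency_matrix(net)
        assert m.shape == (10, 10)

    def test_two_mode_round_trip_exact(self):
        from sociosurvey.networks import TieRecord
        persons = make_roster(3)
        venues = Roster(id="v", members=(Person(id="v1", display_name="V1"),
                                         Person(id="v2", display_name="V2")))
        ties = [TieRecord("p1", "v1", "venue", 2.0), TieRecord("p3", "v2", "venue", 1.0)]
        net = build_two_mode(ties, persons, venues)
        m = incidence_matrix(net)
        assert m.shape == (3, 2)
        back = from_incidence_matrix(m)
        assert set(back.graph.edges) == {("p1", "v1"), ("p3", "v2")}
        assert back.graph["p1"]["v1"]["weight"] == 2.0
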