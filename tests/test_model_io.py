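"""Domain types, CSV readers, and export round-trips."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sociometry import (
    Actor,
    Category,
    Level,
    Nomination,
    Role,
    SurveyResponse,
    build_network,
    calibrated_fixture,
    read_edgelist,
    read_graphml,
    read_roster,
    read_survey,
    read_survey_wide,
    write_edgelist,
    write_graphml,
)
from sociometry.model import hash_name


class TestDomainInvariants:
    def test_policymaker_requires_level(self):
        with pytest.raises(ValueError, match="level"):
            Actor(actor_id="p1", role=Role.policymaker, level=Level.none)

    def test_self_nomination_rejected(self):
        with pytest.raises(ValueError, match="self-nomination"):
            Nomination(source_id="a", target_id="a", category=Category.via_peer)

    def test_nomination_cap_enforced(self):
        noms = [
            Nomination(source_id="r", target_id=f"p{i}", category=Category.direct_to_pm)
            for i in range(8)
        ]
        with pytest.raises(ValueError, match="direct_to_pm"):
            SurveyResponse(respondent_id="r", nominations=noms, cap=7)
        # exactly at the cap is fine
        SurveyResponse(respondent_id="r", nominations=noms[:7], cap=7)

    def test_foreign_nomination_rejected(self):
        nom = Nomination(source_id="x", target_id="p", category=Category.direct_to_pm)
        with pytest.raises(ValueError, match="attached"):
            SurveyResponse(respondent_id="r", nominations=[nom])

    def test_hash_name_is_stable_and_opaque(self):
        assert hash_name("Jane Doe") == hash_name("  jane doe ")
        assert "jane" not in hash_name("Jane Doe", prefix="F")


class TestRoster:
    def test_empty_roster(self, tmp_path):
        path = tmp_path / "roster.csv"
        path.write_text("actor_id,role\n")
        assert read_roster(path) == []

    def test_duplicate_id_names_offender(self, tmp_path):
        path = tmp_path / "roster.csv"
        path.write_text("actor_id,role\nA,faculty\nB,faculty\nA,faculty\n")
        with pytest.raises(ValueError, match="A"):
            read_roster(path)

    def test_missing_required_column(self, tmp_path):
        path = tmp_path / "roster.csv"
        path.write_text("display_code,role\nA,faculty\n")
        with pytest.raises(ValueError, match="actor_id"):
            read_roster(path)

    def test_packaged_fixture_counts(self, roster_path):
        actors = read_roster(roster_path)
        assert len(actors) == 10
        roles = [a.role for a in actors]
        assert roles.count(Role.policymaker) == 4
        assert roles.count(Role.faculty) == 6

    def test_unknown_level_warns_and_defaults(self, tmp_path, caplog):
        path = tmp_path / "roster.csv"
        path.write_text("actor_id,role,level\nA,faculty,galactic\n")
        with caplog.at_level("WARNING"):
            (actor,) = read_roster(path)
        assert actor.level == Level.none
        assert "galactic" in caplog.text


class TestSurvey:
    def test_empty_survey_yields_empty_responses_for_respondents(
        self, tmp_path, roster_path
    ):
        roster = read_roster(roster_path)
        path = tmp_path / "survey.csv"
        path.write_text("respondent_id,target_id,category\n")
        responses = read_survey(path, roster)
        assert len(responses) == 5  # one (empty) response per roster respondent
        assert all(r.nominations == [] for r in responses)

    def test_cap_violation_names_respondent_and_category(self, tmp_path, roster_path):
        roster = read_roster(roster_path)
        rows = "".join(
            f"FA01,T{i},direct_to_pm\n" for i in range(8)
        )
        path = tmp_path / "survey.csv"
        path.write_text("respondent_id,target_id,category\n" + rows)
        with pytest.raises(ValueError, match="FA01.*direct_to_pm"):
            read_survey(path, roster)

    def test_packaged_fixture_counts(self, roster_path, survey_path):
        roster = read_roster(roster_path)
        responses = read_survey(survey_path, roster)
        assert len(responses) == 5
        assert sum(len(r.nominations) for r in responses) == 11

    def test_self_nomination_dropped_with_warning(self, tmp_path, roster_path, caplog):
        roster = read_roster(roster_path)
        path = tmp_path / "survey.csv"
        path.write_text(
            "respondent_id,target_id,category\nFA01,FA01,via_peer\nFA01,PM01,direct_to_pm\n"
        )
        with caplog.at_level("WARNING"):
            responses = read_survey(path, roster)
        fa01 = next(r for r in responses if r.respondent_id == "FA01")
        assert len(fa01.nominations) == 1
        assert "self-nomination" in caplog.text

    def test_unknown_target_auto_registered_by_category(self, tmp_path, roster_path):
        roster = read_roster(roster_path)
        path = tmp_path / "survey.csv"
        path.write_text(
            "respondent_id,target_id,category\n"
            "FA01,NEWPM,direct_to_pm\nFA02,NEWPEER,via_peer\n"
        )
        read_survey(path, roster)
        index = {a.actor_id: a for a in roster}
        assert index["NEWPM"].role == Role.policymaker
        assert not index["NEWPM"].is_respondent
        assert index["NEWPEER"].role == Role.faculty

    def test_wide_reader_matches_long_reader(self, tmp_path, roster_path):
        roster_long = read_roster(roster_path)
        roster_wide = read_roster(roster_path)
        long_path = tmp_path / "long.csv"
        long_path.write_text(
            "respondent_id,target_id,category\n"
            "FA01,PM01,direct_to_pm\nFA01,PM02,direct_to_pm\nFA01,FA02,via_peer\n"
        )
        wide_path = tmp_path / "wide.csv"
        wide_path.write_text(
            "respondent_id,direct_to_pm_1,direct_to_pm_2,via_peer_1\n"
            "FA01,PM01,PM02,FA02\n"
        )
        long_resp = read_survey(long_path, roster_long)
        wide_resp = read_survey_wide(wide_path, roster_wide)
        key = lambda rs: {
            r.respondent_id: sorted((n.target_id, n.category.value) for n in r.nominations)
            for r in rs
        }
        assert key(long_resp) == key(wide_resp)


class TestExports:
    def test_empty_network_edgelist_is_header_only(self, tmp_path):
        from sociometry.builder import SociometricNetwork

        path = tmp_path / "edges.csv"
        write_edgelist(SociometricNetwork(), path)
        df = pd.read_csv(path, comment="#")
        assert list(df.columns) == ["source", "target", "link_type", "reciprocal"]
        assert df.empty

    def test_reciprocal_pair_is_single_record_in_link_mode(self):
        roster = [
            Actor(actor_id="A", is_respondent=True),
            Actor(actor_id="B", is_respondent=True),
        ]
        responses = [
            SurveyResponse(
                respondent_id="A",
                nominations=[
                    Nomination(source_id="A", target_id="B", category=Category.via_peer)
                ],
            ),
            SurveyResponse(
                respondent_id="B",
                nominations=[
                    Nomination(source_id="B", target_id="A", category=Category.via_peer)
                ],
            ),
        ]
        net = build_network(responses, roster, counting_mode="link")
        records = net.links()
        assert len(records) == 1 and records[0].reciprocal
        net_arc = build_network(responses, roster, counting_mode="arc")
        assert len(net_arc.links()) == 2

    def test_edgelist_round_trip_on_calibrated_network(
        self, tmp_path, calibrated, calibrated_network
    ):
        roster, _ = calibrated
        path = tmp_path / "edges.csv"
        write_edgelist(calibrated_network, path)
        back = read_edgelist(path, roster)
        assert set(back.actors) == set(calibrated_network.actors)
        assert back.arcs == calibrated_network.arcs
        assert back.arc_types == calibrated_network.arc_types
        assert back.isolate_count == calibrated_network.isolate_count
        assert back.respondent_count == calibrated_network.respondent_count

    def test_graphml_round_trip_is_exact(self, tmp_path, calibrated_network):
        path = tmp_path / "net.graphml"
        write_graphml(calibrated_network, path)
        back = read_graphml(path)
        assert back.actors == calibrated_network.actors
        assert back.arcs == calibrated_network.arcs
        assert back.arc_types == calibrated_network.arc_types
        assert back.alter_ids == calibrated_network.alter_ids
        assert back.isolate_count == calibrated_network.isolate_count

    @settings(max_examples=25, deadline=None)
    @given(st.data())
    def test_graphml_round_trip_on_generated_networks(self, tmp_path_factory, data):
        """Round-trip identity holds for arbitrary small generated networks."""
        n_pm = data.draw(st.integers(1, 4))
        n_fac = data.draw(st.integers(1, 5))
        roster = [
            Actor(actor_id=f"F{i}", is_respondent=True) for i in range(n_fac)
        ] + [
            Actor(actor_id=f"P{i}", role=Role.policymaker, level=Level.national)
            for i in range(n_pm)
        ]
        responses = []
        for i in range(n_fac):
            noms = []
            targets = data.draw(
                st.lists(st.integers(0, n_pm - 1), unique=True, max_size=n_pm)
            )
            for t in targets:
                noms.append(
                    Nomination(
                        source_id=f"F{i}",
                        target_id=f"P{t}",
                        category=Category.direct_to_pm,
                    )
                )
            responses.append(SurveyResponse(respondent_id=f"F{i}", nominations=noms))
        net = build_network(responses, roster)
        path = tmp_path_factory.mktemp("gml") / "net.graphml"
        write_graphml(net, path)
        back = read_graphml(path)
        assert back.actors == net.actors
        assert back.arcs == net.arcs
        assert back.alter_ids == net.alter_ids
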