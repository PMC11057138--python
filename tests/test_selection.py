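"""Broker scoring/selection and the key-policymaker threshold rule."""

import pytest

from sociometry import (
    eligible_candidates,
    select_brokers,
    select_key_policymakers,
    total_score,
)
from sociometry.centrality import CentralityRecord
from sociometry.selection import BrokerScore, PolicymakerTally, score_candidates


def _rec(aid, pm=0, op=0, ip=0, bw=0.0):
    return CentralityRecord(
        actor_id=aid,
        outdeg_pm=pm,
        outdeg_peer=op,
        indeg_peer=ip,
        betweenness_norm_x100=bw,
    )


def _score(aid, a, b, c, d):
    return BrokerScore(
        actor_id=aid,
        outdeg_pm_norm=a,
        indeg_peer_norm=b,
        outdeg_peer_norm=c,
        betweenness_norm_x100=d,
        total_score=a + b + c + d,
    )


#: the four published broker indicator vectors (normalized degree counts
#: 4,3,3 / 4,2,4 / 4,3,2 / 3,2,3 under truncation, plus betweenness)
PUBLISHED_BROKERS = {
    "FA08": (57.14, 42.85, 42.85, 52.9),
    "FA07": (57.14, 28.57, 57.14, 35.4),
    "FA05": (57.14, 42.85, 28.57, 7.5),
    "FIs01": (42.85, 28.57, 42.85, 2.86),
}
PUBLISHED_TOTALS = {
    "FA08": 195.74,
    "FA07": 178.25,
    "FA05": 136.06,
    "FIs01": 117.13,
}


class TestEligibility:
    def test_pm_links_without_peer_arcs_excluded(self):
        """High policymaker out-degree alone is not brokerage: with no peer
        arcs the actor links nothing to anyone's peers."""
        star = _rec("FT01", pm=7)
        assert eligible_candidates([star]) == []

    def test_all_zero_excluded(self):
        assert eligible_candidates([_rec("Z")]) == []

    def test_enumerated_cohort(self):
        cohort = [
            _rec("A", pm=1, op=1),   # eligible: pm + peer out
            _rec("B", pm=1, ip=1),   # eligible: pm + peer in
            _rec("C", pm=2),         # no peer arcs
            _rec("D", op=3, ip=2),   # no pm link
            _rec("E"),               # isolate-like
            _rec("F", pm=1, op=1, ip=1),
        ]
        assert [r.actor_id for r in eligible_candidates(cohort)] == ["A", "B", "F"]

    def test_custom_rule(self):
        cohort = [_rec("A", pm=1), _rec("B", pm=2)]
        out = eligible_candidates(cohort, rule=lambda r: r.outdeg_pm >= 2)
        assert [r.actor_id for r in out] == ["B"]


class TestTotalScore:
    @pytest.mark.parametrize("code", sorted(PUBLISHED_TOTALS))
    def test_published_indicator_sums(self, code):
        assert total_score(PUBLISHED_BROKERS[code]) == pytest.approx(
            PUBLISHED_TOTALS[code], abs=1e-9
        )

    def test_all_zero(self):
        assert total_score((0.0, 0.0, 0.0, 0.0)) == 0.0

    def test_score_candidates_applies_truncation(self):
        rec = _rec("FA08", pm=4, ip=3, op=3, bw=52.9)
        (score,) = score_candidates([rec], cap=7, paper_compat=True)
        assert score.outdeg_pm_norm == 57.14
        assert score.indeg_peer_norm == 42.85
        assert score.total_score == pytest.approx(195.74)


class TestSelectBrokers:
    def test_single_candidate_selected(self):
        (result,) = select_brokers([_score("A", 1, 1, 1, 1)])
        assert result.selected

    def test_dominance_fixture_selects_exactly_the_four(self):
        """The four published rows plus 20 synthetic candidates dominated on
        every indicator: only the four should pass the top-half rule."""
        scores = [_score(code, *vec) for code, vec in PUBLISHED_BROKERS.items()]
        for i in range(20):
            # strictly below the weakest published row on all four indicators
            scores.append(_score(f"S{i:02d}", 14.28, 14.28, 14.28, 1.0 + i * 0.01))
        result = select_brokers(scores, quantile=0.5)
        selected = {s.actor_id for s in result if s.selected}
        assert selected == set(PUBLISHED_BROKERS)

    def test_tie_symmetry(self):
        tied = [_score("A", 5, 5, 5, 5), _score("B", 5, 5, 5, 5)]
        filler = [_score(f"C{i}", 1, 1, 1, 1) for i in range(2)]
        result = select_brokers(tied + filler)
        flags = {s.actor_id: s.selected for s in result}
        assert flags["A"] == flags["B"]

    def test_selected_implies_top_half_percentiles(self):
        scores = [_score(f"A{i}", i, i, i, float(i)) for i in range(10)]
        for s in select_brokers(scores):
            if s.selected:
                assert all(p >= 50.0 for p in s.percentiles.values())

    def test_raising_quantile_never_grows_selection(self):
        scores = [
            _score(f"A{i}", i, 10 - i, (i * 3) % 10, float(i % 4)) for i in range(10)
        ]
        previous = None
        for q in (0.0, 0.25, 0.5, 0.75, 0.9):
            selected = {
                s.actor_id for s in select_brokers([_copy(s) for s in scores], q) if s.selected
            }
            if previous is not None:
                assert selected <= previous
            previous = selected

    def test_invariant_under_monotone_rescaling(self):
        scores = [
            _score(f"A{i}", i, (i * 7) % 11, (i * 3) % 5, float(i % 6))
            for i in range(12)
        ]
        base = {
            s.actor_id for s in select_brokers([_copy(s) for s in scores]) if s.selected
        }
        rescaled = [
            _score(s.actor_id, s.outdeg_pm_norm * 10 + 3, s.indeg_peer_norm,
                   s.outdeg_peer_norm, s.betweenness_norm_x100)
            for s in scores
        ]
        after = {s.actor_id for s in select_brokers(rescaled) if s.selected}
        assert base == after

    def test_empty_pool_warns_and_returns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            assert select_brokers([]) == []
        assert "no eligible" in caplog.text


def _copy(s: BrokerScore) -> BrokerScore:
    return _score(
        s.actor_id,
        s.outdeg_pm_norm,
        s.indeg_peer_norm,
        s.outdeg_peer_norm,
        s.betweenness_norm_x100,
    )


def _tallies(freqs):
    return [
        PolicymakerTally(actor_id=f"P{i:02d}", indegree_from_faculty=f)
        for i, f in enumerate(freqs)
    ]


class TestKeyPolicymakers:
    def test_published_frequency_profile_selects_six(self):
        """Frequencies spanning 1-5 give a median-of-range cut of 3; the
        profile {5,5,4,3,3,3} + 13x2 + 75x1 yields exactly six."""
        freqs = [5, 5, 4, 3, 3, 3] + [2] * 13 + [1] * 75
        selected = select_key_policymakers(_tallies(freqs))
        assert len(selected) == 6
        assert [t.indegree_from_faculty for t in selected] == [5, 5, 4, 3, 3, 3]

    def test_degenerate_range_selects_everyone(self, caplog):
        with caplog.at_level("WARNING"):
            selected = select_key_policymakers(_tallies([1, 1, 1]))
        assert len(selected) == 3
        assert "degenerate" in caplog.text

    def test_full_range_one_to_seven(self):
        # range 1-7 -> cut 4 -> indegrees {4,5,6,7} pass
        selected = select_key_policymakers(_tallies(range(1, 8)))
        assert sorted(t.indegree_from_faculty for t in selected) == [4, 5, 6, 7]

    def test_integer_threshold_override(self):
        selected = select_key_policymakers(_tallies([1, 2, 3, 4]), threshold=4)
        assert [t.indegree_from_faculty for t in selected] == [4]

    def test_empty_tallies(self):
        assert select_key_policymakers([]) == []

    def test_ordering_by_indegree_then_id(self):
        selected = select_key_policymakers(_tallies([3, 5, 3, 5]), threshold=3)
        assert [t.actor_id for t in selected] == ["P01", "P03", "P00", "P02"]

    def test_calibrated_brokerage_core(self, calibrated_network):
        """The calibrated network carries a small brokerage core: selected
        brokers are a subset of eligible faculty respondents with ties."""
        from sociometry import identify_brokers

        scored = identify_brokers(calibrated_network, paper_compat=True)
        selected = [s for s in scored if s.selected]
        assert len(selected) == 4
        eligible_ids = {s.actor_id for s in scored}
        assert {s.actor_id for s in selected} <= eligible_ids
        for s in selected:
            actor = calibrated_network.actors[s.actor_id]
            assert actor.role.value == "faculty" and actor.is_respondent

    def test_calibrated_network_selects_six(self, calibrated_network):
        from sociometry import policymaker_tallies

        tallies = policymaker_tallies(calibrated_network)
        freqs = [t.indegree_from_faculty for t in tallies]
        assert min(freqs) == 1 and max(freqs) == 5
        selected = select_key_policymakers(tallies)
        assert len(selected) == 6
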