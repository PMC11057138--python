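"""Identification of academic knowledge brokers and key policymakers.

Knowledge brokers are faculty who both reach policymakers and are embedded
among peers.  Candidates are scored on four cap-normalized indicators —
out-degree to policymakers, in-degree from peers, out-degree to peers, and
per-hundred betweenness — and selected when they sit in the top half of the
eligible pool on *all four* at once.  Ranking is inclusive under ties: equal
values share the better position, so two identical candidates are always
selected or rejected together.

Key policymakers are the most-nominated policy-side actors: the cut-off is
the median of the observed nomination-frequency *range* (midpoint of min
and max — e.g. 3 for frequencies spanning 1–5), and everyone nominated at
least that often is selected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

from .builder import SociometricNetwork
from .centrality import CentralityRecord, centrality_records, normalize_degree
from .model import Role

logger = logging.getLogger(__name__)

INDICATORS = ("outdeg_pm_norm", "indeg_peer_norm", "outdeg_peer_norm",
              "betweenness_norm_x100")


@dataclass
class BrokerScore:
    """Four normalized indicators plus composite score for one candidate."""

    actor_id: str
    outdeg_pm_norm: float
    indeg_peer_norm: float
    outdeg_peer_norm: float
    betweenness_norm_x100: float
    ranks: dict[str, int] = field(default_factory=dict)
    percentiles: dict[str, float] = field(default_factory=dict)
    total_score: float = 0.0
    selected: bool = False
    display_code: str = ""

    def indicator(self, name: str) -> float:
        return getattr(self, name)


@dataclass
class PolicymakerTally:
    """Nomination tally for one policymaker."""

    actor_id: str
    indegree_from_faculty: int
    selected: bool = False
    display_code: str = ""
    organization: str = ""


EligibilityRule = Callable[[CentralityRecord], bool]


def default_eligibility(record: CentralityRecord) -> bool:
    """A broker candidate must reach policymakers AND touch the peer network.

    Faculty with many policymaker ties but no peer arcs broker nothing
    between peers and policy, however central they look on one axis.
    """
    return record.outdeg_pm >= 1 and (record.outdeg_peer + record.indeg_peer) >= 1


def eligible_candidates(
    records: list[CentralityRecord],
    rule: Optional[EligibilityRule] = None,
) -> list[CentralityRecord]:
    rule = rule or default_eligibility
    return [r for r in records if rule(r)]


def total_score(indicators: tuple[float, float, float, float]) -> float:
    """Composite broker score: the plain sum of the four indicator values."""
    return sum(indicators)


def score_candidates(
    records: list[CentralityRecord],
    cap: int = 7,
    paper_compat: bool = False,
) -> list[BrokerScore]:
    """Turn centrality records into indicator vectors (no selection yet)."""
    scores = []
    for rec in records:
        indicators = (
            normalize_degree(rec.outdeg_pm, cap, paper_compat),
            normalize_degree(rec.indeg_peer, cap, paper_compat),
            normalize_degree(rec.outdeg_peer, cap, paper_compat),
            rec.betweenness_norm_x100 or 0.0,
        )
        scores.append(
            BrokerScore(
                actor_id=rec.actor_id,
                outdeg_pm_norm=indicators[0],
                indeg_peer_norm=indicators[1],
                outdeg_peer_norm=indicators[2],
                betweenness_norm_x100=indicators[3],
                total_score=total_score(indicators),
                display_code=rec.display_code,
            )
        )
    return scores


def select_brokers(
    scores: list[BrokerScore], quantile: float = 0.5
) -> list[BrokerScore]:
    """Select candidates in the top (1 − quantile) of the pool on all four
    indicators simultaneously.

    On each indicator a candidate passes when no more than ⌈(1 − q)·m⌉ of
    the m candidates score at least as high — i.e. the candidate's worst
    position in any descending ordering still falls inside the cut.  This
    keeps tied candidates symmetric (identical vectors are selected or
    rejected together) and never lets a large tied block slip through on a
    shared value.  Returns all scored candidates with dense ranks,
    percentiles and the ``selected`` flag filled, selected-first by
    descending total score.
    """
    if not 0.0 <= quantile < 1.0:
        raise ValueError("quantile must be in [0, 1)")
    m = len(scores)
    if m == 0:
        logger.warning("no eligible broker candidates")
        return []
    keep = math.ceil((1.0 - quantile) * m)
    for name in INDICATORS:
        values = [s.indicator(name) for s in scores]
        distinct_desc = sorted(set(values), reverse=True)
        dense = {v: i + 1 for i, v in enumerate(distinct_desc)}
        for s in scores:
            v = s.indicator(name)
            better = sum(1 for x in values if x > v)
            at_or_above = sum(1 for x in values if x >= v)
            s.ranks[name] = dense[v]
            s.percentiles[name] = 100.0 * (m - better) / m
            passed = at_or_above <= keep
            s.selected = passed if name == INDICATORS[0] else (s.selected and passed)
    return sorted(scores, key=lambda s: (-s.selected, -s.total_score, s.actor_id))


def identify_brokers(
    network: SociometricNetwork,
    quantile: float = 0.5,
    cap: int = 7,
    paper_compat: bool = False,
    rule: Optional[EligibilityRule] = None,
    treat_directed: bool = True,
) -> list[BrokerScore]:
    """End-to-end broker identification on a built network (faculty only)."""
    records = [
        r
        for r in centrality_records(network, treat_directed=treat_directed, cap=cap)
        if network.actors[r.actor_id].role == Role.faculty
        and network.actors[r.actor_id].is_respondent
    ]
    eligible = eligible_candidates(records, rule)
    return select_brokers(score_candidates(eligible, cap, paper_compat), quantile)


def policymaker_tallies(network: SociometricNetwork) -> list[PolicymakerTally]:
    """Nomination counts (faculty→policymaker in-degree) for every policymaker."""
    counts: dict[str, int] = {}
    for (_, v) in network.pm_arcs:
        counts[v] = counts.get(v, 0) + 1
    tallies = []
    for aid, actor in network.actors.items():
        if actor.role != Role.policymaker:
            continue
        tallies.append(
            PolicymakerTally(
                actor_id=aid,
                indegree_from_faculty=counts.get(aid, 0),
                display_code=actor.display_code,
                organization=actor.organization,
            )
        )
    return sorted(tallies, key=lambda t: (-t.indegree_from_faculty, t.actor_id))


def select_key_policymakers(
    tallies: list[PolicymakerTally],
    threshold: Union[int, str] = "median_of_range",
) -> list[PolicymakerTally]:
    """Key policymakers: nominated at least ``threshold`` times.

    ``threshold="median_of_range"`` uses the midpoint of the observed
    min–max frequency (3 when frequencies span 1–5); an integer overrides.
    When all frequencies coincide the degenerate range selects everyone,
    with a warning.
    """
    if not tallies:
        return []
    freqs = [t.indegree_from_faculty for t in tallies]
    if isinstance(threshold, str):
        if threshold != "median_of_range":
            raise ValueError(f"unknown threshold rule {threshold!r}")
        lo, hi = min(freqs), max(freqs)
        if lo == hi:
            logger.warning(
                "degenerate frequency range [%d, %d]: every policymaker selected",
                lo,
                hi,
            )
        cut = (lo + hi) / 2.0
    else:
        cut = float(threshold)
    selected = [t for t in tallies if t.indegree_from_faculty >= cut]
    for t in tallies:
        t.selected = t.indegree_from_faculty >= cut
    return sorted(selected, key=lambda t: (-t.indegree_from_faculty, t.actor_id))
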