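"""Seeded synthetic sociometric surveys.

Two generators:

* :func:`simulate_survey` draws a stochastic survey with the statistical
  structure of a census-style sociometric study of a 302-member faculty
  population: ~50% response, ~37% of respondents reporting at least one
  policymaker contact, nomination counts truncated-Poisson capped at 7 per
  category, and a small reciprocity rate among peer ties.  Identical seed
  and config give identical output.

* :func:`calibrated_fixture` lays out, deterministically, a survey whose
  built network reproduces a fixed set of marginal counts exactly:
  152 respondents of whom 56 named at least one alter, 94 policymakers all
  nominated, 38 nominated non-respondent peers, 125 faculty→policymaker
  links, 52 peer links of which 9 reciprocal, and 96 isolates — 188
  connected nodes and 177 links in all.  Policymaker nomination frequencies
  span 1–5 and include {5, 5, 4, 3, 3, 3}, so the median-of-range rule
  selects exactly six key policymakers.

The fixture is constructed, not sampled: nomination lists are assigned
round-robin so every marginal count is exact while no respondent exceeds
the 7-per-category cap.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, field_validator

from .model import (
    Actor,
    Category,
    ContactMode,
    Initiator,
    Level,
    Nomination,
    Role,
    SurveyResponse,
)

UNIVERSITIES = [
    "Tehran UMS",
    "Shahid Beheshti UMS",
    "Mashhad UMS",
    "Tabriz UMS",
    "Iran UMS",
    "Shiraz UMS",
    "Isfahan UMS",
    "Ahvaz Jundishapur UMS",
    "Mazandaran UMS",
    "Kerman UMS",
]

NATIONAL_ORGS = [
    "MOHME",
    "National Institute of Health Research",
    "Food and Drug Administration",
    "Health Insurance Organization",
    "Institute of Public Health Research",
    "Environmental Protection Organization",
    "Social Security Organization",
    "Plan and Budget Organization",
    "Parliament Health Commission",
]

PROVINCIAL_ORGS = [
    "Provincial Health Center",
    "Department of Environment",
    "Provincial Governor Office",
    "Provincial Water and Sewage Company",
    "Provincial Welfare Organization",
    "Provincial Education Office",
    "Provincial Industry Office",
    "Provincial Municipality",
]


class SurveySimConfig(BaseModel):
    """Parameters of the stochastic survey generator.

    Defaults emulate the study conditions: a 302-person census with 50.33%
    response, 37% of respondents reporting any policymaker contact, 23.68%
    with decision-making experience, and peer reciprocity near 9/52.  The
    per-category Poisson rates are set so the expected total tie count is
    near 177.
    """

    population_size: int = Field(default=302, ge=0)
    response_rate: float = Field(default=0.5033, ge=0.0, le=1.0)
    p_any_pm_contact: float = Field(default=0.37, ge=0.0, le=1.0)
    lambda_direct: float = Field(default=1.25, ge=0.0)
    lambda_via_peer: float = Field(default=0.65, ge=0.0)
    lambda_broker: float = Field(default=0.30, ge=0.0)
    cap: int = Field(default=7, ge=1)
    peer_reciprocity_prob: float = Field(default=0.173, ge=0.0, le=1.0)
    pm_pool_size: int = Field(default=120, ge=0)
    level_mix: dict[str, float] = Field(
        default={"national": 0.447, "provincial": 0.287, "university": 0.266}
    )
    decision_experience_rate: float = Field(default=0.2368, ge=0.0, le=1.0)
    initiator_probs: dict[str, float] = Field(
        default={"policymaker": 0.54, "researcher": 0.30, "third_party": 0.16}
    )
    mode_face_to_face_prob: float = Field(default=0.6572, ge=0.0, le=1.0)
    n_universities: int = Field(default=10, ge=1)
    seed: int = 0

    @field_validator("level_mix", "initiator_probs")
    @classmethod
    def _mixture_sums_to_one(cls, v: dict[str, float]) -> dict[str, float]:
        if any(p < 0 or p > 1 for p in v.values()):
            raise ValueError("mixture probabilities must lie in [0, 1]")
        if v and not math.isclose(sum(v.values()), 1.0, abs_tol=1e-6):
            raise ValueError("mixture probabilities must sum to 1")
        return v


def _truncated_poisson(rng: np.random.Generator, lam: float, cap: int) -> int:
    return int(min(rng.poisson(lam), cap))


def simulate_survey(
    config: Optional[SurveySimConfig] = None,
) -> tuple[list[Actor], list[SurveyResponse]]:
    """Draw one synthetic survey: (roster, responses).

    Respondents are Bernoulli(response_rate) over the population; a
    respondent reports policymaker contact with probability
    ``p_any_pm_contact``, in which case their direct nominations number
    min(1 + Poisson(λ_direct), cap) and peer nominations follow capped
    Poisson draws; only contact-reporting respondents name anyone, so the
    remaining respondents are potential isolates.  A via-peer target is
    also named in the brokerage category with probability
    ``peer_reciprocity_prob``, producing two-way peer ties.
    """
    config = config or SurveySimConfig()
    rng = np.random.default_rng(config.seed)
    width = max(4, len(str(max(config.population_size, 1))))

    levels = list(config.level_mix)
    level_p = np.array([config.level_mix[k] for k in levels], dtype=float)
    pm_orgs = {
        "national": NATIONAL_ORGS,
        "provincial": PROVINCIAL_ORGS,
        "university": UNIVERSITIES,
    }

    roster: list[Actor] = []
    faculty_ids: list[str] = []
    responding = rng.random(config.population_size) < config.response_rate
    for i in range(config.population_size):
        aid = f"F{i + 1:0{width}d}"
        faculty_ids.append(aid)
        roster.append(
            Actor(
                actor_id=aid,
                display_code=aid,
                role=Role.faculty,
                university=UNIVERSITIES[i % config.n_universities],
                is_respondent=bool(responding[i]),
                has_decision_experience=bool(
                    responding[i]
                    and rng.random() < config.decision_experience_rate
                ),
            )
        )

    pm_ids: list[str] = []
    for j in range(config.pm_pool_size):
        level = levels[int(rng.choice(len(levels), p=level_p))]
        orgs = pm_orgs.get(level, ["unspecified"])
        aid = f"P{j + 1:0{width}d}"
        pm_ids.append(aid)
        roster.append(
            Actor(
                actor_id=aid,
                display_code=aid,
                role=Role.policymaker,
                level=Level(level),
                organization=orgs[int(rng.integers(len(orgs)))],
            )
        )

    initiators = list(config.initiator_probs)
    initiator_p = np.array([config.initiator_probs[k] for k in initiators])

    def attrs() -> dict:
        return {
            "initiator": Initiator(initiators[int(rng.choice(len(initiators), p=initiator_p))]),
            "mode": (
                ContactMode.face_to_face
                if rng.random() < config.mode_face_to_face_prob
                else ContactMode.other
            ),
        }

    responses: list[SurveyResponse] = []
    for i, aid in enumerate(faculty_ids):
        if not responding[i]:
            continue
        nominations: list[Nomination] = []
        if pm_ids and rng.random() < config.p_any_pm_contact:
            n_direct = min(1 + int(rng.poisson(config.lambda_direct)), config.cap)
            targets = rng.choice(pm_ids, size=min(n_direct, len(pm_ids)), replace=False)
            for tid in targets:
                nominations.append(
                    Nomination(
                        source_id=aid,
                        target_id=str(tid),
                        category=Category.direct_to_pm,
                        **attrs(),
                    )
                )
            peer_pool = [f for f in faculty_ids if f != aid]
            n_via = _truncated_poisson(rng, config.lambda_via_peer, config.cap)
            n_broker = _truncated_poisson(rng, config.lambda_broker, config.cap)
            via_targets = rng.choice(
                peer_pool, size=min(n_via, len(peer_pool)), replace=False
            )
            broker_targets = list(
                rng.choice(peer_pool, size=min(n_broker, len(peer_pool)), replace=False)
            )
            for tid in via_targets:
                nominations.append(
                    Nomination(
                        source_id=aid,
                        target_id=str(tid),
                        category=Category.via_peer,
                        **attrs(),
                    )
                )
                if (
                    rng.random() < config.peer_reciprocity_prob
                    and str(tid) not in broker_targets
                    and len(broker_targets) < config.cap
                ):
                    broker_targets.append(str(tid))
            for tid in broker_targets[: config.cap]:
                nominations.append(
                    Nomination(
                        source_id=aid,
                        target_id=str(tid),
                        category=Category.broker_for_peer,
                        **attrs(),
                    )
                )
        responses.append(
            SurveyResponse(respondent_id=aid, nominations=nominations, cap=config.cap)
        )
    return roster, responses


# ---------------------------------------------------------------------------
# deterministic calibrated fixture
# ---------------------------------------------------------------------------

#: policymaker nomination-frequency profile: 5,5,4,3,3,3 then 14 twos, 74 ones
_PM_PROFILE: list[int] = [5, 5, 4, 3, 3, 3] + [2] * 14 + [1] * 74

N_RESPONDENTS = 152
N_CONNECTED = 56
N_PEERS = 38
N_NONRESPONDENT_EXTRA = 112  # 302-person population minus 152 − 38


def _fixture_policymakers() -> list[Actor]:
    """94 policymakers with level/organization layout and target in-degrees.

    The organization layout puts 42 links on the national MOHME and spreads
    the rest over nine national, ~20 provincial and ten university-level
    organizations.
    """
    spec: list[tuple[str, str, str]] = []  # (display, level, organization)
    spec.append(("PN01", "national", "MOHME"))                # indegree 5
    spec.append(("PN02", "national", "MOHME"))                # indegree 5
    spec.append(("PU01", "university", "Isfahan UMS"))        # indegree 4
    spec.append(("PU02", "university", "Mashhad UMS"))        # indegree 3
    spec.append(("PN03", "national", "MOHME"))                # indegree 3
    spec.append(("PN04", "national", "MOHME"))                # indegree 3
    # fourteen twice-nominated policymakers
    for k in range(6):
        spec.append((f"PN{5 + k:02d}", "national", "MOHME"))
    spec.append(("PN11", "national", "National Institute of Health Research"))
    spec.append(("PU03", "university", "Tehran UMS"))
    spec.append(("PU04", "university", "Shiraz UMS"))
    spec.append(("PU05", "university", "Tabriz UMS"))
    spec.append(("PP01", "provincial", "Provincial Health Center"))
    spec.append(("PP02", "provincial", "Provincial Health Center"))
    spec.append(("PP03", "provincial", "Department of Environment"))
    spec.append(("PP04", "provincial", "Provincial Governor Office"))
    # seventy-four once-nominated policymakers
    for k in range(14):
        spec.append((f"PN{12 + k:02d}", "national", "MOHME"))
    for k in range(17):
        org = NATIONAL_ORGS[1 + k % (len(NATIONAL_ORGS) - 1)]
        spec.append((f"PN{26 + k:02d}", "national", org))
    for k in range(20):
        spec.append((f"PU{6 + k:02d}", "university", UNIVERSITIES[k % 10]))
    for k in range(23):
        if k < 3:
            org = "Provincial Health Center"
        elif k < 6:
            org = "Department of Environment"
        else:
            org = f"{PROVINCIAL_ORGS[2 + (k - 6) % 6]} {1 + (k - 6) // 6}"
        spec.append((f"PP{5 + k:02d}", "provincial", org))

    assert len(spec) == 94
    actors = []
    for idx, (display, level, org) in enumerate(spec):
        actors.append(
            Actor(
                actor_id=f"P{idx + 1:03d}",
                display_code=display,
                role=Role.policymaker,
                level=Level(level),
                organization=org,
            )
        )
    return actors


def calibrated_fixture() -> tuple[list[Actor], list[SurveyResponse]]:
    """The deterministic calibrated survey (see module docstring)."""
    ranks = (
        ["instructor"] * 6
        + ["assistant_professor"] * 73
        + ["associate_professor"] * 37
        + ["professor"] * 36
    )
    majors = (
        ["public_health"] * 49
        + ["environmental_health_engineering"] * 36
        + ["occupational_health_engineering"] * 36
        + ["epidemiology"] * 29
        + ["health_education_promotion"] * 2
    )
    roster: list[Actor] = []
    respondent_ids = [f"F{i + 1:03d}" for i in range(N_RESPONDENTS)]
    for i, aid in enumerate(respondent_ids):
        roster.append(
            Actor(
                actor_id=aid,
                display_code=f"FA{i + 1:03d}",
                role=Role.faculty,
                university=UNIVERSITIES[i % 10],
                is_respondent=True,
                has_decision_experience=i < 36,
                gender="male" if i < 106 else "female",
                academic_rank=ranks[i],
                major=majors[i],
            )
        )
    peer_ids = [f"N{i + 1:03d}" for i in range(N_PEERS)]
    for i, aid in enumerate(peer_ids):
        roster.append(
            Actor(
                actor_id=aid,
                display_code=f"FN{i + 1:02d}",
                role=Role.faculty,
                university=UNIVERSITIES[i % 10],
                is_respondent=False,
            )
        )
    for i in range(N_NONRESPONDENT_EXTRA):
        roster.append(
            Actor(
                actor_id=f"X{i + 1:03d}",
                display_code=f"FX{i + 1:03d}",
                role=Role.faculty,
                university=UNIVERSITIES[i % 10],
                is_respondent=False,
            )
        )
    policymakers = _fixture_policymakers()
    roster.extend(policymakers)

    # --- faculty→policymaker nominations: 125 links, profile-exact ---------
    slots: list[str] = []
    for pm, indegree in zip(policymakers, _PM_PROFILE):
        slots.extend([pm.actor_id] * indegree)
    assert len(slots) == 125

    nominations: dict[str, list[Nomination]] = {aid: [] for aid in respondent_ids}
    purposes = ["advice_on_technical_issues", "share_research_results",
                "request_research_collaboration", "membership_in_committee"]
    acquaintances = ["organizational_position", "colleague", "advisory_committee",
                     "former_student"]
    frequencies = ["yearly", "quarterly", "monthly"]

    def nom_attrs(j: int) -> dict:
        r = j % 100
        if r < 54:
            initiator = Initiator.policymaker
        elif r < 84:
            initiator = Initiator.researcher
        else:
            initiator = Initiator.third_party
        return {
            "initiator": initiator,
            "mode": ContactMode.face_to_face if j % 100 < 66 else ContactMode.other,
            "purpose": purposes[j % len(purposes)],
            "acquaintance": acquaintances[j % len(acquaintances)],
            "frequency": frequencies[j % len(frequencies)],
        }

    # Direct nominations follow a graded out-degree sequence: a small core
    # of highly active respondents (5, 4, 4, 4 policymaker contacts), a
    # middle band of three, and the long tail at one or two — summing to
    # 125.  Each policymaker's arcs are assigned greedily to the distinct
    # respondents with the largest remaining quota (ties to the lowest
    # index), so every relation stays binary and the layout is
    # deterministic.
    quotas = [5, 4, 4, 4] + [3] * 5 + [2] * 46 + [1]
    assert len(quotas) == N_CONNECTED and sum(quotas) == 125
    remaining = dict(zip(respondent_ids[:N_CONNECTED], quotas))
    j = 0
    for pm, indegree in zip(policymakers, _PM_PROFILE):
        chosen = sorted(
            (rid for rid in remaining if remaining[rid] > 0),
            key=lambda rid: (-remaining[rid], rid),
        )[:indegree]
        assert len(chosen) == indegree
        for rid in chosen:
            remaining[rid] -= 1
            nominations[rid].append(
                Nomination(
                    source_id=rid,
                    target_id=pm.actor_id,
                    category=Category.direct_to_pm,
                    **nom_attrs(j),
                )
            )
            j += 1
    assert all(v == 0 for v in remaining.values())

    # --- peer nominations: 52 links over 38 peers, 9 reciprocal ------------
    peer_slots: list[str] = []
    for i, aid in enumerate(peer_ids):
        peer_slots.extend([aid] * (2 if i < 14 else 1))
    assert len(peer_slots) == 52
    # Peer ties concentrate on the same brokerage core: the first nine
    # respondents hold the reciprocal ties, the core four also carry the
    # bulk of the conduit (via) and incoming brokerage arcs, and a few
    # mid-list respondents carry single conduit ties.  The interleaving of
    # respondent indices keeps every (respondent, peer) pair distinct so no
    # binary relation collapses.
    via_rids = [0, 1, 0, 1, 0, 2, 1, 2, 0, 3, 1, 3, 2, 3, 0, 2, 3, 1, 9, 10, 11, 4]
    broker_rids = [0, 1, 2, 3] * 4 + [4, 5, 4, 5, 6]
    assert len(via_rids) == 22 and len(broker_rids) == 21
    for k, peer_id in enumerate(peer_slots):
        if k < 9:
            # reciprocal tie: the respondent both reaches policymakers via
            # this peer and brokers for them, giving arcs in both directions
            rid = respondent_ids[k]
            cats = [Category.via_peer, Category.broker_for_peer]
        elif k < 31:
            rid = respondent_ids[via_rids[k - 9]]
            cats = [Category.via_peer]
        else:
            rid = respondent_ids[broker_rids[k - 31]]
            cats = [Category.broker_for_peer]
        for cat in cats:
            nominations[rid].append(
                Nomination(
                    source_id=rid,
                    target_id=peer_id,
                    category=cat,
                    **nom_attrs(k + 125),
                )
            )

    responses = [
        SurveyResponse(respondent_id=rid, nominations=nominations[rid])
        for rid in respondent_ids
    ]
    return roster, responses
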