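"""Construction of the typed directed academic–policymaker network.

The network holds two kinds of directed ties:

* ``pm_link`` — faculty → policymaker.  These are never reciprocal because
  only faculty were surveyed.
* ``peer_link`` — faculty → faculty.  A peer tie is *reciprocal* when both
  directed arcs exist; under ``link`` counting a reciprocal pair is one link.

Nomination categories map onto arcs via a configurable ``category_map``:
by default a ``direct_to_pm`` or ``via_peer`` naming points from the
respondent to the named person, while ``broker_for_peer`` points from the
named peer to the respondent (the peer seeks the respondent's brokerage).
Duplicate nominations of the same ordered pair collapse to a single binary
relation.  Respondents with no surviving nominations are *isolates*: they
are excluded from the network but counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Optional

from .model import (
    Actor,
    Category,
    CountingMode,
    Level,
    LinkType,
    Nomination,
    Role,
    SurveyResponse,
)

logger = logging.getLogger(__name__)

Arc = tuple[str, str]

#: Direction each nomination category induces: "forward" means
#: respondent -> named person, "reverse" means named person -> respondent.
DEFAULT_CATEGORY_MAP: dict[Category, str] = {
    Category.direct_to_pm: "forward",
    Category.via_peer: "forward",
    Category.broker_for_peer: "reverse",
}


@dataclass
class Link:
    """One reported tie as exported: a directed arc, or a merged reciprocal pair."""

    source: str
    target: str
    link_type: LinkType
    reciprocal: bool = False

    def as_tuple(self) -> tuple[str, str, str, bool]:
        return (self.source, self.target, self.link_type.value, self.reciprocal)


@dataclass
class SociometricNetwork:
    """Directed typed graph over connected actors (isolates excluded)."""

    actors: dict[str, Actor] = field(default_factory=dict)
    arcs: set[Arc] = field(default_factory=set)
    arc_types: dict[Arc, LinkType] = field(default_factory=dict)
    alter_ids: set[str] = field(default_factory=set)
    isolate_count: int = 0
    respondent_count: int = 0
    counting_mode: CountingMode = CountingMode.link

    # -- basic counts -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.actors)

    @property
    def arc_count(self) -> int:
        return len(self.arcs)

    @property
    def pm_arcs(self) -> list[Arc]:
        return [a for a in self.arcs if self.arc_types[a] == LinkType.pm_link]

    @property
    def peer_arcs(self) -> list[Arc]:
        return [a for a in self.arcs if self.arc_types[a] == LinkType.peer_link]

    def reciprocal_pairs(self) -> set[frozenset[str]]:
        """Unordered faculty pairs connected by peer arcs in both directions."""
        peer = set(self.peer_arcs)
        return {frozenset((u, v)) for (u, v) in peer if (v, u) in peer}

    @property
    def pm_link_count(self) -> int:
        return len(self.pm_arcs)

    @property
    def peer_link_count(self) -> int:
        n_arcs = len(self.peer_arcs)
        if self.counting_mode == CountingMode.link:
            return n_arcs - len(self.reciprocal_pairs())
        return n_arcs

    @property
    def link_count(self) -> int:
        return self.pm_link_count + self.peer_link_count

    @property
    def reciprocal_count(self) -> int:
        return len(self.reciprocal_pairs())

    # -- degrees ------------------------------------------------------
    def out_arcs(self, actor_id: str) -> list[Arc]:
        return [a for a in self.arcs if a[0] == actor_id]

    def in_arcs(self, actor_id: str) -> list[Arc]:
        return [a for a in self.arcs if a[1] == actor_id]

    # -- exported link records ---------------------------------------
    def links(self) -> list[Link]:
        """Link records under the network's counting mode, deterministically ordered."""
        records: list[Link] = []
        merged = self.reciprocal_pairs() if self.counting_mode == CountingMode.link else set()
        seen_pairs: set[frozenset[str]] = set()
        for (u, v) in sorted(self.arcs):
            ltype = self.arc_types[(u, v)]
            pair = frozenset((u, v))
            if ltype == LinkType.peer_link and pair in merged:
                if pair in seen_pairs:
                    continue
                seen_pairs.add(pair)
                a, b = sorted(pair)
                records.append(Link(a, b, ltype, reciprocal=True))
            else:
                reciprocal = (
                    ltype == LinkType.peer_link and (v, u) in self.arcs
                )
                records.append(Link(u, v, ltype, reciprocal=reciprocal))
        records.sort(key=lambda r: (r.source, r.target, r.link_type.value))
        return records


@dataclass
class ComponentPartition:
    """Weakly connected components, largest first."""

    components: list[frozenset[str]]

    @property
    def main_component(self) -> frozenset[str]:
        return self.components[0] if self.components else frozenset()

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.components]


@dataclass
class OrgNetwork:
    """University → organization weighted links at one policymaking level."""

    level: Level
    links: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def total_weight(self) -> int:
        return sum(self.links.values())

    def org_totals(self) -> dict[str, int]:
        totals: dict[str, int] = {}
        for (_, org), w in self.links.items():
            totals[org] = totals.get(org, 0) + w
        return totals


def _respondent_ids(
    responses: Iterable[SurveyResponse], roster: Iterable[Actor]
) -> set[str]:
    ids = {a.actor_id for a in roster if a.is_respondent}
    ids.update(r.respondent_id for r in responses)
    return ids


def build_network(
    responses: list[SurveyResponse],
    roster: list[Actor],
    category_map: Optional[Mapping[Category, str]] = None,
    role_overrides: Optional[Mapping[str, Role | tuple[Role, Level]]] = None,
    counting_mode: CountingMode | str = CountingMode.link,
    on_violation: Literal["error", "drop"] = "error",
) -> SociometricNetwork:
    """Build the binary relational network from survey responses.

    Parameters
    ----------
    responses
        Validated survey responses (may include empty ones for isolates).
    roster
        All known actors; people named but absent from the roster must have
        been auto-registered by the survey reader beforehand.
    category_map
        Direction semantics per nomination category (see module docstring).
    role_overrides
        ``actor_id -> Role`` or ``actor_id -> (Role, Level)`` applied before
        typing edges, for dual-role actors known to act as policymakers.
    counting_mode
        ``link`` (reciprocal peer pair = one link, the default) or ``arc``.
    on_violation
        What to do with a nomination whose induced arc violates the
        link-type invariants (e.g. a policymaker on the faculty side of a
        peer arc): raise, or drop it with a warning.
    """
    counting_mode = CountingMode(counting_mode)
    category_map = dict(category_map or DEFAULT_CATEGORY_MAP)
    actors = {a.actor_id: a for a in roster}

    for actor_id, override in (role_overrides or {}).items():
        if actor_id not in actors:
            raise KeyError(f"role override for unknown actor {actor_id!r}")
        role, level = (
            override if isinstance(override, tuple) else (override, None)
        )
        updates: dict = {"role": role}
        if level is not None:
            updates["level"] = level
        elif role == Role.policymaker and actors[actor_id].level == Level.none:
            updates["level"] = Level.national
        actors[actor_id] = actors[actor_id].model_copy(update=updates)

    arcs: set[Arc] = set()
    arc_types: dict[Arc, LinkType] = {}
    alter_ids: set[str] = set()
    naming_respondents: set[str] = set()

    for resp in responses:
        for nom in resp.nominations:
            if nom.target_id not in actors:
                raise KeyError(
                    f"nominated actor {nom.target_id!r} missing from roster; "
                    "auto-register at survey read time"
                )
            alter_ids.add(nom.target_id)
            direction = category_map.get(nom.category, "forward")
            if direction == "reverse":
                u, v = nom.target_id, nom.source_id
            else:
                u, v = nom.source_id, nom.target_id
            src, tgt = actors[u], actors[v]
            if tgt.role == Role.policymaker:
                ltype = LinkType.pm_link
                valid = src.role == Role.faculty
            else:
                ltype = LinkType.peer_link
                valid = src.role == Role.faculty
            if not valid:
                msg = (
                    f"nomination {nom.source_id!r}->{nom.target_id!r} "
                    f"({nom.category.value}) induces an invalid "
                    f"{ltype.value} arc {u!r}->{v!r}"
                )
                if on_violation == "error":
                    raise ValueError(msg)
                logger.warning("dropped: %s", msg)
                continue
            naming_respondents.add(nom.source_id)
            arc = (u, v)
            if arc not in arcs:
                arcs.add(arc)
                arc_types[arc] = ltype

    connected = {u for arc in arcs for u in arc}
    respondents = _respondent_ids(responses, actors.values())
    # isolates: respondents with no tie at all (they named nobody and were
    # never named); respondent_count: respondents who named >= 1 alter (the
    # prevalence and effective-density denominator) — a respondent who only
    # *received* nominations is connected but counts in neither.
    isolate_count = len(respondents) - len(respondents & connected)

    network = SociometricNetwork(
        actors={aid: actors[aid] for aid in connected},
        arcs=arcs,
        arc_types=arc_types,
        alter_ids=alter_ids & connected,
        isolate_count=isolate_count,
        respondent_count=len(naming_respondents),
        counting_mode=counting_mode,
    )
    logger.info(
        "built network: %d nodes, %d links (%d pm, %d peer, %d reciprocal), "
        "%d isolates",
        network.n_nodes,
        network.link_count,
        network.pm_link_count,
        network.peer_link_count,
        network.reciprocal_count,
        network.isolate_count,
    )
    return network


def components(network: SociometricNetwork) -> ComponentPartition:
    """Weakly connected components (direction ignored), size-descending.

    Ties on size break by the smallest actor id in the component, so the
    ordering is deterministic.
    """
    neighbours: dict[str, set[str]] = {aid: set() for aid in network.actors}
    for (u, v) in network.arcs:
        neighbours[u].add(v)
        neighbours[v].add(u)

    seen: set[str] = set()
    comps: list[frozenset[str]] = []
    for start in sorted(network.actors):
        if start in seen:
            continue
        stack, comp = [start], {start}
        seen.add(start)
        while stack:
            node = stack.pop()
            for nxt in neighbours[node]:
                if nxt not in comp:
                    comp.add(nxt)
                    seen.add(nxt)
                    stack.append(nxt)
        comps.append(frozenset(comp))
    comps.sort(key=lambda c: (-len(c), min(c)))
    return ComponentPartition(components=comps)


def aggregate_by_organization(
    network: SociometricNetwork, level: Level | str
) -> OrgNetwork:
    """Collapse faculty→policymaker links at one level into a
    university → organization weighted network.

    The weight of a (university, organization) link is the number of
    individual pm links behind it; empty organization names group under
    ``"unspecified"``.
    """
    level = Level(level)
    links: dict[tuple[str, str], int] = {}
    for (u, v) in network.pm_arcs:
        target = network.actors[v]
        if target.level != level:
            continue
        university = network.actors[u].university or "unspecified"
        organization = target.organization or "unspecified"
        key = (university, organization)
        links[key] = links.get(key, 0) + 1
    return OrgNetwork(level=level, links=links)
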