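"""Readers and writers: CSV rosters and surveys, edge-list and GraphML exports.

All tabular inputs are UTF-8 CSV with fixed, documented headers.

Roster columns
    ``actor_id`` (required, unique), ``display_code``, ``role``
    (faculty|policymaker), ``level`` (national|provincial|university|none),
    ``organization``, ``university``, ``is_respondent``,
    ``has_decision_experience``, ``gender``, ``academic_rank``, ``major``.

Survey (long format) columns — one nomination per row
    ``respondent_id``, ``target_id``, ``category``
    (direct_to_pm|via_peer|broker_for_peer), plus optional interaction
    attributes ``initiator``, ``mode``, ``purpose``, ``acquaintance``,
    ``frequency``.  Respondents who named nobody simply have no rows; they
    are recovered from the roster's ``is_respondent`` flag.

A wide-format convenience reader accepts ``respondent_id`` plus columns
``<category>_1`` … ``<category>_<cap>`` naming one target each.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Union

import networkx as nx
import pandas as pd

from .builder import Link, SociometricNetwork
from .model import (
    Actor,
    Category,
    ContactMode,
    CountingMode,
    Initiator,
    Level,
    LinkType,
    Nomination,
    Role,
    SurveyResponse,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

ROSTER_REQUIRED = ["actor_id", "role"]
ROSTER_COLUMNS = [
    "actor_id",
    "display_code",
    "role",
    "level",
    "organization",
    "university",
    "is_respondent",
    "has_decision_experience",
    "gender",
    "academic_rank",
    "major",
]
SURVEY_REQUIRED = ["respondent_id", "target_id", "category"]
SURVEY_COLUMNS = SURVEY_REQUIRED + [
    "initiator",
    "mode",
    "purpose",
    "acquaintance",
    "frequency",
]
EDGELIST_COLUMNS = ["source", "target", "link_type", "reciprocal"]


def _coerce_enum(value, enum_cls, default, context: str):
    if pd.isna(value) or value == "":
        return default
    try:
        return enum_cls(str(value))
    except ValueError:
        logger.warning(
            "unknown %s value %r; using %r", context, value, default.value
        )
        return default


def _coerce_bool(value) -> bool:
    if pd.isna(value) or value == "":
        return False
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in {"1", "true", "yes", "y"}


def _opt_str(value):
    if pd.isna(value) or value == "":
        return None
    return str(value)


def read_roster(path: PathLike) -> list[Actor]:
    """Read an actor roster CSV; duplicate ids and missing columns are errors."""
    df = pd.read_csv(path, dtype=str, comment="#")
    missing = [c for c in ROSTER_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"roster {path} missing required columns: {missing}")
    dupes = df["actor_id"][df["actor_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate actor_id in roster {path}: {sorted(set(dupes))}")

    actors: list[Actor] = []
    for row in df.to_dict("records"):
        role = _coerce_enum(row.get("role"), Role, Role.faculty, "role")
        level = _coerce_enum(row.get("level"), Level, Level.none, "level")
        if role == Role.policymaker and level == Level.none:
            # a policymaker without a stated level is still a policymaker
            logger.warning(
                "policymaker %r has no level; assuming national", row["actor_id"]
            )
            level = Level.national
        actors.append(
            Actor(
                actor_id=str(row["actor_id"]),
                display_code=_opt_str(row.get("display_code")) or str(row["actor_id"]),
                role=role,
                level=level,
                organization=_opt_str(row.get("organization")) or "",
                university=_opt_str(row.get("university")) or "",
                is_respondent=_coerce_bool(row.get("is_respondent")),
                has_decision_experience=_coerce_bool(
                    row.get("has_decision_experience")
                ),
                gender=_opt_str(row.get("gender")),
                academic_rank=_opt_str(row.get("academic_rank")),
                major=_opt_str(row.get("major")),
            )
        )
    return actors


def write_roster(actors: list[Actor], path: PathLike) -> None:
    rows = []
    for a in actors:
        row = a.model_dump()
        row["role"] = a.role.value
        row["level"] = a.level.value
        rows.append(row)
    pd.DataFrame(rows, columns=ROSTER_COLUMNS).to_csv(path, index=False)


def _auto_register(target_id: str, category: Category, roster_index: dict) -> Actor:
    """Register a nominated person absent from the roster.

    People named but never surveyed are kept in the network; the role is
    inferred from the naming category (a ``direct_to_pm`` target is a
    policymaker, otherwise a faculty peer).
    """
    if category == Category.direct_to_pm:
        actor = Actor(
            actor_id=target_id,
            display_code=target_id,
            role=Role.policymaker,
            level=Level.national,
            is_respondent=False,
        )
    else:
        actor = Actor(
            actor_id=target_id,
            display_code=target_id,
            role=Role.faculty,
            is_respondent=False,
        )
    roster_index[target_id] = actor
    logger.warning(
        "auto-registered nominated actor %r as non-respondent %s",
        target_id,
        actor.role.value,
    )
    return actor


def read_survey(
    path: PathLike, roster: list[Actor], cap: int = 7
) -> list[SurveyResponse]:
    """Read a long-format nominations CSV into per-respondent responses.

    Every roster member flagged ``is_respondent`` gets a response, empty if
    they named nobody.  Nominated people absent from the roster are
    auto-registered (appended to ``roster`` in place).  Self-nominations are
    dropped with a warning; more than ``cap`` nominations in one category is
    a hard error naming the respondent and category.
    """
    df = pd.read_csv(path, dtype=str, comment="#")
    missing = [c for c in SURVEY_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"survey {path} missing required columns: {missing}")

    roster_index = {a.actor_id: a for a in roster}
    nominations: dict[str, list[Nomination]] = {
        a.actor_id: [] for a in roster if a.is_respondent
    }
    dropped_self = 0

    for row in df.to_dict("records"):
        rid = str(row["respondent_id"])
        tid = str(row["target_id"])
        category = Category(str(row["category"]))
        if rid not in roster_index:
            actor = Actor(actor_id=rid, display_code=rid, is_respondent=True)
            roster_index[rid] = actor
            roster.append(actor)
            logger.warning("auto-registered unknown respondent %r", rid)
        if rid not in nominations:
            nominations[rid] = []
        if tid == rid:
            dropped_self += 1
            logger.warning("dropped self-nomination by %r", rid)
            continue
        if tid not in roster_index:
            roster.append(_auto_register(tid, category, roster_index))
        nominations[rid].append(
            Nomination(
                source_id=rid,
                target_id=tid,
                category=category,
                initiator=_coerce_enum(
                    row.get("initiator"), Initiator, Initiator.unknown, "initiator"
                ),
                mode=_coerce_enum(
                    row.get("mode"), ContactMode, ContactMode.unknown, "mode"
                ),
                purpose=_opt_str(row.get("purpose")),
                acquaintance=_opt_str(row.get("acquaintance")),
                frequency=_opt_str(row.get("frequency")),
            )
        )

    if dropped_self:
        logger.warning("dropped %d self-nomination(s) in total", dropped_self)

    responses = []
    for rid in sorted(nominations):
        try:
            responses.append(
                SurveyResponse(respondent_id=rid, nominations=nominations[rid], cap=cap)
            )
        except ValueError as exc:
            raise ValueError(f"survey {path}: {exc}") from exc
    return responses


def read_survey_wide(
    path: PathLike, roster: list[Actor], cap: int = 7
) -> list[SurveyResponse]:
    """Wide-format convenience reader (``<category>_1`` … ``<category>_cap``)."""
    df = pd.read_csv(path, dtype=str, comment="#")
    if "respondent_id" not in df.columns:
        raise ValueError(f"survey {path} missing required column respondent_id")
    long_rows = []
    for row in df.to_dict("records"):
        rid = str(row["respondent_id"])
        for cat in Category:
            for k in range(1, cap + 1):
                col = f"{cat.value}_{k}"
                tid = _opt_str(row.get(col)) if col in df.columns else None
                if tid:
                    long_rows.append(
                        {"respondent_id": rid, "target_id": tid, "category": cat.value}
                    )
    tmp = Path(path).with_suffix(".long.tmp.csv")
    pd.DataFrame(long_rows, columns=SURVEY_REQUIRED).to_csv(tmp, index=False)
    try:
        return read_survey(tmp, roster, cap=cap)
    finally:
        tmp.unlink(missing_ok=True)


def write_survey(responses: list[SurveyResponse], path: PathLike) -> None:
    rows = []
    for resp in responses:
        for nom in resp.nominations:
            rows.append(
                {
                    "respondent_id": nom.source_id,
                    "target_id": nom.target_id,
                    "category": nom.category.value,
                    "initiator": nom.initiator.value,
                    "mode": nom.mode.value,
                    "purpose": nom.purpose,
                    "acquaintance": nom.acquaintance,
                    "frequency": nom.frequency,
                }
            )
    pd.DataFrame(rows, columns=SURVEY_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# network exports
# ---------------------------------------------------------------------------

def write_edgelist(network: SociometricNetwork, path: PathLike) -> None:
    """Delimited edge table; network-level counts ride along as # comments."""
    header = (
        f"# isolate_count={network.isolate_count} "
        f"respondent_count={network.respondent_count} "
        f"counting_mode={network.counting_mode.value}\n"
    )
    rows = [r.as_tuple() for r in network.links()]
    df = pd.DataFrame(rows, columns=EDGELIST_COLUMNS)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_edgelist(path: PathLike, roster: list[Actor]) -> SociometricNetwork:
    """Rebuild a network from an exported edge list plus the roster."""
    meta = {"isolate_count": 0, "respondent_count": 0, "counting_mode": "link"}
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("#"):
        for token in first[1:].split():
            if "=" in token:
                key, value = token.split("=", 1)
                if key in meta:
                    meta[key] = value
    df = pd.read_csv(path, dtype=str, comment="#")
    missing = [c for c in EDGELIST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"edge list {path} missing columns: {missing}")

    index = {a.actor_id: a for a in roster}
    arcs: set[tuple[str, str]] = set()
    arc_types: dict[tuple[str, str], LinkType] = {}
    for row in df.to_dict("records"):
        u, v = str(row["source"]), str(row["target"])
        ltype = LinkType(str(row["link_type"]))
        reciprocal = _coerce_bool(row["reciprocal"])
        arcs.add((u, v))
        arc_types[(u, v)] = ltype
        if reciprocal and ltype == LinkType.peer_link:
            arcs.add((v, u))
            arc_types[(v, u)] = ltype

    connected = {x for arc in arcs for x in arc}
    unknown = connected - set(index)
    if unknown:
        raise KeyError(f"edge list {path} references unknown actors: {sorted(unknown)}")
    # Alter reconstruction: pm-arc targets are always alters; for a peer arc
    # the named person is the non-respondent endpoint when there is one
    # (brokerage arcs run peer->respondent), else the target.  Exact alter
    # sets survive in GraphML exports, which store the flag per node.
    alters = {v for (u, v) in arcs if arc_types[(u, v)] == LinkType.pm_link}
    for (u, v) in arcs:
        if arc_types[(u, v)] == LinkType.peer_link:
            u_resp, v_resp = index[u].is_respondent, index[v].is_respondent
            if u_resp and not v_resp:
                alters.add(v)
            elif v_resp and not u_resp:
                alters.add(u)
            else:
                alters.add(v)
    return SociometricNetwork(
        actors={aid: index[aid] for aid in connected},
        arcs=arcs,
        arc_types=arc_types,
        alter_ids=alters,
        isolate_count=int(meta["isolate_count"]),
        respondent_count=int(meta["respondent_count"]),
        counting_mode=CountingMode(meta["counting_mode"]),
    )


def _network_to_nx(network: SociometricNetwork) -> nx.DiGraph:
    g = nx.DiGraph(
        isolate_count=network.isolate_count,
        respondent_count=network.respondent_count,
        counting_mode=network.counting_mode.value,
    )
    for aid in sorted(network.actors):
        actor = network.actors[aid]
        attrs = {
            k: (v.value if hasattr(v, "value") else v)
            for k, v in actor.model_dump().items()
            if v is not None
        }
        attrs["is_alter"] = aid in network.alter_ids
        g.add_node(aid, **attrs)
    for (u, v) in sorted(network.arcs):
        g.add_edge(u, v, link_type=network.arc_types[(u, v)].value)
    return g


def write_graphml(network: SociometricNetwork, path: PathLike) -> None:
    """GraphML export carrying every actor attribute (for external viewers)."""
    nx.write_graphml(_network_to_nx(network), path)


def read_graphml(path: PathLike) -> SociometricNetwork:
    g = nx.read_graphml(path)
    actors: dict[str, Actor] = {}
    alter_ids: set[str] = set()
    for node, data in g.nodes(data=True):
        data = dict(data)
        if data.pop("is_alter", False):
            alter_ids.add(node)
        actors[node] = Actor(**data)
    arcs = set()
    arc_types = {}
    for u, v, data in g.edges(data=True):
        arcs.add((u, v))
        arc_types[(u, v)] = LinkType(data["link_type"])
    return SociometricNetwork(
        actors=actors,
        arcs=arcs,
        arc_types=arc_types,
        alter_ids=alter_ids,
        isolate_count=int(g.graph.get("isolate_count", 0)),
        respondent_count=int(g.graph.get("respondent_count", 0)),
        counting_mode=CountingMode(g.graph.get("counting_mode", "link")),
    )
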