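"""Domain types for sociometric surveys of researcher–policymaker networks.

A sociometric survey asks each respondent (the *ego*) to name the specific
people (*alters*) they interact with.  Here egos are university faculty
members and alters are either policymakers or academic peers, named under
three relationship categories:

``direct_to_pm``
    the respondent interacts with the named policymaker directly;
``via_peer``
    the respondent reaches policymakers through the named peer;
``broker_for_peer``
    the named peer uses the respondent as an intermediary to reach
    policymakers.

Respondents may name at most ``cap`` people per category (default 7, the
usual upper bound for name generators in sociometric instruments).
"""

from __future__ import annotations

import enum
import hashlib
from typing import Optional

from pydantic import BaseModel, ConfigDict, field_validator, model_validator


class Role(str, enum.Enum):
    faculty = "faculty"
    policymaker = "policymaker"


class Level(str, enum.Enum):
    """Policymaking level of an actor; ``none`` for plain researchers."""

    national = "national"
    provincial = "provincial"
    university = "university"
    none = "none"


class Category(str, enum.Enum):
    direct_to_pm = "direct_to_pm"
    via_peer = "via_peer"
    broker_for_peer = "broker_for_peer"


class Initiator(str, enum.Enum):
    researcher = "researcher"
    policymaker = "policymaker"
    third_party = "third_party"
    unknown = "unknown"


class ContactMode(str, enum.Enum):
    face_to_face = "face_to_face"
    other = "other"
    unknown = "unknown"


class LinkType(str, enum.Enum):
    pm_link = "pm_link"
    peer_link = "peer_link"


class CountingMode(str, enum.Enum):
    """How a reciprocal (two-way) peer tie is counted.

    ``link``: a reciprocal pair is ONE link (UCINET-style tie counting);
    ``arc``: every directed arc counts separately.
    """

    link = "link"
    arc = "arc"


DEFAULT_CAP = 7
N_CATEGORIES = 3


class Actor(BaseModel):
    """A person node: a faculty researcher or a policymaker."""

    model_config = ConfigDict(frozen=True)

    actor_id: str
    display_code: str = ""
    role: Role = Role.faculty
    level: Level = Level.none
    organization: str = ""
    university: str = ""
    is_respondent: bool = False
    has_decision_experience: bool = False
    gender: Optional[str] = None
    academic_rank: Optional[str] = None
    major: Optional[str] = None

    @model_validator(mode="after")
    def _policymaker_has_level(self) -> "Actor":
        if self.role == Role.policymaker and self.level == Level.none:
            raise ValueError(
                f"policymaker {self.actor_id!r} must carry a policymaking level"
            )
        return self


class Nomination(BaseModel):
    """One directed naming: a respondent names an alter under a category."""

    model_config = ConfigDict(frozen=True)

    source_id: str
    target_id: str
    category: Category
    initiator: Initiator = Initiator.unknown
    mode: ContactMode = ContactMode.unknown
    purpose: Optional[str] = None
    acquaintance: Optional[str] = None
    frequency: Optional[str] = None

    @model_validator(mode="after")
    def _no_self_nomination(self) -> "Nomination":
        if self.source_id == self.target_id:
            raise ValueError(f"self-nomination by {self.source_id!r}")
        return self


class SurveyResponse(BaseModel):
    """One respondent's nominations, validated against the per-category cap."""

    respondent_id: str
    nominations: list[Nomination] = []
    cap: int = DEFAULT_CAP

    @field_validator("cap")
    @classmethod
    def _cap_positive(cls, v: int) -> int:
        if v < 1:
            raise ValueError("nomination cap must be >= 1")
        return v

    @model_validator(mode="after")
    def _validate_nominations(self) -> "SurveyResponse":
        counts: dict[Category, int] = {}
        for nom in self.nominations:
            if nom.source_id != self.respondent_id:
                raise ValueError(
                    f"nomination by {nom.source_id!r} attached to respondent "
                    f"{self.respondent_id!r}"
                )
            counts[nom.category] = counts.get(nom.category, 0) + 1
        for cat, n in counts.items():
            if n > self.cap:
                raise ValueError(
                    f"respondent {self.respondent_id!r} names {n} people in "
                    f"category {cat.value!r} (cap {self.cap})"
                )
        return self

    def by_category(self, category: Category) -> list[Nomination]:
        return [n for n in self.nominations if n.category == category]

    @property
    def n_alters(self) -> int:
        return len({n.target_id for n in self.nominations})


def hash_name(name: str, prefix: str = "", length: int = 12) -> str:
    """Opaque, stable actor id from a person's name (confidentiality at ingest)."""
    digest = hashlib.sha256(name.strip().lower().encode("utf-8")).hexdigest()
    return f"{prefix}{digest[:length]}"
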