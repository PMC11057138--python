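"""End-to-end pipeline and structured reports.

``run_pipeline`` executes read → build → metrics → centrality → selection
and returns an :class:`AnalysisReport`; given an output directory it also
writes the report JSON, CSV tables and a GraphML export.  Reports carry a
provenance block (config hash, seed, package version) and contain no
timestamps, so regenerating from the same inputs and config is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Sequence, Union

from pydantic import BaseModel, Field

from . import __version__
from .builder import (
    SociometricNetwork,
    aggregate_by_organization,
    build_network,
    components,
)
from .centrality import centrality_records
from .io import write_edgelist, write_graphml, write_roster, write_survey
from .metrics import compute_characteristics, round_half_up
from .model import Actor, CountingMode, Level, Nomination, Role, SurveyResponse
from .selection import (
    identify_brokers,
    policymaker_tallies,
    select_key_policymakers,
)
from .synthetic import SurveySimConfig, calibrated_fixture, simulate_survey

logger = logging.getLogger(__name__)

NOMINATION_FIELDS = {"initiator", "mode", "purpose", "acquaintance", "frequency"}
ACTOR_FIELDS = {"gender", "academic_rank", "major", "role", "level",
                "university", "organization", "has_decision_experience"}


def tabulate_attribute(
    data: Sequence[Union[SurveyResponse, Nomination, Actor]], field: str
) -> dict:
    """Proportion table of one categorical attribute.

    Accepts survey responses (whose nominations are pooled), bare
    nominations, or actors.  Proportions are percentages over non-missing
    values, rounded half-up at two decimals; missing values are counted
    separately.  Unknown fields raise ``ValueError``.
    """
    if field not in NOMINATION_FIELDS | ACTOR_FIELDS:
        raise ValueError(f"unknown attribute field {field!r}")
    values = []
    for item in data:
        if isinstance(item, SurveyResponse):
            if field not in NOMINATION_FIELDS:
                raise ValueError(
                    f"{field!r} is not a nomination attribute; pass actors instead"
                )
            values.extend(getattr(nom, field) for nom in item.nominations)
        else:
            values.append(getattr(item, field))
    cleaned = []
    missing = 0
    for v in values:
        if v is None:
            missing += 1
            continue
        cleaned.append(v.value if hasattr(v, "value") else v)
    counts: dict[str, int] = {}
    for v in cleaned:
        key = str(v)
        counts[key] = counts.get(key, 0) + 1
    n = len(cleaned)
    proportions = {
        k: round_half_up(100.0 * c / n, 2) for k, c in sorted(counts.items())
    }
    return {"field": field, "n": n, "missing": missing, "percent": proportions}


class PipelineConfig(BaseModel):
    """Everything one analysis run depends on."""

    # input: exactly one of (roster+survey paths), simulate, calibrated
    roster_path: Optional[str] = None
    survey_path: Optional[str] = None
    simulate: Optional[SurveySimConfig] = None
    calibrated: bool = False

    cap: int = 7
    n_categories: int = 3
    counting_mode: str = "link"
    treat_directed: bool = True
    paper_compat: bool = False
    quantile: float = 0.5
    kp_threshold: Union[int, str] = "median_of_range"
    role_overrides: dict[str, str] = Field(default_factory=dict)
    attribute_fields: list[str] = Field(default_factory=lambda: ["initiator", "mode"])
    org_levels: list[str] = Field(default_factory=list)
    out_dir: Optional[str] = None

    def config_hash(self) -> str:
        payload = self.model_dump(exclude={"out_dir"})
        canon = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode("utf-8")).hexdigest()[:16]


class AnalysisReport(BaseModel):
    """Structured result of one pipeline run (JSON-serializable, no timestamps)."""

    characteristics: dict
    characteristics_full: dict
    components: dict
    centrality: list[dict]
    brokers: list[dict]
    key_policymakers: list[dict]
    organizations: dict[str, list[dict]]
    attribute_tables: dict[str, dict]
    provenance: dict


def _load_inputs(
    config: PipelineConfig,
) -> tuple[list[Actor], list[SurveyResponse]]:
    from .io import read_roster, read_survey  # local import avoids cycles

    if config.calibrated:
        return calibrated_fixture()
    if config.simulate is not None:
        return simulate_survey(config.simulate)
    if config.roster_path and config.survey_path:
        roster = read_roster(config.roster_path)
        responses = read_survey(config.survey_path, roster, cap=config.cap)
        return roster, responses
    raise ValueError(
        "pipeline config must name roster/survey paths, request simulation, "
        "or request the calibrated fixture"
    )


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Execute the full analysis and (optionally) write all artefacts."""
    roster, responses = _load_inputs(config)

    overrides = {aid: Role(role) for aid, role in config.role_overrides.items()}
    network = build_network(
        responses,
        roster,
        role_overrides=overrides or None,
        counting_mode=CountingMode(config.counting_mode),
    )
    n_respondents_total = sum(1 for a in roster if a.is_respondent)

    chars = compute_characteristics(
        network,
        n_respondents_total=n_respondents_total,
        n_categories=config.n_categories,
        cap=config.cap,
    )
    partition = components(network)
    records = centrality_records(
        network, treat_directed=config.treat_directed, cap=config.cap
    )
    brokers = identify_brokers(
        network,
        quantile=config.quantile,
        cap=config.cap,
        paper_compat=config.paper_compat,
        treat_directed=config.treat_directed,
    )
    key_pms = select_key_policymakers(
        policymaker_tallies(network), threshold=config.kp_threshold
    )
    org_networks = {
        level: aggregate_by_organization(network, Level(level))
        for level in config.org_levels
    }
    tables = {
        field: tabulate_attribute(responses, field)
        for field in config.attribute_fields
    }

    report = AnalysisReport(
        characteristics=chars.rounded(),
        characteristics_full=dict(chars.__dict__),
        components={
            "n_components": len(partition.components),
            "main_component_size": len(partition.main_component),
            "sizes": partition.sizes,
        },
        centrality=[
            {
                "actor_id": r.actor_id,
                "display_code": r.display_code,
                "outdeg_pm": r.outdeg_pm,
                "outdeg_peer": r.outdeg_peer,
                "indeg_peer": r.indeg_peer,
                "indeg_faculty": r.indeg_faculty,
                "betweenness_raw": r.betweenness_raw,
                "betweenness_norm_x100": r.betweenness_norm_x100,
            }
            for r in records
        ],
        brokers=[
            {
                "actor_id": b.actor_id,
                "display_code": b.display_code,
                "outdeg_pm_norm": b.outdeg_pm_norm,
                "indeg_peer_norm": b.indeg_peer_norm,
                "outdeg_peer_norm": b.outdeg_peer_norm,
                "betweenness_norm_x100": b.betweenness_norm_x100,
                "total_score": b.total_score,
                "selected": b.selected,
            }
            for b in brokers
        ],
        key_policymakers=[
            {
                "actor_id": t.actor_id,
                "display_code": t.display_code,
                "organization": t.organization,
                "indegree_from_faculty": t.indegree_from_faculty,
            }
            for t in key_pms
        ],
        organizations={
            level: [
                {"university": u, "organization": o, "weight": w}
                for (u, o), w in sorted(net.links.items())
            ]
            for level, net in org_networks.items()
        },
        attribute_tables=tables,
        provenance={
            "config_hash": config.config_hash(),
            "seed": config.simulate.seed if config.simulate else None,
            "version": __version__,
        },
    )

    if config.out_dir:
        _write_outputs(config, report, network, roster, responses)
    return report


def _write_outputs(
    config: PipelineConfig,
    report: AnalysisReport,
    network: SociometricNetwork,
    roster: list[Actor],
    responses: list[SurveyResponse],
) -> None:
    import pandas as pd

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(
        json.dumps(report.model_dump(), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    pd.DataFrame([report.characteristics]).to_csv(
        out / "characteristics.csv", index=False
    )
    pd.DataFrame(report.centrality).to_csv(out / "centrality.csv", index=False)
    pd.DataFrame(report.brokers).to_csv(out / "brokers.csv", index=False)
    pd.DataFrame(report.key_policymakers).to_csv(
        out / "key_policymakers.csv", index=False
    )
    write_edgelist(network, out / "edgelist.csv")
    write_graphml(network, out / "network.graphml")
    write_roster(roster, out / "roster.csv")
    write_survey(responses, out / "survey.csv")
    logger.info("wrote pipeline outputs to %s", out)


def report_json_schema() -> dict:
    """The JSON schema every report validates against (shipped with the repo)."""
    return AnalysisReport.model_json_schema()
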