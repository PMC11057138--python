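"""Structural characteristics of a nomination-capped sociometric network.

Because respondents may name at most ``cap`` people in each of
``n_categories`` categories, the usual density over all ordered pairs is
uninformative; the *effective density* divides observed ties by the maximum
the instrument permits (connected respondents × cap × categories).

Definitions (with T = ties, A = unique alters, I = isolates,
R = all respondents, C = respondents naming ≥ 1 alter, N = network size):

=======================  =================================
inclusiveness            N / (N + I)
average degree           T / N
effective density        T / (C × cap × n_categories)
absolute prevalence      C  (respondents with ≥ 1 alter)
proportionate prevalence C / R
breadth (contacts)       A
breadth (relations)      T
average breadth          T / R
depth                    (T − A) / A
=======================  =================================

Ratios are carried at full precision; summaries round half-up to two
decimals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal

from .builder import SociometricNetwork
from .model import SurveyResponse

logger = logging.getLogger(__name__)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.345 -> 0.35), unlike banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def truncate(x: float, ndigits: int = 2) -> float:
    """Chop toward zero at ``ndigits`` decimals (42.857 -> 42.85)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_DOWN))


@dataclass
class NetworkCharacteristics:
    """The structural-characteristics record of one drawn network."""

    network_size: int
    isolates: int
    inclusiveness: float
    average_degree: float
    average_degree_arc: float
    effective_density: float
    absolute_prevalence: int
    proportionate_prevalence: float
    breadth_contacts: int
    breadth_relations: int
    average_breadth: float
    depth: float
    potential_ties: int

    def rounded(self, ndigits: int = 2) -> dict:
        """Report view: ratios rounded half-up, counts untouched."""
        out = {}
        for key, value in self.__dict__.items():
            if isinstance(value, float):
                out[key] = round_half_up(value, ndigits)
            else:
                out[key] = value
        return out


def compute_characteristics(
    network: SociometricNetwork,
    n_respondents_total: int,
    n_categories: int = 3,
    cap: int = 7,
) -> NetworkCharacteristics:
    """Compute the full characteristics record for a built network.

    ``n_respondents_total`` counts *all* survey respondents, isolates
    included; the respondents who named at least one alter come from the
    network itself.
    """
    size = network.n_nodes
    isolates = network.isolate_count
    connected = network.respondent_count
    if n_respondents_total < connected:
        raise ValueError(
            f"n_respondents_total={n_respondents_total} is smaller than the "
            f"{connected} alter-naming connected respondents in the network"
        )
    ties = network.link_count
    alters = len(network.alter_ids)

    if size + isolates == 0:
        logger.warning("empty network and no isolates: inclusiveness undefined, reporting 0")
        inclusiveness = 0.0
    else:
        inclusiveness = size / (size + isolates)
    average_degree = ties / size if size else 0.0
    average_degree_arc = network.arc_count / size if size else 0.0
    potential = connected * cap * n_categories
    effective_density = ties / potential if potential else 0.0
    proportionate = connected / n_respondents_total if n_respondents_total else 0.0
    average_breadth = ties / n_respondents_total if n_respondents_total else 0.0
    depth = (ties - alters) / alters if alters else 0.0

    return NetworkCharacteristics(
        network_size=size,
        isolates=isolates,
        inclusiveness=inclusiveness,
        average_degree=average_degree,
        average_degree_arc=average_degree_arc,
        effective_density=effective_density,
        absolute_prevalence=connected,
        proportionate_prevalence=proportionate,
        breadth_contacts=alters,
        breadth_relations=ties,
        average_breadth=average_breadth,
        depth=depth,
        potential_ties=potential,
    )


def prevalence(responses: list[SurveyResponse]) -> tuple[int, float]:
    """(absolute, proportionate) prevalence of having named at least one alter."""
    if not responses:
        raise ValueError("prevalence undefined for zero respondents")
    absolute = sum(1 for r in responses if r.n_alters >= 1)
    return absolute, absolute / len(responses)
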