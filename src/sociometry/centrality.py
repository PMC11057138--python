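"""Degree and betweenness centrality with nomination-cap normalizations.

Degrees are split by tie type, matching how knowledge-broker indicators are
read off a researcher–policymaker network:

* ``outdeg_pm`` — ties the actor reports to policymakers (authority toward
  the policy side);
* ``outdeg_peer`` / ``indeg_peer`` — peer arcs out of / into the actor
  (reach into, and reputation among, academic peers);
* ``indeg_faculty`` — for policymakers, how many faculty report a tie to
  them (the key-policymaker tally).

Degree normalization divides by the ``cap`` potential nominees per category
and scales to 100.  In *paper-compat* mode the per-hundred value is
truncated (not rounded) at two decimals, the convention under which
published composite broker scores are additive to the printed digit.

Betweenness is computed on the combined peer+policymaker directed graph by
accumulation over single-source shortest-path DAGs (Brandes' algorithm);
normalization divides by (n−1)(n−2) ordered pairs (doubled when the graph
is treated as undirected) and scales to 100.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Optional

from .builder import SociometricNetwork
from .metrics import truncate
from .model import LinkType


@dataclass
class CentralityRecord:
    """Per-actor centrality indicators."""

    actor_id: str
    outdeg_pm: int = 0
    outdeg_peer: int = 0
    indeg_peer: int = 0
    indeg_faculty: int = 0
    betweenness_raw: float = 0.0
    betweenness_norm_x100: Optional[float] = None
    display_code: str = ""

    @property
    def outdeg_total(self) -> int:
        return self.outdeg_pm + self.outdeg_peer

    @property
    def indeg_total(self) -> int:
        return self.indeg_peer + self.indeg_faculty


def degree_centralities(network: SociometricNetwork) -> list[CentralityRecord]:
    """Typed in/out degrees for every connected actor.

    Reciprocal peer ties contribute one arc in each direction, so summed
    in-degree, summed out-degree and the arc count all agree.
    """
    records: dict[str, CentralityRecord] = {
        aid: CentralityRecord(
            actor_id=aid, display_code=network.actors[aid].display_code
        )
        for aid in network.actors
    }
    for (u, v) in network.arcs:
        if network.arc_types[(u, v)] == LinkType.pm_link:
            records[u].outdeg_pm += 1
            records[v].indeg_faculty += 1
        else:
            records[u].outdeg_peer += 1
            records[v].indeg_peer += 1
    return [records[aid] for aid in sorted(records)]


def betweenness(
    network: SociometricNetwork, treat_directed: bool = True
) -> dict[str, float]:
    """Raw betweenness: for each node v, sum over ordered pairs (s, t) of the
    fraction of shortest s–t paths through v (Brandes accumulation)."""
    adjacency: dict[str, list[str]] = {aid: [] for aid in network.actors}
    seen: set[tuple[str, str]] = set()
    for (u, v) in network.arcs:
        pairs = [(u, v)] if treat_directed else [(u, v), (v, u)]
        for a, b in pairs:
            if (a, b) not in seen:
                seen.add((a, b))
                adjacency[a].append(b)
    for nbrs in adjacency.values():
        nbrs.sort()

    scores = {aid: 0.0 for aid in network.actors}
    for s in sorted(network.actors):
        # single-source shortest paths (unweighted BFS)
        stack: list[str] = []
        predecessors: dict[str, list[str]] = {v: [] for v in adjacency}
        sigma = {v: 0.0 for v in adjacency}
        dist = {v: -1 for v in adjacency}
        sigma[s], dist[s] = 1.0, 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in adjacency[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    predecessors[w].append(v)
        # back-propagate dependencies along the shortest-path DAG
        delta = {v: 0.0 for v in adjacency}
        while stack:
            w = stack.pop()
            for v in predecessors[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                scores[w] += delta[w]
    if not treat_directed:
        # each unordered pair was visited from both endpoints
        scores = {v: x / 2.0 for v, x in scores.items()}
    return scores


def normalize_degree(count: int, cap: int = 7, paper_compat: bool = False) -> float:
    """Scale a nomination count to its cap: count/cap × 100.

    In paper-compat mode the value is truncated to two decimals
    (3/7 → 42.85, not 42.86); otherwise full precision is returned.
    """
    if count < 0:
        raise ValueError("degree count must be >= 0")
    if count > cap:
        raise ValueError(f"degree count {count} exceeds the nomination cap {cap}")
    value = count / cap * 100.0
    return truncate(value, 2) if paper_compat else value


def normalize_betweenness(raw: float, n: int, treat_directed: bool = True) -> float:
    """Per-hundred betweenness: raw / ((n−1)(n−2)) × 100, doubled if undirected."""
    if n < 3:
        raise ValueError("betweenness normalization requires n >= 3")
    denom = (n - 1) * (n - 2)
    value = raw / denom * 100.0
    return 2.0 * value if not treat_directed else value


def centrality_records(
    network: SociometricNetwork,
    treat_directed: bool = True,
    cap: int = 7,
) -> list[CentralityRecord]:
    """Degrees plus betweenness (raw and per-hundred ×100) in one table."""
    records = degree_centralities(network)
    raw = betweenness(network, treat_directed=treat_directed)
    n = network.n_nodes
    for rec in records:
        rec.betweenness_raw = raw[rec.actor_id]
        if n >= 3:
            rec.betweenness_norm_x100 = (
                normalize_betweenness(rec.betweenness_raw, n, treat_directed) * 100.0
            )
    return records
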