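# Methods

## Data model and network construction

A survey consists of a roster of actors (faculty or policymakers, the
latter carrying a policymaking level — national, provincial or
university — and an organization) and one response per respondent: up to
`cap` nominations (default 7, the usual upper bound for sociometric name
generators) in each of three relationship categories. Names are replaced
by opaque ids at ingest (`hash_name`), with display codes retained for
reporting.

The category → arc mapping is configurable because instruments differ in
how they phrase the brokerage item; the default is:

| category | arc | reading |
|---|---|---|
| `direct_to_pm` | respondent → policymaker | direct contact |
| `via_peer` | respondent → peer | the peer is the respondent's conduit |
| `broker_for_peer` | peer → respondent | the peer seeks the respondent's brokerage |

This default reproduces the canonical typology of such networks: ties to
policymakers are always one-way (only faculty are surveyed, so the policy
side can never reciprocate), while peer ties can be one- or two-way — a
two-way tie arising when a respondent names the same peer as both conduit
and brokerage client. Duplicate nominations of an ordered pair collapse
to one binary relation. Nominated people missing from the roster are
auto-registered as non-respondents, with role inferred from the category
(a `direct_to_pm` target is a policymaker, otherwise a faculty peer);
nothing is silently dropped — every dropped or auto-registered record is
logged and countable.

Three respondent subpopulations matter and are tracked separately:

* **isolates** — respondents with no tie at all; excluded from the drawn
  network, counted in `isolate_count` (the inclusiveness denominator);
* **alter-naming respondents** (`respondent_count`) — respondents who
  named ≥ 1 alter; the prevalence numerator and the effective-density
  denominator;
* respondents who named nobody but were named by someone — connected
  nodes that belong to neither set.

In the empirical setting these distinctions collapse (no respondent was
ever nominated), but on simulated data they matter.

Counting mode: under `link` counting (default) a reciprocal peer pair is
one link, so `links = arcs − reciprocal_pairs`; under `arc` counting every
directed arc counts. Link counting is the default because the tie
decomposition "total = policymaker ties + peer ties, of which some
two-way" is only additive under it. Components use weak connectivity
(direction ignored), ordered by size descending with ties broken by the
smallest actor id. Dual-role actors (a respondent who is also a known
policymaker) are handled by explicit `role_overrides` config, never by
inference; a nomination whose induced arc would violate the typing
invariants (e.g. a policymaker on the faculty side of a peer arc) is an
error by default, droppable by config.

## Structural characteristics

All ratios are carried at full precision and reported at two decimals with
decimal round-half-up (not banker's rounding). The degenerate empty
network reports zeros, warning when inclusiveness is genuinely undefined
(no nodes and no isolates). Two average degrees are computed — ties/N
(primary, consistent with link counting) and arcs/N — because on networks
with reciprocal ties they differ and both are defensible.

## Centrality and normalization

Betweenness is implemented directly (Brandes' single-source shortest-path
DAG accumulation, unweighted) rather than delegated, and is cross-checked
in the test suite against both an exhaustive path-enumeration oracle and
networkx. It runs on the combined peer + policymaker directed graph over
the full drawn network (isolates excluded, n = network size); an
undirected mode (symmetrize, halve) is exposed for sensitivity analysis.
Normalization: raw / ((n−1)(n−2)) × 100, doubled when undirected; the
composite-score indicator is that per-hundred value scaled by a further
×100, matching how UCINET-era reports print it.

Degree normalization is count/cap × 100. In **paper-compat mode** the
value is *truncated* (not rounded) at two decimals — 3/7 → 42.85 — because
published composite scores in this literature are additive to the printed
digit only under truncation; full precision is the default for new
analyses. Truncation is applied per indicator before summing.

## Selection rules

**Eligibility.** A broker candidate must be a faculty respondent with ≥ 1
policymaker tie and ≥ 1 peer arc in either direction. The rationale: an
actor with many policymaker ties but no peer connections, however central,
brokers nothing between peers and policy. The rule is a plain callable
and can be replaced.

**Top-half rule.** With m eligible candidates and quantile q (default
0.5), a candidate passes an indicator when at most ⌈(1−q)·m⌉ candidates
score at least as high — the candidate's *worst* position in a descending
ordering still falls inside the cut. Among the readings of "top 50 %"
this is the one that is simultaneously tie-symmetric (identical vectors
are selected or rejected together), monotone in q, selects a lone
candidate, and never lets a large block of candidates tied on a shared
low value flood through the cut — which the permissive
"ties-take-the-best-position" reading does. Selection requires passing
all four indicators; output is ordered selected-first by total score.

**Key policymakers.** The cut-off is the median of the observed
nomination-frequency *range* — the midpoint of min and max, e.g. 3 for
frequencies spanning 1–5 — not the median of the frequency distribution,
which a long tail of single nominations would drag to 1 and which would
select most of the policy side. Selection is `indegree ≥ cut`; a
degenerate all-equal range selects everyone with a warning; an integer
config value overrides the rule.

## Synthetic data

The stochastic generator (`simulate_survey`) emulates a census-style
survey of a 302-member faculty population: response is
Bernoulli(0.5033) per person; a respondent reports policymaker contact
with probability 0.37, in which case direct nominations number
min(1 + Poisson(1.25), 7) and peer nominations follow capped
Poisson(0.65) (conduits) and Poisson(0.30) (brokerage clients); each
conduit is additionally named as a brokerage client with probability
0.173, producing two-way peer ties near the empirical 9-in-52 rate; 23.68 %
of respondents carry decision-making experience; interaction attributes
follow a (0.54, 0.30, 0.16) initiator mixture and a 0.657 face-to-face
rate. The Poisson rates were chosen so the expected total tie count sits
near 177. Identical config and seed give identical output (single
`numpy` generator, fixed draw order).

What the generator does *not* model: homophily, university clustering,
degree assortativity, or any particular observed topology — so tests
passing on simulated data certify the pipeline's arithmetic and
statistical calibration, not its behaviour on structured real-world
networks.

The **calibrated fixture** (`calibrated_fixture`) is constructed, not
sampled: nomination lists are laid out deterministically so that the
marginal counts are exact — 152 respondents, 56 naming ≥ 1 alter, 94
policymakers all nominated, 38 nominated non-respondent peers, 125
policymaker links, 52 peer links (9 reciprocal), 96 isolates; 188 nodes
and 177 links in all. Policymaker in-degrees follow
{5, 5, 4, 3, 3, 3} + 14 × 2 + 74 × 1 (sum 125), so the median-of-range
rule selects exactly six; note a frequency profile with 75 singletons and
only 13 doubles cannot sum to 125 with that top set, so one extra
twice-nominated policymaker absorbs the difference. Policymaker arcs are
assigned greedily against a graded respondent out-degree sequence
(5, 4, 4, 4, five 3s, a tail of 2s and a 1) so each relation stays binary;
peer ties concentrate on the same first respondents, giving the network a
four-member brokerage core that the top-half rule recovers. The
organization layout puts 42 links on the national health ministry and
spreads the rest over nine national, ~20 provincial and ten
university-level organizations. The per-category split of policymaker
links and the within-respondent distribution of peer links are free
parameters of the construction and are documented in the source.

## Numerical and design choices

* Rounding: round-half-up at 2 decimals for reports; truncation at 2
  decimals only in paper-compat normalization. Both via `decimal`, no
  float re-rounding artefacts.
* Betweenness ties: none to break — the algorithm is exact on unweighted
  graphs; determinism comes from sorted adjacency and node iteration.
* Deterministic ordering everywhere a list is returned (components by
  size then id; tallies by indegree then id; broker scores by selection,
  total, id).
* Reports contain no timestamps; provenance is (config hash, seed,
  version), making byte-identical regeneration a testable contract.
* The report JSON schema shipped in `src/sociometry/schemas/` is generated
  from the pydantic `AnalysisReport` model, which is also the validator.
* Edge-list round-trips preserve node/arc multisets plus the
  isolate/respondent counts (carried as a comment line); GraphML
  round-trips are exact including per-node alter flags.

## Problem sizes in the test and acceptance runs

Betweenness is verified against exhaustive enumeration on 50 random
digraphs of ≤ 10 nodes (enumeration is exponential beyond that);
statistical recovery uses 200 replicates of the 302-person population,
with pooled counts tested against exact binomial 99 % intervals. The full
suite runs in well under a minute.

## Known limitations

* The eligibility rule is a reasoned default; published studies rarely
  state theirs precisely enough to validate a candidate count against.
* Betweenness normalization follows the standard directed formula; legacy
  UCINET output can differ slightly depending on symmetrization settings
  that are generally unrecoverable from published tables.
* The organizational roll-up weights links only; it does not model
  organization-level ties that bypass individuals.
* No inferential uncertainty is attached to selections — the rules are
  deterministic cut-offs, as in the literature they formalize.
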