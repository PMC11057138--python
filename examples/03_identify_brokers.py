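"""Identify academic knowledge brokers.

Scores every eligible faculty respondent on four cap-normalized indicators
(out-degree to policymakers, in-degree from peers, out-degree to peers,
per-hundred betweenness) and keeps those in the top half of the pool on
all four at once.
"""

from sociometry import build_network, calibrated_fixture, identify_brokers

roster, responses = calibrated_fixture()
network = build_network(responses, roster)

scored = identify_brokers(network, quantile=0.5, paper_compat=True)
print(f"eligible candidates (>=1 policymaker tie AND >=1 peer arc): {len(scored)}")
print()
header = f"{'code':8} {'pm_out':>7} {'peer_in':>8} {'peer_out':>9} {'betw':>7} {'total':>8} sel"
print(header)
for s in scored:
    print(
        f"{s.display_code:8} {s.outdeg_pm_norm:7.2f} {s.indeg_peer_norm:8.2f} "
        f"{s.outdeg_peer_norm:9.2f} {s.betweenness_norm_x100:7.2f} "
        f"{s.total_score:8.2f} {'*' if s.selected else ''}"
    )
print()
print("Selected rows are in the top 50% on every indicator simultaneously;")
print("a high policymaker out-degree alone (with no peer arcs) never qualifies,")
print("because such an actor brokers nothing between peers and policy.")
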