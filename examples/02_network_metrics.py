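"""Build the researcher-policymaker network and compute its structure.

Uses the calibrated survey — a deterministic dataset whose marginal counts
match a published census of faculty in ten medical universities — builds
the typed directed network, and prints the structural-characteristics
record.
"""

import json

from sociometry import (
    build_network,
    calibrated_fixture,
    components,
    compute_characteristics,
)

roster, responses = calibrated_fixture()
network = build_network(responses, roster)

print(
    f"{network.n_nodes} nodes, {network.link_count} links "
    f"({network.pm_link_count} to policymakers, {network.peer_link_count} to peers, "
    f"{network.reciprocal_count} two-way), {network.isolate_count} isolates"
)
part = components(network)
print(f"components: {len(part.components)}, largest has {len(part.main_component)} nodes")

record = compute_characteristics(network, n_respondents_total=152)
print(json.dumps(record.rounded(), indent=2))
print()
print("Effective density 0.15 means the 56 connected respondents used 177 of")
print("the 1176 ties their 7-per-category nomination budget allowed; depth")
print("0.34 says ties overlap onto shared alters by about a third.")
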