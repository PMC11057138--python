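from pathlib import Path

import numpy as np
import pytest

from sociometry import build_network, calibrated_fixture
from sociometry.builder import SociometricNetwork
from sociometry.model import Actor, LinkType

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def roster_path() -> Path:
    return DATA / "roster_10.csv"


@pytest.fixture(scope="session")
def survey_path() -> Path:
    return DATA / "survey_5.csv"


@pytest.fixture(scope="session")
def calibrated():
    """(roster, responses) of the deterministic calibrated survey."""
    return calibrated_fixture()


@pytest.fixture(scope="session")
def calibrated_network(calibrated) -> SociometricNetwork:
    roster, responses = calibrated
    return build_network(responses, roster)


def random_digraph(rng: np.random.Generator, n: int, p: float = 0.3):
    """A directed graph over n anonymous faculty nodes, as a network object."""
    arcs = set()
    for u in range(n):
        for v in range(n):
            if u != v and rng.random() < p:
                arcs.add((f"a{u:02d}", f"a{v:02d}"))
    return SociometricNetwork(
        actors={f"a{i:02d}": Actor(actor_id=f"a{i:02d}") for i in range(n)},
        arcs=arcs,
        arc_types={a: LinkType.peer_link for a in arcs},
    )
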