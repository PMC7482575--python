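"""Small deterministic instances shared by the test suites and examples."""

from __future__ import annotations

import numpy as np

from .dynamics import SwarmState, init_aligned
from .network import (
    DegreeSequence,
    InteractionNetwork,
    LatticeSpec,
    build_nn_lattice,
)


def make_fixtures(seed: int = 0) -> dict:
    """Toy cases: the complete graph K4, a two-agent stretched spring
    (rest length 1, initial separation 2), small lattices (L = 3..9) and a
    canned uniform noise stream for replay tests."""
    rng = np.random.default_rng(seed)
    out: dict = {}

    out["k4"] = InteractionNetwork(
        4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    )

    pair = InteractionNetwork(2, [(0, 1)], rest_lengths=[1.0])
    pair_state = SwarmState(
        headings=np.array([0.0, np.pi]),
        positions=np.array([[0.0, 0.0], [2.0, 0.0]]),
    )
    out["spring_pair"] = (pair, pair_state)

    for L in (3, 4, 5, 9):
        positions, net = build_nn_lattice(LatticeSpec(L))
        out[f"lattice_{L}"] = (positions, net)

    out["aligned_9"] = init_aligned(out["lattice_9"][0], np.pi / 2)
    out["canned_noise"] = rng.random((64, 9)) - 0.5
    return out


def sequence_k4() -> DegreeSequence:
    """Degree histogram whose unique simple realization is K4."""
    return DegreeSequence({3: 4})
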