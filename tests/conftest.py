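"""Shared fixtures: canonical synthetic structures and random-frame helpers."""

from __future__ import annotations

import numpy as np
import pytest

from pentassembly.geometry import random_rotation_matrix
from pentassembly.structures import SystemFrame, copy_chain
from pentassembly.synthetic import (
    BoxSpec,
    BuildSpec,
    build_chain,
    build_minimum_bias_box,
    build_salt_bridge_dimer,
    build_sheet_pair,
    build_turn_chain,
)

EXTENDED = ((-139.0, 135.0),) * 5


@pytest.fixture(scope="session")
def extended_chain():
    return build_chain(BuildSpec(phi_psi=EXTENDED))


@pytest.fixture(scope="session")
def beta_turn_chain():
    return build_turn_chain("BETA_TURN")


@pytest.fixture(scope="session")
def gamma_turn_chain():
    return build_turn_chain("GAMMA_TURN")


@pytest.fixture(scope="session")
def anti_sheet_creka():
    return build_sheet_pair("ANTIPARALLEL", "CREKA")


@pytest.fixture(scope="session")
def par_sheet_creka():
    return build_sheet_pair("PARALLEL", "CREKA")


@pytest.fixture(scope="session")
def anti_sheet_crenka():
    return build_sheet_pair("ANTIPARALLEL", "CRE^N^KA")


@pytest.fixture(scope="session")
def par_sheet_crenka():
    return build_sheet_pair("PARALLEL", "CRE^N^KA")


@pytest.fixture(scope="session")
def dimer_frame():
    return build_salt_bridge_dimer()


@pytest.fixture(scope="session")
def bias_box():
    return build_minimum_bias_box(BoxSpec(seed=11))


def make_random_frame(seed: int, n_chains: int = 4, spread: float = 1.2) -> SystemFrame:
    """Chains in mixed conformations thrown into a small region so that
    inter-chain bonds and clashes of every kind occur.  Cheap: the template
    chains are built once and rigidly re-placed."""
    rng = np.random.default_rng(seed)
    templates = _template_chains()
    chains = []
    for i in range(n_chains):
        tpl = templates[int(rng.integers(len(templates)))]
        c = copy_chain(tpl, chain_id=chr(ord("A") + i))
        rot = random_rotation_matrix(rng)
        shift = rng.uniform(-spread, spread, 3)
        coords = (c.coordinates() - c.center()) @ rot.T + shift
        c.set_coordinates(coords)
        chains.append(c)
    return SystemFrame(frame_index=0, chains=chains)


_TEMPLATES = None


def _template_chains():
    global _TEMPLATES
    if _TEMPLATES is None:
        _TEMPLATES = (
            build_chain(BuildSpec(phi_psi=EXTENDED)),
            build_turn_chain("BETA_TURN"),
            build_turn_chain("GAMMA_TURN"),
            build_chain(BuildSpec(sequence="CRE^N^KA", phi_psi=EXTENDED)),
        )
    return _TEMPLATES
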