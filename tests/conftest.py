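import dataclasses
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle module

import uofba as u

MU = 0.03      # 1/h, typical exponential-phase specific growth rate
QP = 0.001     # mmol/gDW/h, small recombinant-product flux


@pytest.fixture(scope="session")
def net1():
    return u.hypothetical_network(False, {"A": 4, "B": 6, "C": 8, "D": 10})


@pytest.fixture(scope="session")
def net2():
    return u.hypothetical_network(True, {"A": 4, "B": 6, "C": 8, "D": 10})


@pytest.fixture(scope="session")
def toy():
    return u.toy_mammalian(n_essential=12, n_nonessential=6, seed=1)


@pytest.fixture(scope="session")
def toy_enm(toy):
    return u.enm_sweep(toy, MU, QP)


@pytest.fixture(scope="session")
def toy_profile(toy):
    """Exactly self-consistent profile (minimal-waste forward simulation)."""
    return u.forward_profile(toy, MU, QP, seed=7, secretion_floors={"EX_lac": 0.02})


@pytest.fixture(scope="session")
def toy_profile_slack(toy_profile):
    """Same scenario with glucose measured above its minimal requirement."""
    rates = dict(toy_profile.measured_rates)
    rates["EX_glc"] += 0.01
    return dataclasses.replace(toy_profile, measured_rates=rates)
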