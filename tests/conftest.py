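import numpy as np
import pytest
from hypothesis import settings

from emra.fixtures import get_fixture, make_toy_chain
from emra.kinetics import ParameterSet, solve_vmax
from emra.network import MetabolicNetwork

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mcc_mixed():
    return get_fixture("mcc_mixed_1_3")


@pytest.fixture(scope="session")
def mcc_xpk():
    return get_fixture("mcc_xpk")


@pytest.fixture(scope="session")
def purge_valve():
    return get_fixture("purge_valve_phb")


@pytest.fixture(scope="session")
def chimeric():
    return get_fixture("chimeric_glycolysis")


@pytest.fixture(scope="session")
def isoprene():
    return get_fixture("glucose_isoprene")


@pytest.fixture
def gk_toy():
    """Glc + ATP -> G6P + ADP with exchanges and an ADP-recycling step."""
    return MetabolicNetwork(
        metabolite_ids=["Glc", "ATP", "G6P", "ADP"],
        reaction_ids=["IN", "GK", "OUT", "ADK"],
        S=np.array([[1, -1, 0, 0], [0, -1, 0, 1], [0, 1, -1, 0], [0, 1, 0, -1]]),
        reversible=np.array([False] * 4),
        kind=["input_exchange", "enzymatic", "output_exchange", "enzymatic"],
        vref=np.ones(4),
    )


@pytest.fixture
def rev_uni_uni():
    """in -> A <-> B -> out with a reversible conversion."""
    return MetabolicNetwork(
        metabolite_ids=["A", "B"],
        reaction_ids=["IN", "R", "OUT"],
        S=np.array([[1, -1, 0], [0, 1, -1]]),
        reversible=np.array([False, True, False]),
        kind=["input_exchange", "enzymatic", "output_exchange"],
        vref=np.ones(3),
    )


@pytest.fixture
def closed_ab():
    """Closed A <-> B interconversion (no exchanges, equilibrium toy)."""
    return MetabolicNetwork(
        metabolite_ids=["A", "B"],
        reaction_ids=["R"],
        S=np.array([[-1], [1]]),
        reversible=np.array([True]),
        kind=["enzymatic"],
        vref=np.array([1.0]),
        check_balance=False,
    )


@pytest.fixture
def single_species():
    """in -> M1 -> out; the textbook one-dimensional example."""
    net = make_toy_chain(1)
    p = solve_vmax(net, ParameterSet(kbar={("OUT", "M1"): 1.0}))
    return net, p


def unit_kbar(net):
    """All-ones scaled affinities for every slot a network needs."""
    kbar = {}
    for j, rxn in enumerate(net.reaction_ids):
        if net.kind[j] == "input_exchange":
            continue
        for met, _ in net.substrates(rxn):
            kbar[(rxn, met)] = 1.0
        if net.kind[j] == "enzymatic" and net.reversible[j]:
            for met, _ in net.products(rxn):
                kbar[(rxn, met)] = 1.0
    return kbar
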