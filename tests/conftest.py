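import numpy as np
import pytest

from quiflux.netdef import toy_branch_config
from quiflux.network import FluxParameterSet, build_network
from quiflux.synthetic import make_condition_preset


@pytest.fixture(scope="session")
def net():
    """The packaged central-carbon network."""
    return build_network()


@pytest.fixture(scope="session")
def presets(net):
    from quiflux.synthetic import CONDITIONS
    return {c: make_condition_preset(c, net) for c in CONDITIONS}


@pytest.fixture(scope="session")
def toy_net():
    return build_network(toy_branch_config())


@pytest.fixture(scope="session")
def toy_parallel_net():
    return build_network(toy_branch_config(parallel=True))


@pytest.fixture()
def toy_truth():
    return FluxParameterSet({"f1": 0.02}, {"A": 0.05}, {"P": 0.3, "Q": 0.15})


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_feasible_free_fluxes(rng, net, scale=0.01):
    """Constructively sample a feasible free-flux set for the central model.

    Each closure inequality is satisfied by drawing downstream demands as
    fractions of their supplies; the result is validated once.
    """
    from quiflux.network import evaluate_all_fluxes

    u = rng.uniform
    free = {}
    free["F1"] = float(u(2, 6) * scale)
    free["F0"] = float(u(0.5, 1.5) * scale)
    free["F4"] = float(u(0.1, 0.9) * free["F0"])               # ntp >= 0
    free["F2"] = float(u(0.5, 0.95) * (2 * free["F1"] + free["F4"] / 3))
    free["F12"] = float(u(0.1, 2.0) * scale)
    free["F5"] = float(u(0.1, 0.5) * scale)
    free["F3"] = float(u(0.05, 0.3) * scale)
    free["F7"] = float(u(0.1, 0.9) * (free["F5"] + free["F3"]))  # fa_syn > 0
    free["F11"] = float(u(0.0, 0.5) * free["F7"])
    free["F10"] = float(u(1.0, 2.0) * free["F7"])
    free["F8"] = float(free["F7"] + u(0.1, 1.0) * scale)       # glu_akg >= 0
    f6 = free["F7"] + free["F10"] - free["F11"]
    y = float(u(0.1, 0.9) * f6)                                # Z >= 0
    rates = {
        "A": free["F0"] + free["F1"] + float(u(0.1, 1.0)) * scale,
        "B": free["F2"] - free["F5"] - y,                      # pins Y >= 0
        "C": free["F8"] + free["F11"] + float(u(0.5, 1.5)) * scale,
        "D": float(u(0.01, 0.2)) * scale,
    }
    assert rates["B"] > 0
    evaluate_all_fluxes(net, free, rates)   # raises if construction is wrong
    return free, rates
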