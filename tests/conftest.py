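import numpy as np
import pytest

from msnsig import build_network
from msnsig.simulate import equilibrate, ScalingState, nmdar_ratio
from msnsig.model_def import DEFAULT_F


@pytest.fixture(scope="session")
def model():
    """Standard network with the single-pool ERK-crosstalk scheme applied."""
    return build_network(scheme="010")


@pytest.fixture(scope="session")
def basal(model):
    net, params = model
    return equilibrate(net, params, tol=3e-8)


@pytest.fixture(scope="session")
def scaling(model, basal):
    net, params = model
    r0 = nmdar_ratio(net, basal, "yTrf", params.totals["NMDAR"])
    return ScalingState("yTrf", DEFAULT_F["yTrf"], r0)


@pytest.fixture(scope="session")
def toy_enzyme():
    """E + S <-> ES -> E + P with textbook conservation."""
    from msnsig.network import Species, Reaction, ReactionNetwork, ParameterSet
    species = [
        Species("E", "E"), Species("S", "S"),
        Species("ES", "E", contents=(("E", 1), ("S", 1))),
        Species("P", "S"),
    ]
    rxn = Reaction("cat", "enzymatic", (("E", 1), ("S", 1)), (("E", 1), ("P", 1)),
                   complex_id="ES")
    net = ReactionNetwork(species, [rxn])
    params = ParameterSet({("cat", "kf"): 1.0, ("cat", "kr"): 2.0,
                           ("cat", "kcat"): 0.5},
                          {"E": 1.0, "S": 2.0}, {"E": "E", "S": "S"})
    return net, params
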