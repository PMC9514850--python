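import numpy as np
import pytest

from difflux.gpr import parse_gpr
from difflux.model import Enzyme, MetabolicModel, Reaction


@pytest.fixture
def chain_model():
    """Linear chain: uptake (ub 5) -> A -> B -> secretion; bottleneck 5."""
    return MetabolicModel(
        model_id="chain",
        metabolites=["A", "B"],
        reactions=[
            Reaction("uptake", {"A": 1.0}, 0.0, 5.0, None, "exchange"),
            Reaction("conv", {"A": -1.0, "B": 1.0}, 0.0, 10.0,
                     parse_gpr("g1 and g2"), "core"),
            Reaction("secretion", {"B": -1.0}, 0.0, 10.0, None, "exchange"),
        ],
        genes=["g1", "g2"],
    )


@pytest.fixture
def diamond_model():
    """Two parallel branches A->B->D and A->C->D between uptake and secretion."""
    return MetabolicModel(
        model_id="diamond",
        metabolites=["A", "B", "C", "D"],
        reactions=[
            Reaction("uptake", {"A": 1.0}, 0.0, 4.0, None, "exchange"),
            Reaction("ab", {"A": -1.0, "B": 1.0}, 0.0, 10.0, None, "left"),
            Reaction("bd", {"B": -1.0, "D": 1.0}, 0.0, 10.0, None, "left"),
            Reaction("ac", {"A": -1.0, "C": 1.0}, 0.0, 10.0, None, "right"),
            Reaction("cd", {"C": -1.0, "D": 1.0}, 0.0, 10.0, None, "right"),
            Reaction("secretion", {"D": -1.0}, 0.0, 4.0, None, "exchange"),
        ],
        genes=[],
    )


@pytest.fixture
def enzymatic_model():
    """One enzymatic conversion with kcat=10/h, mw=2 mg/mmol, pool=1 mg/gDW:
    effective vmax = kcat * pool / mw = 5."""
    return MetabolicModel(
        model_id="enz",
        metabolites=["A", "B"],
        reactions=[
            Reaction("uptake", {"A": 1.0}, 0.0, 100.0, None, "exchange"),
            Reaction("conv", {"A": -1.0, "B": 1.0}, 0.0, 100.0, None, "core",
                     Enzyme(kcat=10.0, mw=2.0)),
            Reaction("secretion", {"B": -1.0}, 0.0, 100.0, None, "exchange"),
        ],
        genes=[],
        enzyme_pool=1.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
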