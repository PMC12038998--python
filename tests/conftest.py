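import numpy as np
import pytest

from cysmca.model import (
    MetabolicModel,
    MetaboliteSpec,
    ReactionSpec,
    build_reduced_model,
)
from cysmca.synthetic import (
    generate_perturbation_dataset,
    make_default_kinetic_model,
)


@pytest.fixture(scope="session")
def reduced_model():
    return build_reduced_model()


@pytest.fixture(scope="session")
def kmodel():
    """Default ground-truth kinetic model (seed 1)."""
    return make_default_kinetic_model(seed=1)


@pytest.fixture(scope="session")
def dataset(kmodel):
    """Noise-free 13-state perturbation dataset."""
    return generate_perturbation_dataset(kmodel, noise_cv=0.0, seed=0)


@pytest.fixture(scope="session")
def fedbatch_series():
    from cysmca.fedbatch import generate_fedbatch_series

    return generate_fedbatch_series()


@pytest.fixture()
def toy_chain():
    """uptake (<=10) -> conversion -> export, single solution at optimum."""
    mets = [MetaboliteSpec("A"), MetaboliteSpec("B")]
    rxns = [
        ReactionSpec("up", stoichiometry={"A": 1}, upper_bound=10),
        ReactionSpec("conv", stoichiometry={"A": -1, "B": 1}),
        ReactionSpec("exp", stoichiometry={"B": -1}),
    ]
    return MetabolicModel(mets, rxns)


@pytest.fixture()
def loop_model():
    """Chain plus an internal 2-cycle (f: A->B, g: B->A)."""
    mets = [MetaboliteSpec("A"), MetaboliteSpec("B")]
    rxns = [
        ReactionSpec("in", stoichiometry={"A": 1}, upper_bound=5),
        ReactionSpec("f", stoichiometry={"A": -1, "B": 1}),
        ReactionSpec("g", stoichiometry={"B": -1, "A": 1}),
        ReactionSpec("out", stoichiometry={"B": -1}),
    ]
    return MetabolicModel(mets, rxns)


@pytest.fixture()
def chain_kinetic_model():
    """Two-step linear chain with eps_supply = -1, eps_demand = +1.

    Closed form: both flux control coefficients are 1/2.
    """
    from cysmca.synthetic import KineticModel

    mets = [MetaboliteSpec("X", internal=False), MetaboliteSpec("S")]
    rxns = [
        ReactionSpec("supply", stoichiometry={"X": -1, "S": 1}),
        ReactionSpec("demand", stoichiometry={"S": -1}),
    ]
    model = MetabolicModel(mets, rxns)
    return KineticModel(
        model=model,
        dynamic_species=["S"],
        c_ref={"X": 1.0, "S": 1.0},
        J_ref={"supply": 1.0, "demand": 1.0},
        kinds={"supply": "linlog", "demand": "linlog"},
        elasticities={"supply": {"S": -1.0}, "demand": {"S": 1.0}},
        dG_ref={},
        dG0={},
        exogenous=(),
    )
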