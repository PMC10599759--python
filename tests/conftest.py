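import warnings

import numpy as np
import pytest

from neurometnet import (
    SyntheticSpec,
    generate_de_tables,
    generate_toy_network,
    run_analysis,
)
from neurometnet.model_io import MetabolicModel


def make_chain_model(uptake_cap: float = 10.0) -> MetabolicModel:
    """uptake(<=cap) -> convert -> export with the objective on export."""
    return MetabolicModel(
        metabolite_ids=["m1_c", "m2_c"],
        reaction_ids=["uptake", "convert", "export"],
        S=np.array([[1.0, -1.0, 0.0], [0.0, 1.0, -1.0]]),
        lower_bounds=np.array([0.0, 0.0, 0.0]),
        upper_bounds=np.array([uptake_cap, 1000.0, 1000.0]),
        objective_coefficients=np.array([0.0, 0.0, 1.0]),
        cell_label=["neuron", "neuron", "neuron"],
        gpr=["g1", "g2", "g3"],
    )


@pytest.fixture
def chain_model():
    return make_chain_model()


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticSpec(seed=0)


@pytest.fixture(scope="session")
def toy_model(default_spec):
    return generate_toy_network(default_spec)


@pytest.fixture(scope="session")
def toy_de_table(default_spec, toy_model):
    return generate_de_tables(toy_model, default_spec)


@pytest.fixture(scope="session")
def toy_analysis(toy_model, toy_de_table):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_analysis(toy_model, toy_de_table)
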