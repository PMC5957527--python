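import numpy as np
import pytest

from avoidgen import (
    AgentParams,
    ModelSpec,
    Variant,
    build_design,
    generate_sequence,
    simulate_agent,
)


@pytest.fixture(scope="session")
def design():
    return build_design()


@pytest.fixture(scope="session")
def sequence(design):
    return generate_sequence(design, seed=123)


@pytest.fixture(scope="session")
def two_width_spec():
    return ModelSpec(variant=Variant.VALUE_2WIDTH)


@pytest.fixture(scope="session")
def typical_params():
    return AgentParams(kappa=0.5, eta=0.3, beta_choice=5.0, bias=0.4,
                       sigma_a=0.75, sigma_n=0.03)


@pytest.fixture(scope="session")
def session_fixture(typical_params, two_width_spec, sequence):
    sess, trace = simulate_agent(typical_params, two_width_spec, sequence,
                                 seed=7)
    return sess


def random_agent_params(rng, spec):
    """Random parameters drawn inside their native bounds."""
    kw = dict(
        kappa=float(rng.uniform(0.05, 0.95)),
        eta=float(rng.uniform(0.05, 0.95)),
        beta_choice=float(rng.uniform(0.1, 10.0)),
        bias=float(rng.uniform(-1.0, 1.0)),
    )
    if spec.variant is not Variant.PERCEPTUAL_ONLY:
        kw["sigma_a"] = float(rng.uniform(0.02, 2.0))
    if spec.variant is Variant.VALUE_2WIDTH:
        kw["sigma_n"] = float(rng.uniform(0.02, 2.0))
    return AgentParams(**kw)
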