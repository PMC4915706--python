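import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fluxinfer.expression import eflux_bounds, reaction_expression, spot_weights
from fluxinfer.fixtures import ToySpec, make_toy_model
from fluxinfer.template import build_template, relax_bounds

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def chain():
    return make_toy_model(ToySpec(topology="chain"))


@pytest.fixture(scope="session")
def branch():
    return make_toy_model(ToySpec(topology="branch"))


@pytest.fixture(scope="session")
def cycle():
    return make_toy_model(ToySpec(topology="cycle"))


@pytest.fixture(scope="session")
def spot_ratio():
    return make_toy_model(ToySpec(topology="spot_ratio"))


@pytest.fixture(scope="session")
def composite():
    return make_toy_model(ToySpec(topology="composite"))


def dc_carbon(topology):
    return {"composite": "EX_glc"}.get(topology, "EX_A")


@pytest.fixture(scope="session")
def composite_dc(composite):
    """DC template, reaction expression and E-Flux bounds for the composite net."""
    model, profile, measured = composite
    template = build_template(model, "DC", carbon_source="EX_glc")
    rxnexp = reaction_expression(template, profile)
    return template, rxnexp, eflux_bounds(template, rxnexp), measured


@pytest.fixture(scope="session")
def branch_dc(branch):
    model, profile, measured = branch
    template = build_template(model, "DC", carbon_source="EX_A")
    rxnexp = reaction_expression(template, profile)
    return template, rxnexp, eflux_bounds(template, rxnexp), measured


@pytest.fixture(scope="session")
def spot_ratio_relaxed(spot_ratio):
    """Bare relaxed template for the ratio toy (keeps all reactions forward)."""
    model, profile, measured = spot_ratio
    template = relax_bounds(model)
    rxnexp = reaction_expression(template, profile)
    return template, rxnexp, spot_weights(template, rxnexp), measured
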