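"""Shared fixtures: the packaged toy network, its states and references,
plus tiny hand-built networks with closed-form solutions."""

from __future__ import annotations

import pytest

from fluxdesigner.refstates import build_reference
from fluxdesigner.solvers import apply_state
from fluxdesigner.stoichmodel import Metabolite, Reaction, StoichiometricModel
from fluxdesigner.toynet import build_core_model, build_vg_model, make_state_spec


@pytest.fixture(scope="session")
def core_model():
    return build_core_model()


@pytest.fixture(scope="session")
def vg_model():
    return build_vg_model()


@pytest.fixture(scope="session")
def respiratory_state():
    return make_state_spec("respiratory")


@pytest.fixture(scope="session")
def rf_state():
    return make_state_spec("respiro_fermentative")


@pytest.fixture(scope="session")
def vg0_state():
    return make_state_spec("measured_vg0")


@pytest.fixture(scope="session")
def rf_model(vg_model, rf_state):
    return apply_state(vg_model, rf_state)


@pytest.fixture(scope="session")
def respiratory_model(vg_model, respiratory_state):
    return apply_state(vg_model, respiratory_state)


@pytest.fixture(scope="session")
def rf_reference(rf_model):
    return build_reference(rf_model, make_state_spec("respiro_fermentative"))


@pytest.fixture(scope="session")
def respiratory_reference(respiratory_model):
    return build_reference(respiratory_model, make_state_spec("respiratory"))


@pytest.fixture(scope="session")
def vg0_model(vg_model, vg0_state):
    return apply_state(vg_model, vg0_state)


@pytest.fixture(scope="session")
def vg0_reference(vg0_model):
    return build_reference(vg0_model, make_state_spec("measured_vg0"))


def chain_model(throughput: tuple[float, float] = (0.0, 10.0)) -> StoichiometricModel:
    """Linear chain U -> A -> B -> X with export of X.

    All internal conversions carry identical flux at steady state, so
    throughput, ranges and turnovers have closed forms.
    """
    m = StoichiometricModel()
    m.metabolites = [
        Metabolite("u_e", is_external=True),
        Metabolite("a"),
        Metabolite("b"),
        Metabolite("x"),
        Metabolite("x_e", is_external=True),
    ]
    lo, hi = throughput
    m.reactions = [
        Reaction("uptake", {"u_e": -1, "a": 1}, lower_bound=0.0, upper_bound=10.0),
        Reaction("r_ab", {"a": -1, "b": 1}, lower_bound=0.0, upper_bound=10.0),
        Reaction("r_bx", {"b": -1, "x": 1}, lower_bound=0.0, upper_bound=10.0),
        Reaction("export", {"x": -1, "x_e": 1}, lower_bound=lo, upper_bound=hi),
    ]
    m.objective = {"export": 1.0}
    return m


def two_branch_model() -> StoichiometricModel:
    """A source of 10 split over parallel branches P and Q."""
    m = StoichiometricModel()
    m.metabolites = [
        Metabolite("s_e", is_external=True),
        Metabolite("mid"),
        Metabolite("p_e", is_external=True),
        Metabolite("q_e", is_external=True),
    ]
    m.reactions = [
        Reaction("source", {"s_e": -1, "mid": 1}, lower_bound=10.0, upper_bound=10.0),
        Reaction("P", {"mid": -1, "p_e": 1}, lower_bound=0.0, upper_bound=20.0),
        Reaction("Q", {"mid": -1, "q_e": 1}, lower_bound=0.0, upper_bound=20.0),
    ]
    m.objective = {"P": 1.0}
    return m
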