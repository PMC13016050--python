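"""Shared fixtures: program configurations used across the suite."""

import numpy as np
import pytest

from mihcost.config import (
    CostElement,
    ProgramConfig,
    SimulationSettings,
    VisitMix,
)
from mihcost.distributions import PertParams
from mihcost.synthetic import program_template


def point(value: float) -> PertParams:
    """A degenerate (point-mass) PERT triple."""
    return PertParams(value, value, value)


def make_config(elements, *, annual_visits=None, prop_basic=0.6,
                weight_basic=1.0, weight_advanced=1.0) -> ProgramConfig:
    """Assemble a config from CostElements with sensible defaults."""
    return ProgramConfig(
        elements=tuple(elements),
        visit_mix=VisitMix(
            annual_visits=annual_visits or point(800),
            prop_basic=prop_basic,
            prop_advanced=1.0 - prop_basic,
        ),
        simulation=SimulationSettings(),
        weight_basic=weight_basic,
        weight_advanced=weight_advanced,
    )


def element(eid, classification="variable", basis="per_visit",
            applicability="all", reimbursable=False, pert=None) -> CostElement:
    return CostElement(
        id=eid, label=eid, classification=classification, basis=basis,
        applicability=applicability, reimbursable=reimbursable,
        pert=pert if pert is not None else point(10.0),
    )


@pytest.fixture
def template():
    return program_template()


@pytest.fixture
def point_mass_config():
    """Fixed pool 100k, 800 visits (60/40), basic variable 50, advanced 200.

    Hand-computed per-visit costs: basic 100000/800 + 50 = 175,
    advanced 125 + 200 = 325.
    """
    return make_config(
        [
            element("fixed_pool", "fixed", "per_period", "all", pert=point(100_000)),
            element("basic_var", applicability="basic_only", pert=point(50.0)),
            element("advanced_var", applicability="advanced_only", pert=point(200.0)),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
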