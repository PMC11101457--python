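"""Shared fixtures: steady Poiseuille benchmark runs reused across files."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lbmuq.boundaries import ConstantInlet, SinusoidalPressure
from lbmuq.geometry import build_bifurcation, cylinder_spec
from lbmuq.lbm_core import UnitSystem
from lbmuq.reference_models import PoiseuilleModel
from lbmuq.solver import Simulation

settings.register_profile(
    "lbmuq", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("lbmuq")

U_INLET = 0.001  # m/s, creeping-flow benchmark velocity


@pytest.fixture(scope="session")
def units():
    return UnitSystem(dx=5e-5, dt=6e-5)


def _poiseuille_run(radius: int, length: int, steps: int, units: UnitSystem):
    dom = build_bifurcation(cylinder_spec(radius, length))
    sim = Simulation(dom, units, inlet=ConstantInlet(U_INLET),
                     outlets={1: SinusoidalPressure(0.0)})
    sim.run(steps)
    model = PoiseuilleModel(radius=radius * units.dx,
                            length=length * units.dx,
                            peak_velocity=U_INLET)
    return dom, sim, model


@pytest.fixture(scope="session")
def poiseuille10(units):
    """Radius-10 cylinder driven to steady state (the verification case)."""
    return _poiseuille_run(10, 40, 4000, units)


@pytest.fixture(scope="session")
def poiseuille5(units):
    """Half-resolution companion for the convergence comparison."""
    return _poiseuille_run(5, 20, 3000, units)


def profile_error(dom, sim, model, units):
    """Pointwise |u - analytic| / U on the mid-tube cross-section."""
    ch = dom.channels
    xmid = int(round(ch.x0 + ch.length / 2))
    sel = dom.fluid_idx[:, 0] == xmid
    pos = dom.fluid_idx[sel]
    r = np.sqrt((pos[:, 1] - ch.centre) ** 2 + (pos[:, 2] - ch.centre) ** 2)
    u = np.sqrt((sim.state.u[:, sel] ** 2).sum(axis=0)) * units.velocity_scale
    return np.abs(u - model.profile(r * units.dx)) / model.peak_velocity
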