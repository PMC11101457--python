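"""Time-stepping driver: collide + pull-stream + boundary closures.

One :meth:`Simulation.step` advances every fluid site exactly once:
BGK collision (in buffered, allocation-free arithmetic equivalent to
:func:`lbmuq.lbm_core.collide`), a single-gather pull streaming pass,
then the wall/inlet/outlet closures overwrite the slots whose streaming
source lies outside the fluid.  Divergence (density outside [0.1, 10] or
NaN) aborts with the offending step and site.
"""

from __future__ import annotations

import numpy as np

from . import boundaries as bnd
from .errors import SimulationDiverged
from .geometry import VoxelDomain
from .lbm_core import CS, Q, UnitSystem, W, _CF, _CFT, FlowState, relaxation_time

_RHO_MIN, _RHO_MAX = 0.1, 10.0


class Simulation:
    """A lattice Boltzmann run on one voxel domain.

    Parameters
    ----------
    domain
        Classified voxel lattice (see :mod:`lbmuq.geometry`).
    units
        Discretisation and fluid constants; fixes the relaxation time.
    inlet
        Object with ``value(t) -> peak velocity in m/s`` (or None).
    outlets
        Mapping outlet id -> object with ``value(t) -> pressure in mmHg``.
    """

    def __init__(self, domain: VoxelDomain, units: UnitSystem,
                 inlet=None, outlets=None):
        self.domain = domain
        self.units = units
        self.tau = relaxation_time(units)
        self.inlet = inlet
        self.outlets = dict(outlets or {})
        self.tables = bnd.compile_link_tables(domain)
        n = domain.n_fluid
        self.state = FlowState.at_rest(n)
        self._max_usq = 0.0
        # work buffers (flat views share memory with the 2D views)
        self._f = self.state.f
        self._fp = np.empty((Q, n))
        self._cu = np.empty((Q, n))
        self._usq = np.empty(n)

    @property
    def n_fluid(self) -> int:
        return self.domain.n_fluid

    @property
    def max_mach(self) -> float:
        """Largest lattice Mach number seen so far in this run."""
        return float(np.sqrt(self._max_usq)) / CS

    def _collide(self):
        """In-place BGK collision; refreshes the state's rho/u caches."""
        f = self._f
        st = self.state
        np.sum(f, axis=0, out=st.rho)
        rho = st.rho
        np.matmul(_CFT, f, out=st.u)
        u = st.u
        u /= rho
        cu = np.matmul(_CF, u, out=self._cu)
        usq = np.einsum("dn,dn->n", u, u, out=self._usq)
        fp = self._fp
        np.multiply(cu, cu, out=fp)
        fp *= 4.5
        cu *= 3.0
        fp += cu
        fp += 1.0
        fp -= 1.5 * usq
        fp *= W[:, None]
        fp *= rho
        # relax: f_post = (1 - 1/tau) f + (1/tau) feq   (f is consumed)
        omega = 1.0 / self.tau
        fp *= omega
        f *= 1.0 - omega
        fp += f

    def _check_divergence(self):
        rho = self.state.rho
        bad = ~np.isfinite(rho) | (rho < _RHO_MIN) | (rho > _RHO_MAX)
        if np.any(bad):
            site = int(np.argmax(bad))
            raise SimulationDiverged(self.state.step, site,
                                     f"rho={rho[site]:.4g}")

    def step(self):
        """Advance one time step."""
        t = self.state.step * self.units.dt
        self._collide()
        self._check_divergence()
        m = float(np.max(self._usq))
        if m > self._max_usq:
            self._max_usq = m
        fp_flat = self._fp.reshape(-1)
        f_flat = self._f.reshape(-1)
        np.take(fp_flat, self.tables.pull_src, out=f_flat)
        tb = self.tables
        if tb.bz_dst.size:
            bnd.apply_bouzidi_walls(f_flat, fp_flat, tb)
        if self.inlet is not None and tb.in_dst.size:
            u_lat = float(self.units.velocity_to_lattice(self.inlet.value(t)))
            bnd.apply_velocity_inlet(f_flat, fp_flat, self.state.rho, tb, u_lat)
        for o, program in self.outlets.items():
            if o in tb.outlets:
                rho_imp = float(self.units.pressure_to_density(program.value(t)))
                bnd.apply_pressure_outlet(f_flat, self.state.u,
                                          tb.outlets[o], rho_imp)
        self.state.step += 1

    def run(self, steps: int, sample_at=None, sampler=None):
        """Run ``steps`` updates; optionally call ``sampler(self, t)`` at steps.

        ``sample_at`` is an iterable of step indices (after which the
        sampler fires, with the state's moments refreshed).
        """
        sample_at = set(int(s) for s in (sample_at or ()))
        for _ in range(int(steps)):
            self.step()
            if self.state.step in sample_at and sampler is not None:
                self.state.refresh_moments()
                sampler(self, self.state.step * self.units.dt)
        self.state.refresh_moments()
        self._check_divergence()
        return self.state
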