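"""D3Q19 single-relaxation-time (BGK) lattice Boltzmann kernel.

The lattice Boltzmann method evolves a set of mesoscopic particle
populations ``f_i`` on a regular grid.  Each site carries 19 populations
(the D3Q19 velocity set: the rest vector, 6 nearest-neighbour and 12
next-nearest-neighbour vectors).  One update consists of a local BGK
collision, relaxing the populations toward a discrete Maxwellian
equilibrium at rate ``1/tau``, followed by streaming of each population
to the neighbour its lattice vector points at.  Macroscopic fields are
moments of the populations: density is the zeroth moment, momentum the
first, and pressure is ``Cs^2`` times density (an ideal equation of
state with lattice sound speed ``Cs = 1/sqrt(3)``).

This module owns the lattice constants, the equilibrium/moment algebra,
the collision operator and the unit system converting between lattice
and physical quantities (blood here is Newtonian: density 1000 kg/m^3,
dynamic viscosity 4 mPa.s).  Streaming schedules and boundary closures
live in :mod:`lbmuq.boundaries` / :mod:`lbmuq.solver`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import SimulationDiverged, StabilityError

log = logging.getLogger(__name__)

#: Squared lattice speed of sound.
CS2 = 1.0 / 3.0
#: Lattice speed of sound, 1/sqrt(3).
CS = CS2**0.5
#: Conversion factor between pascal and mmHg.
PA_PER_MMHG = 133.322387415

#: D3Q19 lattice vectors: rest, 6 nearest, 12 next-nearest neighbours.
C = np.array(
    [
        [0, 0, 0],
        [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
        [1, 1, 0], [-1, -1, 0], [1, -1, 0], [-1, 1, 0],
        [1, 0, 1], [-1, 0, -1], [1, 0, -1], [-1, 0, 1],
        [0, 1, 1], [0, -1, -1], [0, 1, -1], [0, -1, 1],
    ],
    dtype=np.int64,
)

#: Quadrature weights: 1/3 (rest), 1/18 (nearest), 1/36 (next-nearest).
W = np.array([1.0 / 3.0] + [1.0 / 18.0] * 6 + [1.0 / 36.0] * 12)

#: Index of the direction opposite to each lattice vector (an involution).
OPPOSITE = np.array(
    [int(np.flatnonzero((C == -c).all(axis=1))[0]) for c in C], dtype=np.int64
)

_CF = C.astype(float)          # (19, 3)
_CFT = _CF.T.copy()            # (3, 19)

Q = 19


@dataclass(frozen=True)
class LatticeModel:
    """The D3Q19 velocity set bundled as a value object.

    Provided mostly for introspection; the module-level constants are
    what the hot loops use.
    """

    c: np.ndarray = field(default_factory=lambda: C.copy())
    w: np.ndarray = field(default_factory=lambda: W.copy())
    cs2: float = CS2
    opposite: np.ndarray = field(default_factory=lambda: OPPOSITE.copy())


@dataclass(frozen=True)
class UnitSystem:
    """Physical <-> lattice unit conversion for one discretisation.

    Parameters
    ----------
    dx : float
        Grid spacing in metres.
    dt : float
        Time step in seconds.
    rho_phys : float
        Physical fluid density, kg/m^3 (blood: 1000).
    mu_phys : float
        Dynamic viscosity, Pa.s (blood: 4e-3, Newtonian).
    p_ref_mmhg : float
        Reference pressure assigned to lattice density 1.
    """

    dx: float
    dt: float
    rho_phys: float = 1000.0
    mu_phys: float = 4.0e-3
    p_ref_mmhg: float = 0.0

    def __post_init__(self):
        if self.dx <= 0 or self.dt <= 0:
            raise ValueError("dx and dt must be positive")

    @property
    def nu_phys(self) -> float:
        """Kinematic viscosity in m^2/s."""
        return self.mu_phys / self.rho_phys

    @property
    def velocity_scale(self) -> float:
        """Physical velocity of one lattice unit, dx/dt (m/s)."""
        return self.dx / self.dt

    @property
    def pressure_scale(self) -> float:
        """Physical pressure of one lattice pressure unit, rho*(dx/dt)^2 (Pa)."""
        return self.rho_phys * self.velocity_scale**2

    @property
    def tau(self) -> float:
        """BGK relaxation time: tau = 1/2 + nu*dt/(Cs^2 dx^2) (> 1/2)."""
        return 0.5 + self.nu_phys * self.dt / (CS2 * self.dx**2)

    @property
    def lattice_viscosity(self) -> float:
        """Kinematic viscosity in lattice units, Cs^2 (tau - 1/2)."""
        return CS2 * (self.tau - 0.5)

    def velocity_to_lattice(self, v):
        return np.asarray(v, dtype=float) * (self.dt / self.dx)

    def velocity_to_physical(self, v):
        return np.asarray(v, dtype=float) * (self.dx / self.dt)

    def pressure_to_density(self, p_mmhg):
        """Lattice density imposing a physical pressure (mmHg)."""
        p_pa = (np.asarray(p_mmhg, dtype=float) - self.p_ref_mmhg) * PA_PER_MMHG
        return 1.0 + p_pa / (CS2 * self.pressure_scale)

    def density_to_pressure_mmhg(self, rho):
        """Physical pressure (mmHg) of a lattice density."""
        p_pa = CS2 * (np.asarray(rho, dtype=float) - 1.0) * self.pressure_scale
        return p_pa / PA_PER_MMHG + self.p_ref_mmhg


def relaxation_time(units: UnitSystem) -> float:
    """Relaxation time for a unit system, with stability-band logging.

    tau <= 1/2 would mean negative viscosity; tau near 1/2 or well above
    ~3 degrades BGK accuracy/stability, so those bands are logged.
    """
    tau = units.tau
    if tau <= 0.5 + 1e-6:
        log.warning("relaxation time %.6f is at the lower stability limit", tau)
    elif tau >= 3.0:
        log.warning("relaxation time %.3f is large; accuracy will suffer", tau)
    return tau


def mach_number(u):
    """Lattice Mach number Ma = |u|/Cs = |u|*sqrt(3).

    Accepts a scalar speed, a 3-vector, or a (3, n) field; returns a
    scalar or per-site array accordingly.
    """
    u = np.asarray(u, dtype=float)
    if u.ndim == 0:
        return float(abs(u)) / CS
    if u.ndim == 1 and u.shape[0] == 3:
        return float(np.sqrt((u * u).sum())) / CS
    if u.ndim == 2 and u.shape[0] == 3:
        return np.sqrt((u * u).sum(axis=0)) / CS
    raise ValueError("expected a speed, a 3-vector or a (3, n) field")


def equilibrium(rho, u):
    """Second-order Maxwellian equilibrium populations.

    f_i^eq = w_i rho (1 + c.u/Cs^2 + (c.u)^2/(2 Cs^4) - |u|^2/(2 Cs^2)).

    Its zeroth moment is rho and its first moment rho*u exactly.
    ``rho`` may be scalar or (n,); ``u`` a 3-vector or (3, n).
    Raises :class:`StabilityError` when |u| reaches one lattice unit.
    """
    rho = np.asarray(rho, dtype=float)
    u = np.asarray(u, dtype=float)
    scalar = u.ndim == 1
    u2 = u.reshape(3, -1)
    rho2 = np.atleast_1d(rho).reshape(-1)
    usq = (u2 * u2).sum(axis=0)
    if usq.size and np.max(usq) >= 1.0:
        raise StabilityError(
            f"lattice speed {np.sqrt(np.max(usq)):.3f} >= 1; Mach limit exceeded"
        )
    cu = _CF @ u2
    f = W[:, None] * rho2 * (1.0 + 3.0 * cu + 4.5 * cu * cu - 1.5 * usq)
    return f[:, 0] if scalar else f


def moments(f):
    """Density and velocity moments of populations ``f`` (19,) or (19, n).

    rho = sum_i f_i ; u = sum_i f_i c_i / rho.
    """
    f = np.asarray(f, dtype=float)
    scalar = f.ndim == 1
    f2 = f.reshape(Q, -1)
    rho = f2.sum(axis=0)
    if np.any(rho <= 0.0):
        site = int(np.argmax(rho <= 0.0))
        raise SimulationDiverged(-1, site, "non-positive density in moments()")
    u = (_CFT @ f2) / rho
    if scalar:
        return float(rho[0]), u[:, 0]
    return rho, u


def collide(f, tau):
    """BGK collision: relax ``f`` toward its own equilibrium at rate 1/tau.

    Pure functional form used by tests and small scripts; the solver
    uses an in-place buffered variant of the same arithmetic.
    """
    rho, u = moments(f)
    feq = equilibrium(rho, u)
    return np.asarray(f, dtype=float) + (feq - f) / tau


def pressure_physical(rho, units: UnitSystem):
    """Physical pressure (mmHg) for lattice density: p = Cs^2 (rho - 1) scaled."""
    return units.density_to_pressure_mmhg(rho)


@dataclass
class FlowState:
    """Populations plus cached macroscopic fields over the fluid sites."""

    f: np.ndarray          # (19, n_fluid)
    rho: np.ndarray        # (n_fluid,)
    u: np.ndarray          # (3, n_fluid)
    step: int = 0

    @classmethod
    def at_rest(cls, n_fluid: int) -> "FlowState":
        """Stationary reference state: f = f_eq(rho=1, u=0) = w everywhere.

        Matches a domain initialised at constant reference pressure.
        """
        f = np.repeat(W[:, None], n_fluid, axis=1).copy()
        return cls(
            f=f,
            rho=np.ones(n_fluid),
            u=np.zeros((3, n_fluid)),
            step=0,
        )

    def refresh_moments(self):
        self.rho, self.u = moments(self.f)
        return self
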