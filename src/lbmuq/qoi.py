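"""Quantities of interest extracted from flow states.

Two QoI families are supported, matching how vascular CFD studies read
out results: pressure and velocity-magnitude profiles along a branch
centreline (indexed by the count of grid sites along the axis, flow
running left to right from index 0 at the inlet end), and mean/max
velocity time series over a one-site-thick cross-sectional plane.
Extraction is strictly read-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GeometryError
from .geometry import VoxelDomain
from .lbm_core import FlowState, UnitSystem, moments, pressure_physical


@dataclass
class AxisProfile:
    """Pressure (mmHg) and speed (m/s) per centreline site index."""

    branch: str
    index: np.ndarray
    pressure: np.ndarray
    speed: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"index": self.index, "pressure_mmhg": self.pressure,
             "speed_m_per_s": self.speed}
        )


@dataclass(frozen=True)
class PlaneSpec:
    """A one-site-thick cross-sectional slab: point + unit normal (lattice)."""

    point: tuple
    normal: tuple
    radius: float          # sites further than this from the point are excluded

    def __post_init__(self):
        n = np.linalg.norm(self.normal)
        if not np.isclose(n, 1.0, atol=1e-9):
            raise ValueError("plane normal must be a unit vector")


@dataclass
class PlaneSeries:
    """Mean and max speed (m/s) over a plane at sampled times (s)."""

    plane: PlaneSpec
    times: list = field(default_factory=list)
    mean_speed: list = field(default_factory=list)
    max_speed: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.times, "mean_speed_m_per_s": self.mean_speed,
             "max_speed_m_per_s": self.max_speed}
        )


def extract_axis_profile(state: FlowState, domain: VoxelDomain,
                         units: UnitSystem, branch: str = "main") -> AxisProfile:
    """Sample pressure and |u| at each centreline site of a branch.

    Returns an empty profile when the domain has no such branch.
    """
    sites = (domain.main_axis_sites if branch == "main"
             else domain.branch_axis_sites)
    if branch not in ("main", "branch"):
        raise ValueError(f"unknown branch label {branch!r}")
    if sites.size == 0:
        return AxisProfile(branch, np.empty(0, int), np.empty(0), np.empty(0))
    rho, u = moments(state.f[:, sites])
    speed = np.sqrt((u * u).sum(axis=0)) * units.velocity_scale
    return AxisProfile(
        branch=branch,
        index=np.arange(sites.size),
        pressure=np.asarray(pressure_physical(rho, units)),
        speed=speed,
    )


def plane_sites(domain: VoxelDomain, plane: PlaneSpec) -> np.ndarray:
    """Fluid slots inside the slab |(p - point).n| <= 1/2, within the radius."""
    p = domain.fluid_idx.astype(float) - np.asarray(plane.point, dtype=float)
    n = np.asarray(plane.normal, dtype=float)
    axial = p @ n
    r2 = (p * p).sum(axis=1) - axial * axial
    sel = (np.abs(axial) <= 0.5) & (r2 <= plane.radius**2)
    slots = np.flatnonzero(sel)
    if slots.size == 0:
        raise GeometryError("plane contains no fluid sites")
    return slots.astype(np.int64)


def extract_plane_speeds(state: FlowState, domain: VoxelDomain,
                         units: UnitSystem, plane: PlaneSpec):
    """(mean, max) of |u| in m/s over the plane's fluid sites."""
    slots = plane_sites(domain, plane)
    _, u = moments(state.f[:, slots])
    speed = np.sqrt((u * u).sum(axis=0)) * units.velocity_scale
    return float(speed.mean()), float(speed.max())


class PlaneRecorder:
    """Sampler collecting a PlaneSeries during a simulation run."""

    def __init__(self, domain: VoxelDomain, units: UnitSystem, plane: PlaneSpec):
        self.domain = domain
        self.units = units
        self.series = PlaneSeries(plane=plane)
        self._slots = plane_sites(domain, plane)

    def __call__(self, sim, t: float):
        u = sim.state.u[:, self._slots]
        speed = np.sqrt((u * u).sum(axis=0)) * self.units.velocity_scale
        self.series.times.append(float(t))
        self.series.mean_speed.append(float(speed.mean()))
        self.series.max_speed.append(float(speed.max()))
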