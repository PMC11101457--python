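"""Serialisation: HDF5 domain/flow containers and legacy-VTK image export."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .geometry import BifurcationSpec, VoxelDomain, build_bifurcation
from .lbm_core import FlowState, UnitSystem, pressure_physical


def save_domain(domain: VoxelDomain, path):
    """Write a voxel domain to an HDF5 hierarchical container.

    The defining spec is stored alongside the derived arrays so the
    domain can be reconstructed exactly on load.
    """
    with h5py.File(path, "w") as h5:
        if domain.spec is not None:
            g = h5.create_group("spec")
            g.attrs["radius"] = domain.spec.radius
            g.attrs["arm_length_factor"] = domain.spec.arm_length_factor
            g.attrs["branch_angle_deg"] = domain.spec.branch_angle_deg
            g.attrs["include_branch"] = domain.spec.include_branch
        h5.create_dataset("site_type", data=domain.site_type,
                          compression="gzip")
        wall = h5.create_group("wall_q")
        wall.create_dataset("site", data=domain.wall_site)
        wall.create_dataset("direction", data=domain.wall_dir)
        wall.create_dataset("q", data=domain.wall_q)
        reg = h5.create_group("registries")
        reg.create_dataset("inlet_sites", data=domain.inlet_sites)
        reg.create_dataset("inlet_weights", data=domain.inlet_weights)
        reg.create_dataset("main_axis_sites", data=domain.main_axis_sites)
        reg.create_dataset("branch_axis_sites", data=domain.branch_axis_sites)
        for o, slots in domain.outlet_sites.items():
            reg.create_dataset(f"outlet{o}_sites", data=slots)


def load_domain(path) -> VoxelDomain:
    """Rebuild a domain from its stored spec and verify the stored arrays."""
    with h5py.File(path, "r") as h5:
        if "spec" not in h5:
            raise ValueError("container has no geometry spec; cannot rebuild")
        a = h5["spec"].attrs
        spec = BifurcationSpec(
            radius=float(a["radius"]),
            arm_length_factor=float(a["arm_length_factor"]),
            branch_angle_deg=float(a["branch_angle_deg"]),
            include_branch=bool(a["include_branch"]),
        )
        site_type = h5["site_type"][...]
    domain = build_bifurcation(spec)
    if not np.array_equal(domain.site_type, site_type):
        raise ValueError("stored site classification does not match the spec")
    return domain


def write_vtk_image(path, shape, point_data: dict, spacing: float = 1.0):
    """Legacy-ASCII VTK structured-points file for quick inspection.

    ``point_data`` maps names to 3D scalar arrays (or (3,)+shape vector
    arrays) over the full lattice.
    """
    nx, ny, nz = shape
    n = nx * ny * nz
    lines = [
        "# vtk DataFile Version 3.0", "lbmuq image data", "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        "ORIGIN 0 0 0",
        f"SPACING {spacing} {spacing} {spacing}",
        f"POINT_DATA {n}",
    ]
    for name, arr in point_data.items():
        arr = np.asarray(arr)
        if arr.shape == tuple(shape):
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            flat = arr.transpose(2, 1, 0).reshape(-1)   # VTK is x-fastest
            lines.extend(" ".join(f"{v:.9g}" for v in row)
                         for row in np.array_split(flat, max(1, n // 9)))
        elif arr.shape == (3, *shape):
            lines.append(f"VECTORS {name} double")
            vec = arr.transpose(3, 2, 1, 0).reshape(-1, 3)
            lines.extend(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}" for v in vec)
        else:
            raise ValueError(f"field {name}: shape {arr.shape} does not "
                             f"match the lattice {shape}")
    Path(path).write_text("\n".join(lines) + "\n")


def export_flow(domain: VoxelDomain, state: FlowState, units: UnitSystem,
                h5_path=None, vtk_path=None):
    """Export pressure (mmHg) and velocity (m/s) fields of a flow state."""
    p = np.zeros(domain.shape)
    vel = np.zeros((3, *domain.shape))
    idx = domain.fluid_idx
    p[idx[:, 0], idx[:, 1], idx[:, 2]] = pressure_physical(state.rho, units)
    u_phys = state.u * units.velocity_scale
    for d in range(3):
        vel[d][idx[:, 0], idx[:, 1], idx[:, 2]] = u_phys[d]
    if h5_path is not None:
        with h5py.File(h5_path, "w") as h5:
            h5.attrs["step"] = state.step
            h5.attrs["dx"] = units.dx
            h5.attrs["dt"] = units.dt
            h5.create_dataset("pressure_mmhg", data=p, compression="gzip")
            h5.create_dataset("velocity_m_per_s", data=vel, compression="gzip")
    if vtk_path is not None:
        write_vtk_image(vtk_path, domain.shape,
                        {"pressure_mmhg": p, "velocity": vel},
                        spacing=units.dx)
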