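"""Stationary current conduction, electroosmotic coupling and Darcy flow.

The simulation follows three stages; this module covers the first two:

1. conduction: div(sigma_eff grad V) = 0 with the applied current injected
   over the source-lumen inlet and grounded at the dialysate outlet;
2. flow: the electroosmotic superficial velocity is slaved to the local
   current density (thin-double-layer Helmholtz-Smoluchowski, generalized
   to porous media by the alpha/lambda^2 factor, which cancels so that
   q_eo = eps*|zeta|/(mu*sigma_solution) * I_face), and a Darcy/Brinkman
   pressure field enforces incompressibility, the dialysate inflow, and the
   lumped Hagen-Poiseuille backpressure of the downstream capillaries.

Because EO flux is proportional to face current, the EO field is exactly
divergence-free inside uniform media; the pressure equation only corrects
zeta/conductivity mismatches (device/tissue interfaces) and the imposed
dialysate circuit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import fv
from .errors import ConfigurationError, SolverError
from .geometry import DeviceGeometry, Region, StructuredGrid
from .materials import MaterialProperties

WATER_DENSITY = 1000.0  # kg/m^3, for Reynolds checks
#: room-temperature water viscosity used for the bench-side capillaries
EXTERNAL_CAPILLARY_VISCOSITY = 0.00089  # Pa s


@dataclass(frozen=True)
class CurrentProgram:
    """Applied constant current, stepped on at t = 0.

    Positive current enters at the source and leaves at the dialysate
    outlet (conventional current); with the negative zeta potentials here
    this drives fluid from the source into the tissue.
    """
    applied_current: float  # A
    t_on: float = 0.0
    compliance: float = 100e-6  # A

    def __post_init__(self):
        if abs(self.applied_current) > self.compliance:
            raise ConfigurationError(
                f"|current| = {abs(self.applied_current):.3g} A exceeds the "
                f"configured compliance {self.compliance:.3g} A")


@dataclass(frozen=True)
class CapillaryNetwork:
    """Capillaries in series downstream of the probe outlet (length, i.d.)."""
    segments: tuple[tuple[float, float], ...]
    viscosity: float = EXTERNAL_CAPILLARY_VISCOSITY

    @classmethod
    def from_geometry(cls, geometry: DeviceGeometry,
                      viscosity: float = EXTERNAL_CAPILLARY_VISCOSITY):
        return cls(segments=tuple(geometry.lumped_capillary_network),
                   viscosity=viscosity)


class ReynoldsWarning(UserWarning):
    pass


def hagen_poiseuille_backpressure(network: CapillaryNetwork, flow: float) -> float:
    """Series pressure drop sum(128 mu L Q / (pi d^4)) of the lumped
    capillaries at volumetric flow ``flow`` (m^3/s)."""
    mu = network.viscosity
    dp = 0.0
    for length, diam in network.segments:
        if diam <= 0 or length <= 0:
            raise ConfigurationError("capillary length and diameter must be > 0")
        reynolds = 4.0 * WATER_DENSITY * abs(flow) / (math.pi * mu * diam)
        if reynolds > 100.0:
            warnings.warn(f"capillary Re = {reynolds:.0f} > 100; laminar "
                          "Hagen-Poiseuille assumption is marginal",
                          ReynoldsWarning, stacklevel=2)
        dp += 128.0 * mu * length * flow / (math.pi * diam**4)
    return dp


def darcy_velocity(pressure_drop: float, length: float, kappa: float,
                   mu: float) -> float:
    """Superficial Darcy velocity (kappa/mu) * dP/L for a uniform slab."""
    if length <= 0 or kappa <= 0 or mu <= 0:
        raise ConfigurationError("length, kappa and mu must be > 0")
    return kappa / mu * pressure_drop / length


# --- materials on the grid ----------------------------------------------

def region_materials(media: dict[str, MaterialProperties],
                     geometry: DeviceGeometry
                     ) -> dict[Region, MaterialProperties]:
    """Assign a medium to every grid region.

    Open channels receive an equivalent Brinkman permeability from their
    hydraulic width so that one Darcy formulation covers all regions.
    """
    chan = media["fluidic_channels"]
    d = geometry.conduit_inner_diameter
    return {
        Region.TISSUE: media["tissue"],
        Region.SOURCE_LUMEN: chan.with_overrides(
            permeability_kappa=d**2 / 32.0),
        Region.SINK_LUMEN: chan.with_overrides(
            permeability_kappa=d**2 / 32.0),
        Region.CHAMBER_FLUID: chan.with_overrides(
            permeability_kappa=(2 * geometry.channel_half_width)**2 / 12.0),
        Region.MEMBRANE: media["membrane"],
        Region.DIALYSATE_LUMEN: chan.with_overrides(
            permeability_kappa=geometry.dialysate_lumen_width**2 / 12.0),
    }


def _cell_property(grid: StructuredGrid,
                   matmap: dict[Region, MaterialProperties],
                   getter) -> np.ndarray:
    out = np.empty(grid.n_active)
    for region, mat in matmap.items():
        out[grid.cell_region == int(region)] = getter(mat)
    return out


# --- electric field ------------------------------------------------------

@dataclass
class PotentialField:
    grid: StructuredGrid
    V: np.ndarray                      # volts per active cell
    face_current: np.ndarray           # A per interior face, positive a->b
    boundary_current: dict             # name -> A per face, positive out
    balance_residual: float            # |sum of boundary currents| / I

    def potential_3d(self) -> np.ndarray:
        return self.grid.expand(self.V)


@dataclass
class ElectricField:
    grid: StructuredGrid
    face_E: np.ndarray       # V/m per interior face (along face normal, a->b)
    cell_E: np.ndarray       # (n_active, 3) reconstructed components

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.cell_E, axis=1)

    def mean_region_magnitude(self, region: Region) -> float:
        m = self.grid.cell_region == int(region)
        w = self.grid.cell_volume[m]
        return float((self.magnitude()[m] * w).sum() / w.sum())


def solve_electric_field(grid: StructuredGrid,
                         matmap: dict[Region, MaterialProperties],
                         current: CurrentProgram
                         ) -> tuple[PotentialField, ElectricField]:
    """Current conduction with insulating walls.

    Current is injected uniformly over the source-lumen inlet face and
    grounded (V = 0) at the dialysate outlet face; every other boundary is
    insulating. Conservation holds cell-by-cell to the direct-solver
    residual.
    """
    sigma = _cell_property(grid, matmap, lambda m: m.effective_conductivity)
    n = grid.n_active
    A, Tf = fv.assemble_diffusion(grid, sigma)
    out_bf = grid.named_faces["dialysate_outlet"]
    diag, rhs_d, Tb = fv.dirichlet_terms(out_bf, sigma, 0.0, n)
    A = A + diag
    b = rhs_d.copy()
    in_bf = grid.named_faces["source_inlet"]
    inj = current.applied_current * in_bf.area / in_bf.area.sum()
    np.add.at(b, in_bf.cells, inj)

    V = fv.direct_solve(A, b, what="current conduction")

    f = grid.faces
    face_I = Tf * (V[f["ia"]] - V[f["ib"]])
    boundary_I = {name: np.zeros(bf.cells.shape)
                  for name, bf in grid.named_faces.items()}
    boundary_I["source_inlet"] = -inj  # positive out of the domain
    boundary_I["dialysate_outlet"] = Tb * V[out_bf.cells]
    total_out = sum(q.sum() for q in boundary_I.values())
    scale = abs(current.applied_current) or 1.0
    residual = abs(total_out) / scale

    face_E = (V[f["ia"]] - V[f["ib"]]) / (f["da"] + f["db"])
    cell_E = _reconstruct_cell_vectors(grid, face_E, boundary_values=None)
    pot = PotentialField(grid=grid, V=V, face_current=face_I,
                         boundary_current=boundary_I, balance_residual=residual)
    return pot, ElectricField(grid=grid, face_E=face_E, cell_E=cell_E)


def _reconstruct_cell_vectors(grid: StructuredGrid, face_vals: np.ndarray,
                              boundary_values=None) -> np.ndarray:
    """Average face-normal scalars onto cell-centered vector components."""
    f = grid.faces
    n = grid.n_active
    comp = np.zeros((n, 3))
    count = np.zeros((n, 3))
    for ax in range(3):
        m = f["axis"] == ax
        np.add.at(comp[:, ax], f["ia"][m], face_vals[m])
        np.add.at(comp[:, ax], f["ib"][m], face_vals[m])
        np.add.at(count[:, ax], f["ia"][m], 1.0)
        np.add.at(count[:, ax], f["ib"][m], 1.0)
    count[count == 0] = 1.0
    return comp / count


# --- electroosmotic velocity --------------------------------------------

@dataclass
class VelocityField:
    """Signed volumetric face flows (m^3/s); positive a->b on interior
    faces, positive out of the domain on boundary faces."""
    grid: StructuredGrid
    q_interior: np.ndarray
    q_boundary: dict[str, np.ndarray]
    pressure: np.ndarray | None = None  # Pa per active cell (None for EO-only)
    mass_residual: float = 0.0

    def flow_through(self, surface: str) -> float:
        """Net volumetric flow out of the domain through a named surface."""
        return float(self.q_boundary[surface].sum())

    def superficial_face_velocity(self) -> np.ndarray:
        return self.q_interior / self.grid.faces["area"]

    def cell_velocity(self) -> np.ndarray:
        return _reconstruct_cell_vectors(
            self.grid, self.superficial_face_velocity())

    def scaled(self, factor: float) -> "VelocityField":
        return VelocityField(
            grid=self.grid, q_interior=self.q_interior * factor,
            q_boundary={k: v * factor for k, v in self.q_boundary.items()},
            pressure=None if self.pressure is None else self.pressure * factor,
            mass_residual=self.mass_residual)


def electroosmotic_velocity(grid: StructuredGrid,
                            matmap: dict[Region, MaterialProperties],
                            potential: PotentialField) -> VelocityField:
    """EO face flows slaved to the conservative face currents.

    q_eo = c * I_face with c = eps*(-zeta)/(mu*sigma_solution); c is
    averaged arithmetically across faces, so divergence appears only where
    zeta or conductivity changes (the mismatch the pressure field corrects).
    """
    c = _cell_property(
        grid, matmap,
        lambda m: m.permittivity * (-m.zeta_potential)
        / (m.viscosity * m.solution_conductivity))
    f = grid.faces
    c_face = 0.5 * (c[f["ia"]] + c[f["ib"]])
    q_int = c_face * potential.face_current
    q_bnd = {}
    for name, bf in grid.named_faces.items():
        q_bnd[name] = c[bf.cells] * potential.boundary_current[name]
    return VelocityField(grid=grid, q_interior=q_int, q_boundary=q_bnd)


# --- pressure-driven flow ------------------------------------------------

@dataclass
class PressureField:
    grid: StructuredGrid
    P: np.ndarray  # Pa per active cell
    backpressure: float  # Pa applied at the dialysate outlet

    def pressure_3d(self) -> np.ndarray:
        return self.grid.expand(self.P)


def solve_pressure_and_velocity(grid: StructuredGrid,
                                matmap: dict[Region, MaterialProperties],
                                v_eo: VelocityField,
                                capillary_network: CapillaryNetwork | None = None,
                                dialysate_inflow: float = 8.33e-12,
                                picard_iterations: int = 2
                                ) -> tuple[PressureField, VelocityField]:
    """Darcy/Brinkman pressure correction of the EO field.

    Boundary conditions: source reservoir and waste overflow at P = 0;
    prescribed dialysate inflow; dialysate outlet held at the
    Hagen-Poiseuille backpressure of the lumped downstream capillaries,
    evaluated at the instantaneous outlet flow (a short Picard loop).
    """
    c = _cell_property(grid, matmap,
                       lambda m: m.permeability_kappa / m.viscosity)
    n = grid.n_active
    A0, Tf = fv.assemble_diffusion(grid, c)

    # open-reservoir surfaces (P = 0), present surfaces only — fixtures may
    # lack the chamber circuit entirely
    zero_p = [name for name in ("source_inlet", "waste_outlet")
              if name in grid.named_faces]
    outlet = grid.named_faces.get("dialysate_outlet")
    inlet = grid.named_faces.get("dialysate_inlet")

    A = A0
    rhs_fixed = np.zeros(n)
    Tb_zero = {}
    for name in zero_p:
        bf = grid.named_faces[name]
        diag, r, Tb = fv.dirichlet_terms(bf, c, 0.0, n)
        A = A + diag
        rhs_fixed += r
        Tb_zero[name] = Tb
    Tb_out = np.zeros(0)
    if outlet is not None:
        _, _, Tb_out = fv.dirichlet_terms(outlet, c, 0.0, n)
        A = A + sp.coo_matrix((Tb_out, (outlet.cells, outlet.cells)),
                              shape=(n, n)).tocsr()
    if not zero_p and outlet is None:
        raise SolverError("pressure problem has no reference boundary")
    A = A.tocsc()

    eo_div = fv.scatter_face_divergence(
        grid, v_eo.q_interior,
        {name: (grid.named_faces[name], v_eo.q_boundary[name])
         for name in grid.named_faces})

    inflow_share = np.zeros(0)
    if inlet is not None:
        inflow_share = dialysate_inflow * inlet.area / inlet.area.sum()

    backpressure = 0.0
    q_out_nominal = dialysate_inflow
    P = np.zeros(n)
    for _ in range(max(1, picard_iterations)):
        if capillary_network is not None:
            backpressure = hagen_poiseuille_backpressure(
                capillary_network, q_out_nominal)
        b = -eo_div + rhs_fixed
        if inlet is not None:
            np.add.at(b, inlet.cells, inflow_share)
        if outlet is not None:
            np.add.at(b, outlet.cells, Tb_out * backpressure)
        P = fv.direct_solve(A, b, what="pressure")
        if outlet is not None:
            q_out_nominal = float(
                (Tb_out * (P[outlet.cells] - backpressure)
                 + v_eo.q_boundary["dialysate_outlet"]).sum())
        if capillary_network is None:
            break

    f = grid.faces
    q_int = v_eo.q_interior + Tf * (P[f["ia"]] - P[f["ib"]])
    q_bnd = dict(v_eo.q_boundary)
    for name in zero_p:
        bf = grid.named_faces[name]
        q_bnd[name] = q_bnd[name] + Tb_zero[name] * P[bf.cells]
    if outlet is not None:
        q_bnd["dialysate_outlet"] = (q_bnd["dialysate_outlet"]
                                     + Tb_out * (P[outlet.cells] - backpressure))
    if inlet is not None:
        q_bnd["dialysate_inlet"] = q_bnd["dialysate_inlet"] - inflow_share
    div = fv.scatter_face_divergence(
        grid, q_int, {name: (grid.named_faces[name], q_bnd[name])
                      for name in q_bnd})
    inflow_total = -sum(q[q < 0].sum() for q in q_bnd.values())
    residual = float(np.abs(div).max() / inflow_total) if inflow_total else 0.0
    if residual > 1e-6:
        raise SolverError(f"pressure solve left mass imbalance {residual:.2e}",
                          residual=residual)
    vel = VelocityField(grid=grid, q_interior=q_int, q_boundary=q_bnd,
                        pressure=P, mass_residual=residual)
    return PressureField(grid=grid, P=P, backpressure=backpressure), vel


def interface_pressures(grid: StructuredGrid, geometry: DeviceGeometry,
                        pressure: PressureField) -> tuple[float, float]:
    """Mean tissue pressure next to the source and sink orifices (the
    zeta-mismatch signature: positive at the source, negative at the sink)."""
    centers = grid.cell_centers()
    tissue = grid.cell_region == int(Region.TISSUE)
    r = 1.5 * geometry.conduit_outer_diameter
    zoff = geometry.source_sink_vertical_offset
    out = []
    for x0 in (geometry.x_source_orifice, geometry.x_sink_orifice):
        target = np.array([x0, 0.0, zoff])
        near = tissue & (np.linalg.norm(centers - target, axis=1) < r)
        if not near.any():
            raise SolverError("no tissue cells found near an orifice")
        out.append(float(pressure.P[near].mean()))
    return out[0], out[1]
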