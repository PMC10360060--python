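"""Time-dependent multi-species advection-diffusion-reaction transport.

Concentrations are tracked on a pore-fluid basis; porosity enters through
the accessible cell volume alpha*V and through alpha-weighted diffusive
face fluxes, so mass is conserved across porosity jumps
(channel/tissue/membrane). Advection uses first-order upwinding on the
divergence-free face flows from the flow solve; time integration is
implicit Euler (unconditionally stable, positivity-preserving), with a
tiered time step that is fine over the breakthrough front and coarse on
the slow approach to steady state.

First-order hydrolysis substrate -> product runs in TISSUE cells only
(ectopeptidases are tissue-bound). Solving the substrate implicitly first
and feeding k*C_S^(n+1) to the product step makes the pair exactly
superpose: with equal diffusion coefficients C_S + C_P reproduces the
unreactive substrate field to solver precision at every step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from . import fv
from .errors import AnalysisError, ConfigurationError, SolverError
from .fieldflow import VelocityField, _cell_property
from .geometry import ProbePointSet, Region, StructuredGrid
from .materials import (MaterialProperties, ReactionSpec, SpeciesSpec,
                        effective_diffusivity)


def _check_species_subset(species) -> None:
    """Subset runs may omit the internal standard but never duplicate names
    or carry more than one standard."""
    names = [s.name for s in species]
    if len(set(names)) != len(names):
        raise ConfigurationError("duplicate species names")
    if sum(1 for s in species if s.role == "internal_standard") > 1:
        raise ConfigurationError("at most one internal_standard per run")

#: default tiered time steps: (end time s, dt s); fine while the
#: breakthrough front passes, coarse on the slow tail
DEFAULT_DT_TIERS = ((120.0, 0.5), (600.0, 2.0), (float("inf"), 10.0))


@dataclass(frozen=True)
class TransportConfig:
    """Run duration, output cadence and implicit time-step schedule.

    ``tissue_farfield`` selects the outer tissue boundary: "absorbing"
    (default; the surrounding brain drains solute diffusively through an
    exterior shell of thickness ``farfield_shell`` before reaching the
    perfused-brain baseline C = 0 — a Robin condition emulating the
    unbounded exterior) or "no_flux" (sealed box). ``farfield_shell = 0``
    puts C = 0 directly on the box surface.
    """
    duration: float = 2400.0       # s (40 min reference window)
    output_interval: float = 30.0  # s
    dt_tiers: tuple = DEFAULT_DT_TIERS
    negative_tolerance: float = 1e-8  # fraction of the inlet concentration
    tissue_farfield: str = "absorbing"
    farfield_shell: float = 0.1e-3  # m; cortical perfusion clearance scale

    def __post_init__(self):
        if self.duration <= 0:
            raise ConfigurationError("duration must be > 0")
        if not (0 < self.output_interval <= self.duration):
            raise ConfigurationError("output interval must be in (0, duration]")
        if self.tissue_farfield not in ("absorbing", "no_flux"):
            raise ConfigurationError(
                "tissue_farfield must be 'absorbing' or 'no_flux'")
        prev = 0.0
        for t_end, dt in self.dt_tiers:
            if dt <= 0 or t_end <= prev:
                raise ConfigurationError("dt tiers must be increasing with dt > 0")
            n = round(self.output_interval / dt)
            if abs(n * dt - self.output_interval) > 1e-9 * self.output_interval:
                raise ConfigurationError(
                    f"dt {dt} must divide the output interval "
                    f"{self.output_interval}")
            prev = t_end

    def steps(self, duration: float):
        """Yield (t_new, dt) pairs covering [0, duration]."""
        t = 0.0
        for t_end, dt in self.dt_tiers:
            stop = min(t_end, duration)
            while t < stop - 1e-9:
                t = min(t + dt, stop)
                yield t, dt
            if t >= duration - 1e-9:
                return


@dataclass
class BreakthroughCurve:
    """Concentration versus time at a named probe point."""
    probe: str
    species: str
    times: np.ndarray       # s, strictly increasing
    concentrations: np.ndarray  # mol/m^3, pore-fluid basis

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.ndim != 1 or self.times.size != self.concentrations.size:
            raise ConfigurationError("times and concentrations must match")
        if np.any(np.diff(self.times) <= 0):
            raise ConfigurationError("times must be strictly increasing")
        if np.any(self.concentrations < -1e-12 * max(
                1.0, np.abs(self.concentrations).max() if self.concentrations.size else 1.0)):
            raise ConfigurationError("concentrations must be >= 0")


@dataclass
class MassBalance:
    inflow: float      # mol entering through inlets
    outflow: float     # mol leaving through outlets
    stored: float      # mol resident at the end
    reacted: float     # mol consumed (substrate) or produced (product)

    @property
    def residual(self) -> float:
        """|in - out - stored - consumed| relative to the dominant term;
        ``reacted`` is net moles consumed (negative for the product)."""
        scale = max(self.inflow, self.outflow + self.stored, 1e-300)
        return abs(self.inflow - self.outflow - self.stored - self.reacted) / scale


@dataclass
class TransportResult:
    times: np.ndarray
    curves: dict                  # (probe, species) -> np.ndarray
    mass_balance: dict            # species -> MassBalance
    final_fields: dict            # species -> active-cell concentrations
    species: list
    config: TransportConfig

    def curve(self, probe: str, species: str) -> BreakthroughCurve:
        return BreakthroughCurve(probe=probe, species=species,
                                 times=self.times,
                                 concentrations=self.curves[(probe, species)])


def _diffusion_coef(grid: StructuredGrid,
                    matmap: dict[Region, MaterialProperties],
                    spec: SpeciesSpec) -> np.ndarray:
    """alpha * D / lambda^2 per active cell (alpha-weighted pore diffusion)."""
    out = np.empty(grid.n_active)
    for region, mat in matmap.items():
        d_eff = effective_diffusivity(spec.diffusion_at(mat.temperature),
                                      mat.tortuosity_lambda)
        out[grid.cell_region == int(region)] = mat.porosity_alpha * d_eff
    return out


def _operators(grid: StructuredGrid,
               matmap: dict[Region, MaterialProperties],
               velocity: VelocityField,
               species: list[SpeciesSpec],
               reaction: ReactionSpec | None,
               reactive_region: Region = Region.TISSUE,
               tissue_farfield: str = "absorbing",
               farfield_shell: float = 0.1e-3):
    """Per-species steady operator A, rhs b, pore-volume vector, reaction
    diagonal, advective outflows and far-field transmissibilities."""
    bflows = {name: (grid.named_faces[name], velocity.q_boundary[name])
              for name in velocity.q_boundary}
    A_adv, outflows = fv.upwind_advection(grid, velocity.q_interior, bflows)

    alpha = _cell_property(grid, matmap, lambda m: m.porosity_alpha)
    pore_volume = alpha * grid.cell_volume

    react_diag = np.zeros(grid.n_active)
    if reaction is not None and reaction.rate_constant_k > 0:
        mask = grid.cell_region == int(reactive_region)
        react_diag[mask] = reaction.rate_constant_k * pore_volume[mask]
    K = sp.diags(react_diag).tocsr()

    farfield_names = [n for n in grid.named_faces
                      if n.startswith("tissue_farfield")
                      and grid.named_faces[n].cells.size
                      and tissue_farfield == "absorbing"]

    ops = {}
    farfield = {}
    n = grid.n_active
    for spec in species:
        coef = _diffusion_coef(grid, matmap, spec)
        A_diff, _ = fv.assemble_diffusion(grid, coef)
        b = np.zeros(n)
        bf = grid.named_faces["source_inlet"]
        q_in = np.maximum(-velocity.q_boundary["source_inlet"], 0.0)
        np.add.at(b, bf.cells, q_in * spec.infused_concentration)
        # dialysate inlet carries clean perfusate (C = 0): no rhs term
        A = (A_adv + A_diff).tocsr()
        ff = []
        for name in farfield_names:
            bfx = grid.named_faces[name]
            cc = coef[bfx.cells]
            # series resistance: half cell + exterior shell of tissue
            Tb = np.where(cc > 0,
                          bfx.area * cc / (bfx.dist + farfield_shell), 0.0)
            diag = sp.coo_matrix((Tb, (bfx.cells, bfx.cells)),
                                 shape=(n, n)).tocsr()
            A = A + diag
            ff.append((bfx.cells, Tb))
        farfield[spec.name] = ff
        if reaction is not None and spec.name == reaction.substrate:
            A = A + K
        ops[spec.name] = (A, b)
    return ops, K, pore_volume, outflows, farfield


def solve_transport(grid: StructuredGrid,
                    matmap: dict[Region, MaterialProperties],
                    velocity: VelocityField,
                    species: list[SpeciesSpec],
                    reaction: ReactionSpec | None,
                    config: TransportConfig,
                    probes: ProbePointSet | None = None,
                    reactive_region: Region = Region.TISSUE) -> TransportResult:
    """Step the coupled species from a clean device to ``config.duration``.

    The inlet is an ideal step to the infused concentration at t = 0 on the
    source lumen. Breakthrough curves are recorded every output interval at
    each probe point; the MD_OUTLET entry is the flow-weighted mean over
    the dialysate outlet faces.
    """
    _check_species_subset(species)
    if reaction is not None and reaction.rate_constant_k > 0:
        names = {s.name for s in species}
        if reaction.substrate not in names:
            raise ConfigurationError("reaction substrate not among species")
    ops, K, pore_volume, outflows, farfield = _operators(
        grid, matmap, velocity, species, reaction, reactive_region,
        config.tissue_farfield, config.farfield_shell)

    order = sorted(species, key=lambda s: 0 if reaction is None
                   or s.name == reaction.substrate else 1)
    conc = {s.name: np.zeros(grid.n_active) for s in species}
    inflow = {s.name: 0.0 for s in species}
    outflow = {s.name: 0.0 for s in species}
    consumed = {s.name: 0.0 for s in species}

    out_times = [0.0]
    curves = {}
    probe_names = []
    if probes is not None:
        for p in probes:
            probe_names.append(p.name)
            for s in species:
                curves[(p.name, s.name)] = [0.0]

    out_bf = grid.named_faces["dialysate_outlet"]
    q_md = np.maximum(velocity.q_boundary["dialysate_outlet"], 0.0)

    def record(t):
        out_times.append(t)
        for p in probes:
            for s in species:
                if p.name == "MD_OUTLET" and q_md.sum() > 0:
                    val = float((q_md * conc[s.name][out_bf.cells]).sum()
                                / q_md.sum())
                else:
                    val = float(conc[s.name][p.cell])
                curves[(p.name, s.name)].append(val)

    lus = {}
    current_dt = None
    next_output = config.output_interval
    c_in_max = max((s.infused_concentration for s in species), default=1.0)
    for t, dt in config.steps(config.duration):
        if dt != current_dt:
            lus = {}
            for s in species:
                A, _ = ops[s.name]
                M = sp.diags(pore_volume / dt)
                lus[s.name] = splu((M + A).tocsc())
            current_dt = dt
        substrate_new = None
        for s in order:
            A, b = ops[s.name]
            rhs = pore_volume / dt * conc[s.name] + b
            if (reaction is not None and s.name == reaction.product
                    and substrate_new is not None):
                rhs = rhs + K @ substrate_new
            c_new = lus[s.name].solve(rhs)
            if c_new.min() < -config.negative_tolerance * max(c_in_max, 1e-300):
                raise SolverError(
                    f"negative concentration {c_new.min():.3e} for {s.name} "
                    f"at t = {t:.1f} s; refine dt or the grid")
            np.clip(c_new, 0.0, None, out=c_new)
            if reaction is not None and s.name == reaction.substrate:
                substrate_new = c_new
                consumed[s.name] += float((K @ c_new).sum()) * dt
            if (reaction is not None and s.name == reaction.product
                    and substrate_new is not None):
                consumed[s.name] -= float((K @ substrate_new).sum()) * dt
            inflow[s.name] += float(b.sum()) * dt
            out_total = 0.0
            for name, q_out in outflows.items():
                cells = grid.named_faces[name].cells
                out_total += float((q_out * c_new[cells]).sum())
            for cells, Tb in farfield[s.name]:
                out_total += float((Tb * c_new[cells]).sum())
            outflow[s.name] += out_total * dt
            conc[s.name] = c_new
        if probes is not None and t >= next_output - 1e-9:
            record(t)
            next_output += config.output_interval

    balances = {}
    for s in species:
        stored = float((pore_volume * conc[s.name]).sum())
        balances[s.name] = MassBalance(inflow=inflow[s.name],
                                       outflow=outflow[s.name],
                                       stored=stored,
                                       reacted=consumed[s.name])
    return TransportResult(
        times=np.asarray(out_times),
        curves={k: np.asarray(v) for k, v in curves.items()},
        mass_balance=balances,
        final_fields=conc,
        species=list(species),
        config=config)


def solve_transport_steady(grid: StructuredGrid,
                           matmap: dict[Region, MaterialProperties],
                           velocity: VelocityField,
                           species: list[SpeciesSpec],
                           reaction: ReactionSpec | None,
                           probes: ProbePointSet | None = None,
                           reactive_region: Region = Region.TISSUE,
                           tissue_farfield: str = "absorbing",
                           farfield_shell: float = 0.1e-3) -> dict:
    """Steady-state concentrations (the t -> infinity limit of the step
    response); used for calibration sweeps over the rate constant.

    Returns {"fields": {species: conc}, "probe": {(probe, species): value}}.
    """
    _check_species_subset(species)
    ops, K, _, _, _ = _operators(grid, matmap, velocity, species, reaction,
                                 reactive_region, tissue_farfield,
                                 farfield_shell)
    order = sorted(species, key=lambda s: 0 if reaction is None
                   or s.name == reaction.substrate else 1)
    conc = {}
    substrate = None
    for s in order:
        A, b = ops[s.name]
        rhs = b.copy()
        if reaction is not None and s.name == reaction.product:
            rhs = rhs + K @ substrate
        c = fv.direct_solve(A.tocsc(), rhs, what=f"steady transport {s.name}")
        np.clip(c, 0.0, None, out=c)
        if reaction is not None and s.name == reaction.substrate:
            substrate = c
        conc[s.name] = c

    out = {"fields": conc, "probe": {}}
    if probes is not None:
        out_bf = grid.named_faces["dialysate_outlet"]
        q_md = np.maximum(velocity.q_boundary["dialysate_outlet"], 0.0)
        for p in probes:
            for s in species:
                if p.name == "MD_OUTLET" and q_md.sum() > 0:
                    val = float((q_md * conc[s.name][out_bf.cells]).sum()
                                / q_md.sum())
                else:
                    val = float(conc[s.name][p.cell])
                out["probe"][(p.name, s.name)] = val
    return out


def steady_state_fraction(curve: BreakthroughCurve, t_ref: float) -> np.ndarray:
    """Curve normalized by its value at the reference time (95%-of-40-min
    convention); undefined (error) when the reference value is zero."""
    if curve.times[-1] < t_ref - 1e-9:
        raise AnalysisError(f"curve ends at {curve.times[-1]:.0f} s, before "
                            f"t_ref = {t_ref:.0f} s")
    c_ref = float(np.interp(t_ref, curve.times, curve.concentrations))
    if c_ref <= 0.0:
        raise AnalysisError("reference concentration is zero; fraction undefined")
    return curve.concentrations / c_ref
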