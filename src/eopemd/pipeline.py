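"""High-level orchestration: build the device model, run the three solver
stages, and derive the summary readouts.

`DeviceModel` wires geometry, grid, materials, probes and the lumped
capillary network together and caches the (k-independent) field/flow
solution per applied current, so rate-constant sweeps pay for the flow
problem once.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import io as _io
from .config import RunConfig, dump_config
from .errors import ConfigurationError
from .fieldflow import (CapillaryNetwork, CurrentProgram, ElectricField,
                        PotentialField, PressureField, VelocityField,
                        electroosmotic_velocity, region_materials,
                        solve_electric_field, solve_pressure_and_velocity)
from .geometry import (DeviceGeometry, ProbePointSet, Region, StructuredGrid,
                       build_default_geometry, discretize, probe_points)
from .materials import (ReactionSpec, SpeciesSpec, load_default_parameters,
                        effective_diffusivity)
from .readouts import (CalibrationSweep, recovery_ratio,
                       sweep_rate_constants, DEFAULT_REFERENCE_TIME)
from .transport import (TransportConfig, TransportResult, solve_transport,
                        solve_transport_steady)


@dataclass
class FieldSolution:
    current: float
    potential: PotentialField
    efield: ElectricField
    pressure: PressureField
    velocity: VelocityField


class DeviceModel:
    """The assembled EOP-EMD simulation for one configuration."""

    def __init__(self, config: RunConfig | None = None):
        self.config = config or RunConfig()
        self.geometry: DeviceGeometry = build_default_geometry(
            **self.config.geometry)
        self.grid: StructuredGrid = discretize(self.geometry,
                                               self.config.resolution)
        self.media, species = load_default_parameters(
            self.config.temperature_context)
        for medium, overrides in self.config.materials.items():
            # MaterialProperties re-validates its invariants here, so an
            # out-of-range override fails naming the offending field
            self.media[medium] = self.media[medium].with_overrides(**overrides)
        c_in = self.config.infused_concentration
        self.species = [
            replace(s, infused_concentration=c_in)
            if s.infused_concentration > 0 else s for s in species]
        self.matmap = region_materials(self.media, self.geometry)
        self.probes: ProbePointSet = probe_points(self.grid, self.geometry)
        self.capnet = CapillaryNetwork.from_geometry(self.geometry)
        self.reaction = ReactionSpec(
            substrate=self.config.reaction.substrate,
            product=self.config.reaction.product,
            rate_constant_k=self.config.rate_constant())
        self._field_cache: dict[float, FieldSolution] = {}
        self._steady_cache: dict[tuple, tuple[float, float]] = {}

    # -- fields ----------------------------------------------------------
    def solve_fields(self, current: float | None = None) -> FieldSolution:
        i_app = self.config.current if current is None else float(current)
        if i_app not in self._field_cache:
            program = CurrentProgram(applied_current=i_app)
            pot, ef = solve_electric_field(self.grid, self.matmap, program)
            v_eo = electroosmotic_velocity(self.grid, self.matmap, pot)
            pres, vel = solve_pressure_and_velocity(
                self.grid, self.matmap, v_eo, self.capnet,
                dialysate_inflow=self.config.dialysate_inflow)
            self._field_cache[i_app] = FieldSolution(
                current=i_app, potential=pot, efield=ef, pressure=pres,
                velocity=vel)
        return self._field_cache[i_app]

    # -- transport -------------------------------------------------------
    def species_subset(self, names=None) -> list[SpeciesSpec]:
        if names is None:
            return list(self.species)
        by_name = {s.name: s for s in self.species}
        try:
            return [by_name[n] for n in names]
        except KeyError as exc:
            raise ConfigurationError(f"unknown species {exc}") from None

    def transport_config(self, duration: float | None = None) -> TransportConfig:
        return TransportConfig(
            duration=self.config.duration if duration is None else duration,
            output_interval=self.config.output_interval,
            tissue_farfield=self.config.tissue_farfield,
            farfield_shell=self.config.farfield_shell)

    def run_transport(self, current: float | None = None,
                      k: float | None = None, species_names=None,
                      duration: float | None = None) -> TransportResult:
        fields = self.solve_fields(current)
        reaction = self.reaction if k is None else replace(
            self.reaction, rate_constant_k=float(k))
        return solve_transport(
            self.grid, self.matmap, fields.velocity,
            self.species_subset(species_names), reaction,
            self.transport_config(duration), probes=self.probes)

    def steady_ratios(self, current: float | None = None,
                      k: float | None = None,
                      probe: str = "MD_OUTLET") -> tuple[float, float]:
        """Steady (S/IS, P/IS) at a probe for one rate constant (cached:
        sweeps and closed-loop tests revisit the same operating points)."""
        fields = self.solve_fields(current)
        reaction = self.reaction if k is None else replace(
            self.reaction, rate_constant_k=float(k))
        key = (fields.current, reaction.rate_constant_k, probe)
        if key in self._steady_cache:
            return self._steady_cache[key]
        res = solve_transport_steady(
            self.grid, self.matmap, fields.velocity, self.species,
            reaction, probes=self.probes,
            tissue_farfield=self.config.tissue_farfield,
            farfield_shell=self.config.farfield_shell)
        c_is = res["probe"][(probe, "yaGfl")]
        if c_is <= 0:
            raise ConfigurationError("internal standard absent at the probe")
        out = (res["probe"][(probe, self.reaction.substrate)] / c_is,
               res["probe"][(probe, self.reaction.product)] / c_is)
        self._steady_cache[key] = out
        return out

    def calibration_sweep(self, k_grid, current: float | None = None,
                          probe: str = "MD_OUTLET") -> CalibrationSweep:
        i_app = self.config.current if current is None else float(current)
        self.solve_fields(i_app)  # pay for the flow solve once
        return sweep_rate_constants(
            lambda k: self.steady_ratios(i_app, k, probe),
            k_grid, current=i_app, probe=probe)

    def synthesize_measurements(self, true_k: float, cv: float, n: int,
                                seed: int, current: float | None = None
                                ) -> dict:
        """Noisy replicate steady ratios at a true rate constant
        (multiplicative lognormal noise with the stated CV)."""
        from .fixtures import lognormal_replicates
        s_is, p_is = self.steady_ratios(current, true_k)
        rng = np.random.default_rng(seed)
        return {"s_over_is": lognormal_replicates(s_is, cv, n, rng),
                "p_over_is": lognormal_replicates(p_is, cv, n, rng),
                "true_k": true_k}


# --- full run with outputs ----------------------------------------------

@dataclass
class SimulationRun:
    model: DeviceModel
    fields: FieldSolution
    result: TransportResult
    summary: dict
    output_dir: Path | None = None


def summarize(model: DeviceModel, fields: FieldSolution,
              result: TransportResult) -> dict:
    """Headline numbers of one run: solver balances, flows, residence-time
    stats of the internal standard, and recovery ratios."""
    vel = fields.velocity
    tissue_mat = model.matmap[Region.TISSUE]
    summary = {
        "current_A": fields.current,
        "rate_constant_per_s": model.reaction.rate_constant_k,
        "n_active_cells": model.grid.n_active,
        "current_balance_residual": fields.potential.balance_residual,
        "mass_balance_residual": vel.mass_residual,
        "backpressure_Pa": fields.pressure.backpressure,
        "source_inflow_m3_s": -vel.flow_through("source_inlet"),
        "dialysate_outflow_m3_s": vel.flow_through("dialysate_outlet"),
        "waste_outflow_m3_s": vel.flow_through("waste_outlet"),
        "mean_source_lumen_field_V_m":
            fields.efield.mean_region_magnitude(Region.SOURCE_LUMEN),
    }
    t_ref = min(DEFAULT_REFERENCE_TIME, result.times[-1]) if result.times.size \
        else None
    is_species = next((s for s in result.species
                       if s.role == "internal_standard"), None)
    if is_species is not None and ("SINK_ORIFICE", is_species.name) in result.curves:
        d_eff = effective_diffusivity(
            is_species.diffusion_at(tissue_mat.temperature),
            tissue_mat.tortuosity_lambda)
        try:
            from .readouts import peclet_number, transit_first_moment
            m1 = transit_first_moment(
                result.curve("SOURCE_ORIFICE", is_species.name),
                result.curve("SINK_ORIFICE", is_species.name))
            summary["m1_source_to_sink_s"] = m1
            summary["peclet"] = peclet_number(
                m1, model.geometry.source_sink_orifice_separation, d_eff)
        except Exception as exc:  # pragma: no cover - diagnostic path
            summary["m1_error"] = str(exc)
    for s in result.species:
        key = ("MD_OUTLET", s.name)
        if key in result.curves and s.infused_concentration > 0:
            curve = result.curve(*key)
            summary[f"recovery_{s.name}"] = recovery_ratio(
                curve, s.infused_concentration)
            from .readouts import time_to_fraction
            try:
                summary[f"t95_md_outlet_{s.name}_s"] = time_to_fraction(
                    curve, 0.95, t_ref)
            except Exception as exc:
                summary[f"t95_error_{s.name}"] = str(exc)
    for name, bal in result.mass_balance.items():
        summary[f"species_balance_residual_{name}"] = bal.residual
    return summary


def run_simulation(config: RunConfig, output_dir: str | Path | None = None,
                   species_names=None) -> SimulationRun:
    """Execute the three solver stages for one configuration and, when an
    output directory is given, write the config snapshot, summary CSV,
    per-probe curve CSVs and VTK field snapshots."""
    t0 = time.perf_counter()
    model = DeviceModel(config)
    fields = model.solve_fields()
    result = model.run_transport(species_names=species_names)
    summary = summarize(model, fields, result)
    wall_time = time.perf_counter() - t0

    out = Path(output_dir) if output_dir else (
        Path(config.output_dir) if config.output_dir else None)
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        dump_config(config, out / "config_snapshot.yaml")
        _io.write_summary_csv(out / "summary.csv", summary)
        (out / "curves").mkdir(exist_ok=True)
        for probe in model.probes:
            _io.write_curves_csv(out / "curves" / f"{probe.name}.csv",
                                 result, probe.name)
        (out / "fields").mkdir(exist_ok=True)
        _io.write_fields_vtr(out / "fields" / "final.vtr", model.grid,
                             fields, result)
        with open(out / "log.json", "w") as fh:
            json.dump({**summary, "wall_time_s": wall_time}, fh,
                      indent=2, default=float)
    return SimulationRun(model=model, fields=fields, result=result,
                         summary=summary, output_dir=out)
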