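"""Analytic test problems and synthetic noisy measurements.

Each fixture builds a small grid plus materials for which the governing
equations have closed-form solutions, and records those expectations with
tolerances at generation time:

* ``slab_conduction``: two conductive slabs in series — field ratio
  E2/E1 = sigma1/sigma2;
* ``channel_eo``: uniform channel carrying current — EO flow per current
  Q/I = eps*|zeta|/(mu*sigma), independent of cross section;
* ``breakthrough_1d``: step input into a uniform-velocity channel — the
  advection-diffusion step response in a semi-infinite domain;
* ``plug_flow_decay``: first-order decay over a fixed transit time —
  survival exp(-k*tau).

`lognormal_replicates` generates the multiplicative measurement noise used
by the closed-loop rate-inference tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erfc, erfcx

from .errors import ConfigurationError
from .fieldflow import CurrentProgram
from .geometry import (BoundaryFaces, ProbePoint, ProbePointSet, Region,
                       StructuredGrid)
from .materials import default_material


@dataclass
class FixtureCase:
    """A generated problem with analytically known outputs."""
    name: str
    description: str
    grid: StructuredGrid | None
    matmap: dict | None
    current: CurrentProgram | None
    expected: dict          # name -> (value, relative tolerance)
    extras: dict = field(default_factory=dict)


def channel_grid(length: float = 1.0e-3, width: float = 100e-6,
                 n_axial: int = 50, resolution: int = 1,
                 split_label: tuple | None = None) -> StructuredGrid:
    """A straight square channel along x with inlet and outlet tagged as
    ``source_inlet`` / ``dialysate_outlet`` so the device solvers apply
    unchanged. ``split_label=(regA, regB)`` labels the two halves
    differently (series-slab problems)."""
    n = n_axial * resolution
    xf = np.linspace(0.0, length, n + 1)
    yf = np.array([0.0, width])
    zf = np.array([0.0, width])
    label = np.full((n, 1, 1), int(Region.SOURCE_LUMEN), dtype=np.int8)
    if split_label is not None:
        half = n // 2
        label[:half] = int(split_label[0])
        label[half:] = int(split_label[1])
    grid = StructuredGrid(xf=xf, yf=yf, zf=zf, label=label)
    area = np.array([width * width])
    grid.named_faces["source_inlet"] = BoundaryFaces(
        cells=np.array([grid.index[0, 0, 0]]), axis=0, side=-1,
        area=area.copy(), dist=np.array([0.5 * grid.dx[0]]))
    grid.named_faces["dialysate_outlet"] = BoundaryFaces(
        cells=np.array([grid.index[n - 1, 0, 0]]), axis=0, side=+1,
        area=area.copy(), dist=np.array([0.5 * grid.dx[-1]]))
    return grid


def channel_probe(grid: StructuredGrid, x_probe: float,
                  name: str = "PROBE") -> ProbePointSet:
    i = int(np.argmin(np.abs(grid.xc - x_probe)))
    cell = int(grid.index[i, 0, 0])
    region = Region(grid.label[i, 0, 0])
    return ProbePointSet(points={name: ProbePoint(
        name=name, region=region, cell=cell,
        position=(float(grid.xc[i]), float(grid.yc[0]), float(grid.zc[0])))})


def advection_diffusion_step(x: float, t: np.ndarray, v: float, D: float,
                             c0: float = 1.0) -> np.ndarray:
    """Step response of 1D advection-diffusion in a semi-infinite channel
    with a flux (Danckwerts) inlet, v*C0 = v*C - D dC/dx at x = 0 — the
    condition a conservative finite-volume advective inlet realizes. The
    resident concentration is (van Genuchten & Alves closed form)

        C/C0 = 1/2 erfc(a1) + sqrt(v^2 t/(pi D)) exp(-a1^2)
               - 1/2 (1 + vx/D + v^2 t/D) exp(vx/D) erfc(a2)

    with a1 = (x-vt)/sqrt(4Dt), a2 = (x+vt)/sqrt(4Dt); the last term is
    evaluated overflow-safely via erfcx (exp(vx/D) erfc(a2) =
    erfcx(a2) exp(-a1^2))."""
    t = np.asarray(t, float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    s = np.sqrt(4.0 * D * tp)
    a1 = (x - v * tp) / s
    a2 = (x + v * tp) / s
    g = np.exp(-a1**2)
    out[pos] = (0.5 * erfc(a1)
                + np.sqrt(v * v * tp / (np.pi * D)) * g
                - 0.5 * (1.0 + v * x / D + v * v * tp / D) * erfcx(a2) * g)
    return c0 * out


FIXTURE_NAMES = ("slab_conduction", "channel_eo", "breakthrough_1d",
                 "plug_flow_decay")


def make_fixture(name: str, resolution: int = 1, **overrides) -> FixtureCase:
    """Build one named analytic fixture (see module docstring)."""
    if name == "slab_conduction":
        sigma1, sigma2 = overrides.get("sigmas", (1.80, 0.30))
        grid = channel_grid(resolution=resolution,
                            split_label=(Region.SOURCE_LUMEN,
                                         Region.SINK_LUMEN))
        base = default_material("fluidic_channels", 37.0)
        matmap = {
            Region.SOURCE_LUMEN: base.with_overrides(
                medium_name="slab_1", solution_conductivity=sigma1),
            Region.SINK_LUMEN: base.with_overrides(
                medium_name="slab_2", solution_conductivity=sigma2),
        }
        return FixtureCase(
            name=name, grid=grid, matmap=matmap,
            current=CurrentProgram(applied_current=10e-6),
            description="two equal-length conductive slabs in series",
            expected={"field_ratio_E2_over_E1": (sigma1 / sigma2, 1e-10)})

    if name == "channel_eo":
        mat = overrides.get("material",
                            default_material("fluidic_channels", 37.0)
                            .with_overrides(medium_name="tissue_solution",
                                            zeta_potential=-0.0228))
        grid = channel_grid(resolution=resolution)
        q_per_i = mat.permittivity * (-mat.zeta_potential) / (
            mat.viscosity * mat.solution_conductivity)
        nl_min_per_ua = q_per_i * 1e-6 * 1e12 * 60.0
        return FixtureCase(
            name=name, grid=grid, matmap={Region.SOURCE_LUMEN: mat},
            current=CurrentProgram(applied_current=1e-6),
            description="uniform channel: EO flow per unit current, "
                        "independent of cross section",
            expected={"q_per_current_m3_per_C": (q_per_i, 1e-10),
                      "nl_min_per_ua": (nl_min_per_ua, 1e-10)})

    if name == "breakthrough_1d":
        mat = default_material("fluidic_channels", 37.0)
        length = overrides.get("length", 1.0e-3)
        width = overrides.get("width", 100e-6)
        v = overrides.get("velocity", 3.0e-6)      # m/s
        D = overrides.get("diffusivity", 5.4e-10)  # m^2/s
        grid = channel_grid(length=length, width=width, n_axial=100,
                            resolution=resolution)
        c_coef = mat.permittivity * (-mat.zeta_potential) / (
            mat.viscosity * mat.solution_conductivity)
        current = v * width * width / c_coef  # current that drives v
        x_probe = 0.6 * length
        return FixtureCase(
            name=name, grid=grid, matmap={Region.SOURCE_LUMEN: mat},
            current=CurrentProgram(applied_current=current),
            description="step input into a uniform-velocity channel",
            expected={"velocity_m_s": (v, 1e-6)},
            extras={"x_probe": x_probe, "velocity": v, "diffusivity": D,
                    "analytic": lambda t: advection_diffusion_step(
                        x_probe, t, v, D)})

    if name == "plug_flow_decay":
        k = overrides.get("rate_constant", 0.005)
        tau = overrides.get("transit_time", 84.0)
        sigma = tau / 50.0
        t = np.linspace(0.0, tau + 10 * sigma, 4001)
        f = np.exp(-0.5 * ((t - tau) / sigma) ** 2)
        f /= np.trapezoid(f, t)
        survival = math.exp(-k * tau)
        return FixtureCase(
            name=name, grid=None, matmap=None, current=None,
            description="first-order decay over a fixed transit time",
            expected={"survival": (survival, 1e-4)},
            extras={"rate_constant": k, "transit_time": tau,
                    "rtd_times": t, "rtd": f})

    raise ConfigurationError(
        f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")


def lognormal_replicates(value: float, cv: float, n: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Median-unbiased multiplicative lognormal noise with the stated CV."""
    if cv < 0:
        raise ConfigurationError("cv must be >= 0")
    if cv == 0:
        return np.full(n, value)
    sigma = math.sqrt(math.log1p(cv * cv))
    return value * np.exp(sigma * rng.standard_normal(n))


def synth_measurements(model, true_k: float, cv: float = 0.05, n: int = 20,
                       seed: int = 0) -> dict:
    """Noisy replicate steady ratios from a device model at a true k."""
    return model.synthesize_measurements(true_k, cv, n, seed)
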