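# Methods

## Physical model

The device infuses peptide solution into cortical tissue through a 50 µm
source conduit by electroosmosis, draws it across a 269 µm gap to a sink
conduit, and conducts it into a 290 µm chamber where a hollow-fiber
microdialysis membrane (200/220 µm i.d./o.d., 13 kDa MWCO, 1 mm active
length) perfused at 0.5 µL/min samples the stream. The same electrical
current that drives the flow passes through the whole fluidic path to a
ground at the dialysate outlet.

The simulation proceeds in three stages on one labeled structured grid.

**Current conduction.** ∇·(σ_eff ∇V) = 0 with σ_eff = σ·α/λ² in porous
media. Current is injected uniformly over the source-lumen inlet face and
the dialysate outlet face is grounded; every other boundary (including
the waste overflow) is electrically insulating. This boundary choice
reproduces the expected ~3 kV/m field inside the source lumen
(I/(σA) = 2.83 kV/m analytically at 10 µA).

**Electrokinetic flow.** In the thin-double-layer limit the
electroosmotic superficial velocity is v_eo = −(εζ/μ)(α/λ²)E. Because
current density obeys j = σ(α/λ²)E, the EO volumetric face flow can be
written q_eo = ε|ζ|/(μσ)·I_face: slaving flow to the conservative face
currents makes ∇·v_eo = 0 exact inside uniform media (and reproduces the
channel invariant Q/I = ε|ζ|/(μσ) to machine precision), so the pressure
equation only corrects ζ/σ mismatches and the imposed dialysate circuit.
The pressure field solves ∇·((κ/μ)∇P) = ∇·v_eo with the source reservoir
and waste overflow at P = 0, a prescribed 0.5 µL/min dialysate inflow,
and the dialysate outlet held at the Hagen–Poiseuille backpressure of the
three downstream bench capillaries evaluated at the instantaneous outlet
flow (two Picard passes; the coupling is weak). Open channels are Darcy
media in the Brinkman limit with α = λ = 1 and an equivalent permeability
d²/32 (conduits) or w²/12 (slab channels), which reproduces lumped
Poiseuille resistances; with the tissue's κ = 10⁻¹⁵ m² the
pressure-driven contribution to tissue transport is an order of magnitude
slower than electroosmosis, matching the closed-form estimate
(14.2 Pa across 269 µm → 7.5×10⁻⁸ m/s → ~1 h transit).

**Reactive transport.** Concentrations are carried on a pore-fluid basis;
porosity enters through the accessible volume αV and α-weighted diffusive
face fluxes, and hindered diffusion is D/λ² (conductivity additionally
carries α, i.e. the σ·α/λ² convention). Hydrolysis S → P is first order —
infusate concentrations (~1 µM) are far below ectopeptidase Km
(~20–200 µM), so k = Vmax/Km — and is confined to tissue cells, because
the responsible ectopeptidases are membrane-bound in the parenchyma; no
hydrolysis occurs in the device lumens, chamber, or membrane. The
membrane transmits solutes diffusively (λ = 2.42, α = 0.2) and
convectively through its κ = 2×10⁻¹⁹ m²; no size exclusion is applied to
these tetra/pentapeptides, far below the 13 kDa cutoff.

## Geometry reduction

The solver uses a tensor-product hexahedral grid, so curved conduits are
represented by equal-area squares (side d·√π/2), preserving lumen current
density and flow per current. The probe-in-chamber annulus becomes a
planar counter-current exchanger — chamber channel | 10 µm membrane slab
| dialysate lumen slab — whose channel cross sections and membrane
exchange area match the cylindrical values to within 10%. A dead entry
section of 0.35 mm of chamber channel precedes the active membrane,
standing for the chamber base around the glue plug and the
outlet-capillary clearance; the captured perfusate crosses it before any
exchange, which sets the chamber's washout delay. Conduit run lengths
(0.3 mm source feed, 1.0 mm sink-to-chamber) are documented
approximations of the printed device and are configurable.

Residence times are referenced to the orifices: the mean source-to-sink
residence time is the difference of step-response first moments between a
probe in the last source-lumen cell and one in the first sink-lumen cell
(RTD moments compose additively along the path), so conduit transit does
not contaminate the tissue statistic.

## Far-field boundary

The tissue block (1.0 × 0.6 × 1.67 mm) is embedded in an effectively
unbounded, perfused brain. Sealing its outer faces would force every
infused molecule to be captured eventually and drag the approach to
steady state past the 40-min window; clamping C = 0 directly on the box
faces overstates the loss. The outer tissue faces therefore carry a Robin
condition: diffusive flux through an exterior tissue shell of thickness
0.1 mm to a zero-concentration bath. The 0.1 mm default is the cortical
perfusion clearance scale — inter-capillary spacing in cortex is
~50–100 µm, so beyond roughly that distance the extracellular
concentration of a clearable solute is pinned near baseline. Both the
condition (`tissue_farfield: no_flux` restores a sealed box) and the
shell thickness are configurable. No current or fluid crosses these
faces.

## Parameters

All material constants (ζ, μ, σ, α, λ, κ per medium; per-temperature
diffusion coefficients of YGGFL, GGFL and yaGfl) are the tabulated
literature values at the two working temperatures, 37 °C (tissue and
device interior) and 22 °C (bench). Water relative permittivity is 74 at
37 °C and 80 at 22 °C (handbook values; configurable). The membrane's
bulk conductivity of 0.046 S/m follows from the bench-temperature saline
conductivity (1.36 S/m)·α/λ², and is loaded as such. The external
capillary network uses room-temperature viscosity 8.9×10⁻⁴ Pa·s, which
reproduces the expected 9.39 kPa backpressure at 0.5 µL/min; the printed
conduits are assigned the fused-silica ζ = −46.5 mV (the tissue flow per
current is insensitive to this choice at the <1% level). The default
infusate is 1 mol/m³ of substrate and internal standard; the model is
linear, so every reported ratio is independent of this value.

## Numerics

- Finite volumes with two-point flux and distance-weighted harmonic
  averaging of face coefficients; first-order upwind advection. The
  operator is an M-matrix, so concentrations remain in [0, C_in].
- Implicit (backward Euler) time stepping with a tiered step: 0.5 s to
  2 min, 2 s to 10 min, 10 s thereafter. Each tier factorizes the system
  once (sparse LU) and reuses the factors; all linear solves are direct
  and deterministic, with residuals checked at 10⁻⁸.
- Steady states (used for calibration sweeps over k) solve the stationary
  system directly, reusing the k-independent flow solution.
- Base resolution puts ≤ 12 µm cells at the orifices (conduit radius/2)
  and ~35k active cells on the full device; the refinement parameter
  multiplies every axis's cell count. Problem sizes were chosen so a full
  40-min coupled run completes in about a minute: the published
  three-dimensional finite-element model is reproduced at reduced scale,
  which is why the operating-point checks carry the wide tolerance bands
  they do.
- Validation oracles: two-slab conduction (exact field ratio), uniform
  channel EO flow (Q/I exact), 1D step breakthrough against the
  flux-inlet (Danckwerts) advection–diffusion closed form (<2%), an exact
  equal-diffusivity superposition identity for the reaction pair, and
  machine-precision mass/current balances.

## Rate inference

Steady S/IS and P/IS at the probe outlet are simulated over a sorted
log-spaced k grid (one steady solve per k). Measured ratios are inverted
by minimizing the squared log-residual along monotone PCHIP interpolants
on log k; replicates combine by geometric mean (consistent with
multiplicative lognormal measurement noise), a stated measurement CV is
propagated through the interpolant to an interval, and observables
outside the sweep's hull set an extrapolation flag instead of failing.
With a 5 nM quantitation floor on a 1000 nM infusion, the product ratio
resolves slow rates and the substrate ratio fast ones; together they
cover more than three decades of k at a single current.

## What the synthetic measurements do and do not emulate

`synth_measurements` draws multiplicative lognormal replicates around the
simulated steady ratios (default CV 5%, seeded). This emulates
proportional quantitation error of an LC/UV–MS pipeline after internal
standard normalization. It does not emulate drift, carryover,
probe-to-probe geometric variability, tissue heterogeneity or trauma
around the track, adsorption losses, or model misspecification of the
rate law — closed-loop recovery tests therefore demonstrate the
invertibility of the calibration under the stated noise model, not
end-to-end in vivo accuracy.

## Known limitations

- The planar exchanger ignores azimuthal variation around the probe and
  slightly redistributes membrane exchange along the flow; the chamber
  washout delay is common to reactive and unreactive runs, which damps
  the contrast between their approach-to-steady-state times relative to
  the full 3D geometry (measured t95 ratio ≈ 1.46 vs ≈ 2 reported for
  the full model).
- First-order upwinding adds numerical diffusion near the orifices where
  the cell Péclet number exceeds 2; the operating-point statistics are
  insensitive at the stated tolerances, but sharp-front problems should
  use a finer grid.
- Electrode chemistry, Joule heating, electrophoretic migration of the
  (zwitterionic) peptides, Michaelis–Menten saturation, and
  tissue-damage dynamics are out of scope.
- The source/sink vertical offset present in the physical device is
  configurable but defaults to coaxial alignment; its magnitude is not
  published.
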