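"""Physical parameters of the media and solutes.

Electrokinetic, hydraulic and electrical constants for each medium in the
device (brain tissue, microdialysis membrane, open fluidic channels and the
infused saline), at the two working temperatures (37 degC in the animal,
22 degC on the bench), together with the peptide solutes: the substrate
YGGFL (leu-enkephalin), its hydrolysis product GGFL, and the
peptidase-resistant all-D analog yaGfl used as internal standard.

Porous media reduce transport relative to free solution: conductivity by the
porosity-over-tortuosity-squared factor alpha/lambda^2, diffusion by
1/lambda^2 (porosity enters separately through the accessible volume).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

from .errors import ConfigurationError

VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m

#: Relative permittivity of water at the two tabulated temperatures.
RELATIVE_PERMITTIVITY = {37.0: 74.0, 22.0: 80.0}

TABULATED_TEMPERATURES = (37.0, 22.0)


@dataclass(frozen=True)
class MaterialProperties:
    """Electrokinetic / hydraulic / electrical constants of one medium.

    ``solution_conductivity`` is the conductivity of the pore fluid; the
    conductivity of the bulk porous medium is ``effective_conductivity``.
    ``permeability_kappa`` is the Darcy permeability; open channels use an
    equivalent Poiseuille permeability (Brinkman limit) so a single Darcy
    formulation covers every region.
    """

    medium_name: str
    zeta_potential: float  # V (negative for silica-like and tissue surfaces)
    viscosity: float  # Pa s
    solution_conductivity: float  # S/m
    porosity_alpha: float = 1.0
    tortuosity_lambda: float = 1.0
    permeability_kappa: float = 1e-10  # m^2
    temperature: float = 37.0  # degC

    def __post_init__(self):
        if not (0.0 < self.porosity_alpha <= 1.0):
            raise ConfigurationError(
                f"{self.medium_name}: porosity_alpha must be in (0, 1], "
                f"got {self.porosity_alpha}")
        if self.tortuosity_lambda < 1.0:
            raise ConfigurationError(
                f"{self.medium_name}: tortuosity_lambda must be >= 1")
        if self.viscosity <= 0.0:
            raise ConfigurationError(f"{self.medium_name}: viscosity must be > 0")
        if self.permeability_kappa <= 0.0:
            raise ConfigurationError(
                f"{self.medium_name}: permeability_kappa must be > 0")
        if self.solution_conductivity <= 0.0:
            raise ConfigurationError(
                f"{self.medium_name}: solution_conductivity must be > 0")

    @property
    def effective_conductivity(self) -> float:
        """Bulk conductivity sigma * alpha / lambda^2 of the porous medium."""
        return effective_conductivity(
            self.solution_conductivity, self.porosity_alpha, self.tortuosity_lambda)

    @property
    def permittivity(self) -> float:
        """Absolute permittivity of the pore fluid at this temperature."""
        rel = RELATIVE_PERMITTIVITY.get(self.temperature)
        if rel is None:
            # linear fallback between the tabulated points is deliberately not
            # offered; off-table temperatures must supply epsilon explicitly
            raise ConfigurationError(
                f"no tabulated permittivity at {self.temperature} degC")
        return rel * VACUUM_PERMITTIVITY

    @property
    def electroosmotic_mobility(self) -> float:
        """Helmholtz-Smoluchowski mobility -eps*zeta/mu (m^2/(V s), > 0 for
        negative zeta: flow along the conventional current)."""
        return -self.permittivity * self.zeta_potential / self.viscosity

    def with_overrides(self, **kwargs) -> "MaterialProperties":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SpeciesSpec:
    """A transported solute with per-temperature free diffusion coefficients."""

    name: str
    free_diffusion_coefficient: dict  # degC -> m^2/s
    infused_concentration: float = 0.0  # mol/m^3
    role: str = "custom"  # substrate | product | internal_standard | custom

    def __post_init__(self):
        if any(d <= 0 for d in self.free_diffusion_coefficient.values()):
            raise ConfigurationError(f"{self.name}: diffusion coefficients must be > 0")
        if self.infused_concentration < 0:
            raise ConfigurationError(f"{self.name}: infused_concentration must be >= 0")

    def diffusion_at(self, temperature: float) -> float:
        try:
            return self.free_diffusion_coefficient[temperature]
        except KeyError:
            raise ConfigurationError(
                f"species {self.name}: no diffusion coefficient tabulated at "
                f"{temperature} degC") from None


@dataclass(frozen=True)
class ReactionSpec:
    """First-order hydrolysis substrate -> product (1:1), rate k = Vmax/Km."""

    substrate: str
    product: str
    rate_constant_k: float  # 1/s
    vmax: float | None = None  # mol/(m^3 s)
    km: float | None = None  # mol/m^3

    def __post_init__(self):
        if self.rate_constant_k < 0:
            raise ConfigurationError("rate_constant_k must be >= 0")
        if self.substrate == self.product:
            raise ConfigurationError("substrate and product must differ")

    @classmethod
    def from_michaelis_menten(cls, substrate: str, product: str,
                              vmax: float, km: float,
                              substrate_concentration: float = 0.0) -> "ReactionSpec":
        k = linearized_rate_constant(vmax, km, substrate_concentration)
        return cls(substrate=substrate, product=product, rate_constant_k=k,
                   vmax=vmax, km=km)


def effective_conductivity(solution_conductivity: float, porosity_alpha: float,
                           tortuosity_lambda: float) -> float:
    """Conductivity of a porous medium: sigma * alpha / lambda^2."""
    if not (0.0 < porosity_alpha <= 1.0):
        raise ConfigurationError("porosity_alpha must be in (0, 1]")
    if tortuosity_lambda < 1.0:
        raise ConfigurationError("tortuosity_lambda must be >= 1")
    if solution_conductivity <= 0.0:
        raise ConfigurationError("solution_conductivity must be > 0")
    return solution_conductivity * porosity_alpha / tortuosity_lambda**2


def effective_diffusivity(free_diffusion_coefficient: float,
                          tortuosity_lambda: float) -> float:
    """Hindered diffusion coefficient D / lambda^2 (Nicholson convention).

    Porosity is *not* applied here; it enters mass balances through the
    accessible pore volume, keeping concentrations on a pore-fluid basis.
    """
    if free_diffusion_coefficient <= 0.0:
        raise ConfigurationError("free diffusion coefficient must be > 0")
    if tortuosity_lambda < 1.0:
        raise ConfigurationError("tortuosity_lambda must be >= 1")
    return free_diffusion_coefficient / tortuosity_lambda**2


class LinearizationWarning(UserWarning):
    """Substrate concentration is not small versus Km; k = Vmax/Km is suspect."""


def linearized_rate_constant(vmax: float, km: float,
                             substrate_concentration: float = 0.0) -> float:
    """First-order rate constant k = Vmax/Km of the linearized rate law.

    Valid when the substrate concentration is well below Km (infusates are
    ~1 uM against Km of ~20-200 uM); a warning is emitted when
    S_i > 0.1 * Km.
    """
    if km <= 0.0:
        raise ConfigurationError("Km must be > 0")
    if substrate_concentration < 0.0:
        raise ConfigurationError("substrate concentration must be >= 0")
    if substrate_concentration > 0.1 * km:
        warnings.warn(
            f"substrate concentration {substrate_concentration} mol/m^3 exceeds "
            f"0.1*Km = {0.1 * km}; the linear rate law k = Vmax/Km is questionable",
            LinearizationWarning, stacklevel=2)
    return vmax / km


# --- Table of default media ----------------------------------------------

_ZETA_TISSUE = -0.0228  # V
_ZETA_CHANNEL = -0.0465  # V (fused silica; also used for printed conduits)
_VISCOSITY = {37.0: 0.00070, 22.0: 0.00096}  # Pa s
_SOLUTION_CONDUCTIVITY = {37.0: 1.80, 22.0: 1.36}  # S/m
_KAPPA_TISSUE = 1.0e-15  # m^2
_KAPPA_MEMBRANE = 2.0e-19  # m^2

_DIFFUSION = {
    "YGGFL": {37.0: 5.5e-10, 22.0: 4.2e-10},
    "GGFL": {37.0: 6.5e-10, 22.0: 5.0e-10},
    "yaGfl": {37.0: 5.4e-10, 22.0: 4.2e-10},
}

#: Default infused concentration, mol/m^3 (1 mM; every result downstream is
#: linear in this value, ratios are independent of it).
DEFAULT_INFUSED_CONCENTRATION = 1.0

KNOWN_MEDIA = ("tissue", "membrane", "fluidic_channels", "infused_solution")


def _check_temperature(temperature: float) -> float:
    t = float(temperature)
    if t not in TABULATED_TEMPERATURES:
        raise ConfigurationError(
            f"temperature {temperature} degC is not tabulated; "
            f"choose one of {TABULATED_TEMPERATURES}")
    return t


def default_material(medium: str, temperature: float = 37.0) -> MaterialProperties:
    """Default constants for one medium at a tabulated temperature.

    The membrane's pore-fluid conductivity is the bench-temperature saline
    value independent of context, so that its bulk conductivity reproduces
    the tabulated 0.046 S/m.
    """
    t = _check_temperature(temperature)
    mu = _VISCOSITY[t]
    sigma = _SOLUTION_CONDUCTIVITY[t]
    if medium == "tissue":
        return MaterialProperties(
            medium_name="tissue", zeta_potential=_ZETA_TISSUE, viscosity=mu,
            solution_conductivity=sigma, porosity_alpha=0.2,
            tortuosity_lambda=1.61, permeability_kappa=_KAPPA_TISSUE,
            temperature=t)
    if medium == "membrane":
        return MaterialProperties(
            medium_name="membrane", zeta_potential=0.0, viscosity=mu,
            solution_conductivity=_SOLUTION_CONDUCTIVITY[22.0],
            porosity_alpha=0.2, tortuosity_lambda=2.42,
            permeability_kappa=_KAPPA_MEMBRANE, temperature=t)
    if medium == "fluidic_channels":
        return MaterialProperties(
            medium_name="fluidic_channels", zeta_potential=_ZETA_CHANNEL,
            viscosity=mu, solution_conductivity=sigma, temperature=t)
    if medium == "infused_solution":
        return MaterialProperties(
            medium_name="infused_solution", zeta_potential=_ZETA_CHANNEL,
            viscosity=mu, solution_conductivity=sigma, temperature=t)
    raise ConfigurationError(
        f"unknown medium {medium!r}; known media: {KNOWN_MEDIA}")


def default_species(temperature: float = 37.0) -> list[SpeciesSpec]:
    """The three peptides with tabulated diffusion coefficients.

    Exactly one internal standard (yaGfl) is defined; substrate and internal
    standard are co-infused, the product enters at zero concentration.
    """
    _check_temperature(temperature)
    return [
        SpeciesSpec("YGGFL", dict(_DIFFUSION["YGGFL"]),
                    infused_concentration=DEFAULT_INFUSED_CONCENTRATION,
                    role="substrate"),
        SpeciesSpec("GGFL", dict(_DIFFUSION["GGFL"]),
                    infused_concentration=0.0, role="product"),
        SpeciesSpec("yaGfl", dict(_DIFFUSION["yaGfl"]),
                    infused_concentration=DEFAULT_INFUSED_CONCENTRATION,
                    role="internal_standard"),
    ]


def load_default_parameters(temperature_context: float = 37.0
                            ) -> tuple[dict[str, MaterialProperties], list[SpeciesSpec]]:
    """All default media and species for one temperature context.

    Returns ``(media, species)`` where ``media`` maps medium name to
    :class:`MaterialProperties` and ``species`` lists the three peptides.
    """
    t = _check_temperature(temperature_context)
    media = {name: default_material(name, t) for name in KNOWN_MEDIA}
    return media, default_species(t)


def validate_species_set(species: list[SpeciesSpec]) -> None:
    """Exactly one internal standard; unique names."""
    names = [s.name for s in species]
    if len(set(names)) != len(names):
        raise ConfigurationError("duplicate species names")
    n_is = sum(1 for s in species if s.role == "internal_standard")
    if n_is != 1:
        raise ConfigurationError(
            f"exactly one internal_standard species required, found {n_is}")


def poiseuille_permeability(hydraulic_diameter: float, kind: str = "tube") -> float:
    """Equivalent Darcy permeability of an open conduit (Brinkman limit).

    ``tube``: kappa = d^2/32 reproduces Hagen-Poiseuille resistance;
    ``slit``: kappa = w^2/12 for a parallel-plate gap of width w.
    """
    if hydraulic_diameter <= 0:
        raise ConfigurationError("hydraulic diameter must be > 0")
    if kind == "tube":
        return hydraulic_diameter**2 / 32.0
    if kind == "slit":
        return hydraulic_diameter**2 / 12.0
    raise ConfigurationError(f"unknown conduit kind {kind!r}")
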