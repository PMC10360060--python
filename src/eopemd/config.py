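"""Run configuration: unit-aware parsing and validation.

Configs are plain YAML with explicit units on dimensional values
("current: 10 uA", "duration: 40 min"); everything is converted to SI at
parse time and unknown keys are rejected.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Any

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .errors import ConfigurationError

#: factors to SI for the accepted unit spellings
_UNITS = {
    "A": 1.0, "mA": 1e-3, "uA": 1e-6, "nA": 1e-9,
    "V": 1.0, "mV": 1e-3,
    "m": 1.0, "cm": 1e-2, "mm": 1e-3, "um": 1e-6, "nm": 1e-9,
    "s": 1.0, "min": 60.0, "h": 3600.0,
    "Pa": 1.0, "kPa": 1e3,
    "Pa*s": 1.0, "Pa.s": 1.0,
    "S/m": 1.0,
    "m2": 1.0, "m^2": 1.0,
    "m2/s": 1.0, "m^2/s": 1.0,
    "m3/s": 1.0, "m^3/s": 1.0,
    "uL/min": 1e-9 / 60.0, "nL/min": 1e-12 / 60.0, "uL/s": 1e-9,
    "mol/m3": 1.0, "mol/m^3": 1.0,
    "M": 1e3, "mM": 1.0, "uM": 1e-3, "nM": 1e-6,
    "1/s": 1.0, "degC": 1.0,
    "mol/(m3*s)": 1.0, "mol/(m^3*s)": 1.0,
}

_QTY_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*([^\s]*)\s*$")


def parse_quantity(value: Any, key: str = "value") -> float:
    """'10 uA' -> 1e-5; bare numbers are taken as SI already."""
    if isinstance(value, (int, float)):
        return float(value)
    m = _QTY_RE.match(str(value))
    if not m:
        raise ConfigurationError(f"{key}: cannot parse quantity {value!r}")
    try:
        num = float(m.group(1))
    except ValueError:
        raise ConfigurationError(f"{key}: bad number in {value!r}") from None
    unit = m.group(2)
    if not unit:
        return num
    if unit not in _UNITS:
        raise ConfigurationError(f"{key}: unknown unit {unit!r} in {value!r}")
    return num * _UNITS[unit]


class ReactionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k: Any = "0 1/s"
    vmax: Any = None
    km: Any = None
    substrate: str = "YGGFL"
    product: str = "GGFL"


class RunConfig(BaseModel):
    """Validated simulation configuration; all stored values are SI."""
    model_config = ConfigDict(extra="forbid", validate_default=True)

    current: Any = "10 uA"
    duration: Any = "40 min"
    output_interval: Any = "30 s"
    resolution: int = 1
    temperature_context: float = 37.0
    dialysate_inflow: Any = "0.5 uL/min"
    infused_concentration: Any = "1 mM"
    reaction: ReactionConfig = Field(default_factory=ReactionConfig)
    geometry: dict[str, Any] = Field(default_factory=dict)
    materials: dict[str, dict[str, Any]] = Field(default_factory=dict)
    tissue_farfield: str = "absorbing"
    farfield_shell: Any = "0.1 mm"
    seed: int = 0
    output_dir: str | None = None

    @field_validator("tissue_farfield")
    @classmethod
    def _farfield(cls, v):
        if v not in ("absorbing", "no_flux"):
            raise ConfigurationError(
                "tissue_farfield must be 'absorbing' or 'no_flux'")
        return v

    @field_validator("current", "duration", "output_interval",
                     "dialysate_inflow", "infused_concentration",
                     "farfield_shell", mode="after")
    @classmethod
    def _to_si(cls, v, info):
        x = parse_quantity(v, info.field_name)
        if info.field_name in ("duration", "output_interval",
                               "dialysate_inflow", "infused_concentration"):
            if x <= 0:
                raise ConfigurationError(f"{info.field_name} must be > 0")
        return x

    @field_validator("resolution")
    @classmethod
    def _res(cls, v):
        if v < 1:
            raise ConfigurationError("resolution must be >= 1")
        return v

    @field_validator("temperature_context")
    @classmethod
    def _temp(cls, v):
        from .materials import TABULATED_TEMPERATURES
        if float(v) not in TABULATED_TEMPERATURES:
            raise ConfigurationError(
                f"temperature_context must be one of {TABULATED_TEMPERATURES}")
        return float(v)

    @field_validator("geometry")
    @classmethod
    def _geom(cls, v):
        from .geometry import DeviceGeometry
        known = set(DeviceGeometry.__dataclass_fields__)
        out = {}
        for key, raw in v.items():
            if key not in known:
                raise ConfigurationError(f"geometry: unknown key {key!r}")
            if key == "tissue_box":
                out[key] = tuple(parse_quantity(x, key) for x in raw)
            elif key == "lumped_capillary_network":
                out[key] = tuple(
                    (parse_quantity(a, key), parse_quantity(b, key))
                    for a, b in raw)
            else:
                out[key] = parse_quantity(raw, key)
            if isinstance(out[key], float) and out[key] <= 0 \
                    and key != "source_sink_vertical_offset":
                raise ConfigurationError(f"geometry: {key} must be > 0")
        return out

    @field_validator("materials")
    @classmethod
    def _materials(cls, v):
        from .materials import KNOWN_MEDIA, MaterialProperties
        known_fields = set(MaterialProperties.__dataclass_fields__) - {
            "medium_name"}
        out = {}
        for medium, overrides in v.items():
            if medium not in KNOWN_MEDIA:
                raise ConfigurationError(
                    f"materials: unknown medium {medium!r}; "
                    f"known media: {KNOWN_MEDIA}")
            out[medium] = {}
            for key, raw in overrides.items():
                if key not in known_fields:
                    raise ConfigurationError(
                        f"materials.{medium}: unknown key {key!r}")
                out[medium][key] = parse_quantity(raw, f"{medium}.{key}")
        return out

    def rate_constant(self) -> float:
        from .materials import linearized_rate_constant
        r = self.reaction
        if r.vmax is not None and r.km is not None:
            return linearized_rate_constant(parse_quantity(r.vmax, "vmax"),
                                            parse_quantity(r.km, "km"))
        return parse_quantity(r.k, "k")


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    try:
        return RunConfig(**raw)
    except ConfigurationError:
        raise
    except Exception as exc:  # pydantic ValidationError with key names
        raise ConfigurationError(f"invalid configuration: {exc}") from exc


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Snapshot the validated (SI) configuration next to the outputs."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=True)
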