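"""Device geometry, materials, and simulation controls.

All quantities are stored internally in SI units.  Configuration files
(YAML or JSON; JSON is parsed by the same loader since it is a YAML
subset) use the bench-friendly units the device community works in —
micrometres for lengths, milliamperes for coil current, nanometres for
particle diameter, microlitres per minute for flow — with unit-suffixed
keys so a file is unambiguous on its own.  The loader converts to SI,
rejects unknown keys, and validates every physical invariant.

Coordinate convention used throughout the package: ``z = 0`` at the top
surface of the coil wires, so the filament plane sits at ``z = -h/2``
and the channel floor at ``z = K_coil``.  The channel axis runs along
``x`` over the coil centre; ``y`` is lateral.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ConfigError",
    "CoilSpec",
    "ChannelSpec",
    "FluidSpec",
    "ParticleSpec",
    "ElectrodeSpec",
    "DielectricStack",
    "SimulationSpec",
    "DeviceConfig",
    "LoopSet",
    "COIL_CATALOG",
    "default_config",
    "derive_loop_set",
    "load_config",
    "write_config",
    "config_hash",
]


class ConfigError(ValueError):
    """Raised when a configuration file or parameter set is invalid."""


#: Catalogue of the four reference spiral coils.  Turn counts follow the
#: rule that the innermost filament sits at 75 µm radius (the value the
#: 97-turn, 2000 µm coil implies at a 20 µm pitch) and turns fill outward.
COIL_CATALOG: dict[str, tuple[float, int]] = {
    "R500": (500e-6, 22),
    "R1000": (1000e-6, 47),
    "R1500": (1500e-6, 72),
    "R2000": (2000e-6, 97),
}

#: Operating current range the coil designs were characterised over (A).
#: Values outside it only warn — the physics stays valid, the thermal
#: envelope may not.
CURRENT_RANGE = (0.1, 0.7)


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass(frozen=True)
class CoilSpec:
    """Planar spiral microcoil, modelled as concentric circular filaments.

    Parameters are SI: radii/widths in metres, current in amperes,
    conductivity in S/m.
    """

    outer_radius: float
    n_turns: int
    wire_width: float = 10e-6
    wire_height: float = 10e-6
    spacing: float = 10e-6
    current: float = 0.4
    conductivity: float = 59.6e6

    def __post_init__(self) -> None:
        _require(self.outer_radius > 0, "coil.outer_radius must be > 0")
        _require(self.n_turns >= 1, "coil.n_turns must be a positive integer")
        _require(self.wire_width > 0, "coil.wire_width must be > 0")
        _require(self.wire_height > 0, "coil.wire_height must be > 0")
        _require(self.spacing >= 0, "coil.spacing must be >= 0")
        _require(self.conductivity > 0, "coil.conductivity must be > 0")
        _require(
            self.pitch > 0 and self.innermost_radius > 0,
            "coil geometry leaves no room for the innermost turn: "
            f"outer_radius={self.outer_radius}, n_turns={self.n_turns}, "
            f"pitch={self.pitch}",
        )
        lo, hi = CURRENT_RANGE
        if not (lo <= abs(self.current) <= hi):
            warnings.warn(
                f"coil current {self.current} A lies outside the "
                f"characterised range {lo}-{hi} A",
                stacklevel=2,
            )

    @property
    def pitch(self) -> float:
        return self.wire_width + self.spacing

    @property
    def innermost_radius(self) -> float:
        return (self.outer_radius - self.wire_width / 2) - (self.n_turns - 1) * self.pitch


@dataclass(frozen=True)
class ChannelSpec:
    """Rectangular microchannel above the coil.

    ``coil_separation`` is the vertical gap between the wire top surface
    and the channel floor; ``lateral_offset`` shifts the channel axis in
    ``y`` relative to the coil centre.
    """

    width: float = 50e-6
    height: float = 50e-6
    length: float = 4.8e-3
    coil_separation: float = 30e-6
    lateral_offset: float = 0.0

    def __post_init__(self) -> None:
        _require(self.width > 0, "channel.width must be > 0")
        _require(self.height > 0, "channel.height must be > 0")
        _require(self.length > 0, "channel.length must be > 0")
        _require(self.coil_separation >= 0, "channel.coil_separation must be >= 0")


@dataclass(frozen=True)
class FluidSpec:
    """Carrier fluid (sweat is essentially water at these scales)."""

    density: float = 1000.0
    viscosity: float = 1e-3
    flow_rate: float = 1e-9 / 60.0  # 1 µL/min
    relative_permeability: float = 1.0
    relative_permittivity: float = 80.0

    def __post_init__(self) -> None:
        _require(self.density > 0, "fluid.density must be > 0")
        _require(self.viscosity > 0, "fluid.viscosity must be > 0")
        _require(self.flow_rate > 0, "fluid.flow_rate must be > 0")
        _require(self.relative_permeability >= 1, "fluid.relative_permeability must be >= 1")
        _require(self.relative_permittivity > 0, "fluid.relative_permittivity must be > 0")


@dataclass(frozen=True)
class ParticleSpec:
    """Magnetic nanoparticle (magnetite-like label).

    ``mass_density`` is metadata used only by the optional inertial
    integration mode; the default transport model is overdamped.
    """

    diameter: float = 50e-9
    relative_permeability: float = 5000.0
    relative_permittivity: float = 10.0
    mass_density: float = 5200.0

    def __post_init__(self) -> None:
        _require(self.diameter > 0, "particle.diameter must be > 0")
        _require(self.relative_permeability > 0, "particle.relative_permeability must be > 0")
        _require(self.relative_permittivity > 0, "particle.relative_permittivity must be > 0")
        _require(self.mass_density > 0, "particle.mass_density must be > 0")

    @property
    def radius(self) -> float:
        return self.diameter / 2

    @property
    def volume(self) -> float:
        return math.pi * self.diameter**3 / 6

    @property
    def mass(self) -> float:
        return self.mass_density * self.volume


@dataclass(frozen=True)
class ElectrodeSpec:
    """Parallel-plate sensing electrodes flanking the channel.

    ``gap`` is the plate separation and spans wall + channel + wall.
    Conductivity is metadata only: capacitance assumes ideal conductors.
    """

    height: float = 50e-6
    length: float = 500e-6
    gap: float = 60e-6
    voltage: float = 5.0
    conductivity: float = 59.6e6

    def __post_init__(self) -> None:
        _require(self.height > 0, "electrodes.height must be > 0")
        _require(self.length > 0, "electrodes.length must be > 0")
        _require(self.gap > 0, "electrodes.gap must be > 0")

    @property
    def area(self) -> float:
        return self.height * self.length


@dataclass(frozen=True)
class DielectricStack:
    """Wall–channel–wall dielectric stack between the electrodes."""

    channel_thickness: float = 50e-6
    wall_thickness: float = 5e-6
    eps_channel: float = 80.0
    eps_wall: float = 2.7

    def __post_init__(self) -> None:
        _require(self.channel_thickness > 0, "stack.channel_thickness must be > 0")
        _require(self.wall_thickness >= 0, "stack.wall_thickness must be >= 0")
        _require(self.eps_channel > 0, "stack.eps_channel must be > 0")
        _require(self.eps_wall > 0, "stack.eps_wall must be > 0")

    @property
    def gap(self) -> float:
        return self.channel_thickness + 2 * self.wall_thickness


@dataclass(frozen=True)
class SimulationSpec:
    """Transport-simulation controls."""

    horizon: float = 60.0
    injection_window: float = 10.0
    n_particles: int = 500
    seed: int = 0
    rtol: float = 1e-5
    atol: float = 1e-8
    packing_fraction: float = 0.01
    occupancy_model: str = "parallel-column"

    def __post_init__(self) -> None:
        _require(self.horizon > 0, "simulation.horizon must be > 0")
        _require(0 < self.injection_window <= self.horizon,
                 "simulation.injection_window must lie in (0, horizon]")
        _require(self.n_particles >= 1, "simulation.n_particles must be >= 1")
        _require(self.rtol > 0 and self.atol > 0, "simulation tolerances must be > 0")
        _require(0 < self.packing_fraction <= 1,
                 "simulation.packing_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class DeviceConfig:
    """Complete, cross-validated device description."""

    coil: CoilSpec
    channel: ChannelSpec
    fluid: FluidSpec
    particle: ParticleSpec
    electrodes: ElectrodeSpec
    stack: DielectricStack
    simulation: SimulationSpec

    def __post_init__(self) -> None:
        _require(
            math.isclose(self.stack.channel_thickness, self.channel.width, rel_tol=1e-12),
            "stack.channel_thickness must equal channel.width "
            f"({self.stack.channel_thickness} != {self.channel.width})",
        )
        _require(
            math.isclose(self.electrodes.gap, self.stack.gap, rel_tol=1e-12),
            "electrodes.gap must equal stack wall+channel+wall thickness "
            f"({self.electrodes.gap} != {self.stack.gap})",
        )


@dataclass(frozen=True)
class LoopSet:
    """Concentric circular filaments standing in for one spiral coil."""

    radii: tuple[float, ...]
    z: float
    current: float
    wire_width: float = 10e-6
    wire_height: float = 10e-6

    def __len__(self) -> int:
        return len(self.radii)

    @property
    def outer_radius(self) -> float:
        return max(self.radii) + self.wire_width / 2


def derive_loop_set(coil: CoilSpec) -> LoopSet:
    """Discretise a spiral coil into concentric circular filaments.

    Filament ``k`` sits at radius ``(outer_radius - w/2) - k*(w+s)`` on
    the wire mid-plane ``z = -h/2`` (wire top surface defines z = 0).
    """
    pitch = coil.pitch
    radii = tuple(
        (coil.outer_radius - coil.wire_width / 2) - k * pitch for k in range(coil.n_turns)
    )
    if radii[-1] <= 0:
        raise ConfigError("innermost filament radius is not positive")
    return LoopSet(
        radii=radii,
        z=-coil.wire_height / 2,
        current=coil.current,
        wire_width=coil.wire_width,
        wire_height=coil.wire_height,
    )


def default_config(coil_name: str = "R2000") -> DeviceConfig:
    """Reference operating point of the optimised device.

    50x50 µm channel at 30 µm coil separation, 1 µL/min sweat flow,
    50 nm particles with relative permeability 5000, 400 mA drive,
    5 µm PDMS walls and 50x500 µm electrodes at 5 V.
    """
    try:
        outer_radius, n_turns = COIL_CATALOG[coil_name]
    except KeyError:
        raise ConfigError(
            f"unknown coil name {coil_name!r}; expected one of {sorted(COIL_CATALOG)}"
        ) from None
    channel = ChannelSpec(length=round(2.4 * outer_radius, 9))
    stack = DielectricStack(channel_thickness=channel.width)
    return DeviceConfig(
        coil=CoilSpec(outer_radius=outer_radius, n_turns=n_turns),
        channel=channel,
        fluid=FluidSpec(),
        particle=ParticleSpec(),
        electrodes=ElectrodeSpec(gap=stack.gap),
        stack=stack,
        simulation=SimulationSpec(),
    )


# --- config file schema -------------------------------------------------
#
# section -> file key -> (dataclass attribute, scale factor to SI)

_UM = 1e6  # divisor: value_um / 1e6 = metres (exactly invertible)
_SCHEMA: dict[str, tuple[str, dict[str, tuple[str, float]]]] = {
    "coil": ("coil", {
        "outer_radius_um": ("outer_radius", _UM),
        "n_turns": ("n_turns", 1),
        "wire_width_um": ("wire_width", _UM),
        "wire_height_um": ("wire_height", _UM),
        "wire_spacing_um": ("spacing", _UM),
        "current_ma": ("current", 1e3),
        "conductivity_s_per_m": ("conductivity", 1),
    }),
    "channel": ("channel", {
        "width_um": ("width", _UM),
        "height_um": ("height", _UM),
        "length_um": ("length", _UM),
        "coil_separation_um": ("coil_separation", _UM),
        "lateral_offset_um": ("lateral_offset", _UM),
    }),
    "fluid": ("fluid", {
        "density_kg_per_m3": ("density", 1),
        "viscosity_pa_s": ("viscosity", 1),
        "flow_rate_ul_per_min": ("flow_rate", 6e10),
        "relative_permeability": ("relative_permeability", 1),
        "relative_permittivity": ("relative_permittivity", 1),
    }),
    "particle": ("particle", {
        "diameter_nm": ("diameter", 1e9),
        "relative_permeability": ("relative_permeability", 1),
        "relative_permittivity": ("relative_permittivity", 1),
        "mass_density_kg_per_m3": ("mass_density", 1),
    }),
    "electrodes": ("electrodes", {
        "height_um": ("height", _UM),
        "length_um": ("length", _UM),
        "voltage_v": ("voltage", 1),
        "conductivity_s_per_m": ("conductivity", 1),
    }),
    "stack": ("stack", {
        "wall_thickness_um": ("wall_thickness", _UM),
        "pdms_relative_permittivity": ("eps_wall", 1),
    }),
    "simulation": ("simulation", {
        "horizon_s": ("horizon", 1),
        "injection_window_s": ("injection_window", 1),
        "n_particles": ("n_particles", 1),
        "seed": ("seed", 1),
        "rtol": ("rtol", 1),
        "atol_m": ("atol", 1),
        "packing_fraction": ("packing_fraction", 1),
        "occupancy_model": ("occupancy_model", None),  # passthrough string
    }),
}

_INT_FIELDS = {"n_turns", "n_particles", "seed"}


def load_config(path: str | Path, *, coil_name: str | None = None) -> DeviceConfig:
    """Load and validate a device configuration file (YAML or JSON).

    Missing keys fall back to the reference defaults (`default_config`);
    a partial file overriding a single parameter is therefore valid.
    Unknown sections or keys are rejected with the offending name.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"config file {path} is not valid YAML/JSON: {exc}") from None
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("top level of a config file must be a mapping")

    name = raw["coil"].get("name") if isinstance(raw.get("coil"), dict) else None
    name = coil_name or name or "R2000"
    base = default_config(name)

    updates: dict[str, dict[str, object]] = {}
    for section, content in raw.items():
        if section not in _SCHEMA:
            raise ConfigError(f"unknown config section {section!r}")
        if not isinstance(content, dict):
            raise ConfigError(f"config section {section!r} must be a mapping")
        attr_name, keys = _SCHEMA[section]
        out: dict[str, object] = {}
        for key, value in content.items():
            if section == "coil" and key == "name":
                continue
            if key not in keys:
                raise ConfigError(f"unknown key {section}.{key}")
            attr, scale = keys[key]
            if scale is None:
                out[attr] = str(value)
            else:
                if isinstance(value, str):
                    # pyyaml's YAML-1.1 resolver misses '1e-05'-style floats
                    try:
                        value = float(value)
                    except ValueError:
                        pass
                if not isinstance(value, (int, float)) or isinstance(value, bool):
                    raise ConfigError(f"{section}.{key} must be a number, got {value!r}")
                out[attr] = int(value) if attr in _INT_FIELDS else float(value) / scale
        updates[attr_name] = out

    parts = {}
    for section, (attr_name, _) in _SCHEMA.items():
        spec = getattr(base, attr_name)
        over = updates.get(attr_name, {})
        parts[attr_name] = dataclasses.replace(spec, **over) if over else spec

    # keep the dependent dielectric geometry consistent with the channel
    stack = dataclasses.replace(parts["stack"], channel_thickness=parts["channel"].width,
                                eps_channel=parts["fluid"].relative_permittivity)
    electrodes = dataclasses.replace(parts["electrodes"], gap=stack.gap)
    return DeviceConfig(
        coil=parts["coil"],
        channel=parts["channel"],
        fluid=parts["fluid"],
        particle=parts["particle"],
        electrodes=electrodes,
        stack=stack,
        simulation=parts["simulation"],
    )


def config_to_dict(config: DeviceConfig) -> dict:
    """Serialise a DeviceConfig to the file-unit dictionary schema."""
    out: dict[str, dict[str, object]] = {}
    for section, (attr_name, keys) in _SCHEMA.items():
        spec = getattr(config, attr_name)
        sec: dict[str, object] = {}
        for key, (attr, scale) in keys.items():
            value = getattr(spec, attr)
            if scale is None:
                sec[key] = value
            elif attr in _INT_FIELDS:
                sec[key] = int(value)
            else:
                # round in file units so load(write(cfg)) is exact
                sec[key] = round(float(value) * scale, 9)
        out[section] = sec
    return out


def write_config(config: DeviceConfig, path: str | Path) -> Path:
    """Write a DeviceConfig to YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    data = config_to_dict(config)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    return path


def config_hash(config: DeviceConfig) -> str:
    """Short stable hash identifying a configuration (for output headers)."""
    blob = json.dumps(config_to_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
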