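"""Direct-field capacitive readout of nanoparticle occupancy.

The detection zone is a parallel-plate capacitor whose gap spans a
PDMS wall, the fluid channel, and a second PDMS wall.  The equivalent
series capacitance of that stack is

    C_eq = eps0 * eps_PDMS * eps_ch / (eps_PDMS * d_ch + 2 * eps_ch * d_PDMS) * A

i.e. the harmonic combination of three ideal plate capacitors.  When
trapped magnetic nanoparticles occupy a fraction phi of the detection
zone they replace high-permittivity sweat (eps ~ 80) with a lower-
permittivity particle-rich phase (eps 10-40), reducing the capacitance;
the sensitivity is the relative capacitance drop
100*(C(0) - C(phi))/C(0).

The default occupancy geometry is a *parallel-column* plug: the
particle-rich phase fills the full gap over a length fraction phi of the
electrodes, so C(phi) is the area-weighted parallel combination of two
stacks and is exactly affine in phi.  Volumetric mixing alternatives
(linear mixture, Maxwell-Garnett) are selectable for sensitivity
analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.constants import epsilon_0

from .config import DeviceConfig, DielectricStack, ElectrodeSpec, ParticleSpec

__all__ = [
    "OccupancyState",
    "CapacitanceResult",
    "parallel_plate_capacitance",
    "stack_capacitance",
    "occupancy_capacitance",
    "sensitivity",
    "delta_capacitance",
    "occupancy_from_trap",
    "dynamic_trace",
    "MIXING_MODELS",
]

MIXING_MODELS = ("parallel-column", "linear-mixture", "maxwell-garnett")


@dataclass(frozen=True)
class OccupancyState:
    """Fraction ``phi`` of the detection-zone channel volume occupied by
    the nanoparticle-rich phase, with its relative permittivity."""

    phi: float
    eps_particle: float = 10.0
    model: str = "parallel-column"

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError(f"occupancy phi must lie in [0, 1], got {self.phi}")
        if self.eps_particle <= 0:
            raise ValueError("eps_particle must be > 0")
        if self.model not in MIXING_MODELS:
            raise ValueError(
                f"unknown mixing model {self.model!r}; expected one of {MIXING_MODELS}")


@dataclass(frozen=True)
class CapacitanceResult:
    """Before/after capacitance pair with the derived readout figures."""

    c_before: float
    c_after: float

    @property
    def delta(self) -> float:
        return self.c_after - self.c_before

    @property
    def sensitivity(self) -> float:
        return 100.0 * (self.c_before - self.c_after) / self.c_before


def parallel_plate_capacitance(electrodes: ElectrodeSpec, eps_r: float) -> float:
    """Ideal parallel-plate capacitance eps0 * eps_r * A / d (farad)."""
    if eps_r <= 0:
        raise ValueError("eps_r must be > 0")
    return epsilon_0 * eps_r * electrodes.area / electrodes.gap


def stack_capacitance(electrodes: ElectrodeSpec, stack: DielectricStack,
                      eps_channel: float | None = None) -> float:
    """Series wall-channel-wall capacitance of the detection zone.

    With zero wall thickness this reduces exactly to the single-layer
    plate formula.  ``eps_channel`` overrides the stack's channel
    permittivity (used by the occupancy models).
    """
    eps_ch = stack.eps_channel if eps_channel is None else eps_channel
    if eps_ch <= 0:
        raise ValueError("channel permittivity must be > 0")
    denom = stack.eps_wall * stack.channel_thickness + 2 * eps_ch * stack.wall_thickness
    return epsilon_0 * stack.eps_wall * eps_ch / denom * electrodes.area


def _effective_permittivity(occ: OccupancyState, eps_ch: float) -> float:
    """phi-weighted channel permittivity for the volumetric mixing models."""
    phi, eps_p = occ.phi, occ.eps_particle
    if occ.model == "linear-mixture":
        return (1 - phi) * eps_ch + phi * eps_p
    if occ.model == "maxwell-garnett":
        # spherical inclusions eps_p at volume fraction phi in host eps_ch
        k = (eps_p - eps_ch) / (eps_p + 2 * eps_ch)
        return eps_ch * (1 + 2 * phi * k) / (1 - phi * k)
    raise ValueError(f"unknown mixing model {occ.model!r}")


def occupancy_capacitance(electrodes: ElectrodeSpec, stack: DielectricStack,
                          occ: OccupancyState) -> float:
    """Detection-zone capacitance at occupancy ``occ.phi``.

    Parallel-column model: the particle-rich plug spans the full gap
    over a fraction phi of the electrode length, so
    C(phi) = (1-phi) C_stack(eps_ch) + phi C_stack(eps_p).
    """
    if occ.model == "parallel-column":
        c_fluid = stack_capacitance(electrodes, stack)
        c_plug = stack_capacitance(electrodes, stack, eps_channel=occ.eps_particle)
        return (1 - occ.phi) * c_fluid + occ.phi * c_plug
    eps_eff = _effective_permittivity(occ, stack.eps_channel)
    return stack_capacitance(electrodes, stack, eps_channel=eps_eff)


def sensitivity(electrodes: ElectrodeSpec, stack: DielectricStack,
                occ: OccupancyState) -> float:
    """Relative capacitance drop 100*(C(0) - C(phi))/C(0) in percent."""
    c0 = stack_capacitance(electrodes, stack)
    c = occupancy_capacitance(electrodes, stack, occ)
    return 100.0 * (c0 - c) / c0


def delta_capacitance(c_before: float, c_after: float) -> float:
    """Signed capacitance change C_after - C_before (negative when the
    effective permittivity drops)."""
    return c_after - c_before


def occupancy_from_trap(result, zone_length: float, channel_width: float,
                        channel_height: float, particle: ParticleSpec,
                        packing_fraction: float = 0.01) -> pd.DataFrame:
    """Occupancy time series phi(t) implied by trapped-particle counts.

    The trapped particles form a plug of volume
    N * V_particle / packing_fraction (the plug is a dilute suspension at
    the given particle volume packing); phi is that volume over the
    detection-zone channel volume, clipped to [0, 1].  Requires a
    TrapResult recorded with a ``trapped_in_zone`` series column (or
    uses total trapped counts as a fallback).
    """
    if zone_length <= 0 or channel_width <= 0 or channel_height <= 0:
        raise ValueError("detection zone dimensions must be positive")
    if not 0 < packing_fraction <= 1:
        raise ValueError("packing_fraction must lie in (0, 1]")
    series = result.series
    counts = (series["trapped_in_zone"] if "trapped_in_zone" in series
              else series["trapped"]).to_numpy(dtype=float)
    v_zone = zone_length * channel_width * channel_height
    phi = np.clip(counts * particle.volume / packing_fraction / v_zone, 0.0, 1.0)
    return pd.DataFrame({"t": series["t"].to_numpy(), "phi": phi})


def dynamic_trace(config: DeviceConfig, schedule: list[tuple[float, float]],
                  n_particles: int | None = None, seed: int | None = None,
                  ) -> pd.DataFrame:
    """Capacitance response C(t) to a coil on/off schedule.

    Runs the trapping simulation with the given coil activation
    intervals (trapped particles release when the coil switches off),
    converts trapped-in-zone counts to occupancy, and evaluates the
    stack capacitance.  Returns a table (t, trapped_in_zone, phi, C_fF).
    """
    from .transport import simulate_ensemble

    sim = config.simulation
    for a, b in schedule:
        if not (0 <= a < b):
            raise ValueError(f"bad schedule interval ({a}, {b})")
        if a > sim.horizon:
            raise ValueError(f"schedule interval ({a}, {b}) starts beyond the horizon")
    half_zone = config.electrodes.length / 2
    result = simulate_ensemble(config, n_particles=n_particles, seed=seed,
                               schedule=schedule, zone=(-half_zone, half_zone))
    phi_t = occupancy_from_trap(
        result, config.electrodes.length, config.channel.width,
        config.channel.height, config.particle,
        packing_fraction=sim.packing_fraction)
    occs = [OccupancyState(phi=p, eps_particle=config.particle.relative_permittivity,
                           model=sim.occupancy_model) for p in phi_t["phi"]]
    c = np.array([occupancy_capacitance(config.electrodes, config.stack, o)
                  for o in occs])
    out = phi_t.copy()
    if "trapped_in_zone" in result.series:
        out["trapped_in_zone"] = result.series["trapped_in_zone"].to_numpy()
    out["C_fF"] = c * 1e15
    return out
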