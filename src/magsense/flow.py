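"""Steady laminar flow of sweat in a rectangular microchannel.

At the device's Reynolds number (~0.3) the flow is Stokes-like and fully
developed over essentially the whole channel, so the Navier-Stokes
problem reduces to the classical pressure-driven rectangular-duct
solution: a Fourier series in the channel height with hyperbolic decay
across the width.  The series is scaled so the integrated flux equals
the imposed volumetric rate Q exactly (closed-form flux integral, no
numerical quadrature).

Channel-local coordinates: ``y`` lateral in [-W/2, W/2], ``z`` vertical
in [0, H] measured from the channel floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ChannelSpec, FluidSpec

__all__ = ["FlowField", "solve_flow", "velocity_at"]


@dataclass(frozen=True)
class FlowField:
    """Axial velocity field u(y, z) of a rectangular duct at flow rate Q."""

    channel: ChannelSpec
    fluid: FluidSpec
    n_terms: int = 51
    _scale: float = field(init=False, repr=False, default=0.0)

    def __post_init__(self) -> None:
        if self.n_terms < 11 or self.n_terms % 2 == 0:
            raise ValueError("n_terms must be an odd integer >= 11")
        a = self.channel.height / 2
        b = self.channel.width / 2
        i = np.arange(1, self.n_terms + 1, 2, dtype=float)
        alpha = i * np.pi / (2 * a)
        # flux of the unscaled series, term by term (closed form)
        sign = (-1.0) ** ((i - 1) / 2)
        int_z = (4 * a / (i * np.pi)) * sign          # integral of cos term
        int_y = 2 * b - (4 * a / (i * np.pi)) * np.tanh(alpha * b)
        flux = np.sum(sign / i**3 * int_z * int_y)
        object.__setattr__(self, "_i", i)
        object.__setattr__(self, "_alpha", alpha)
        object.__setattr__(self, "_sign", sign)
        object.__setattr__(self, "_scale", self.fluid.flow_rate / flux)

    def velocity(self, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Axial velocity u (m/s) at channel-local (y, z); vectorised."""
        y = np.asarray(y, dtype=float)
        z = np.asarray(z, dtype=float)
        a = self.channel.height / 2
        b = self.channel.width / 2
        zc = z - a  # series is symmetric about the mid-height
        i, alpha, sign = self._i, self._alpha, self._sign
        # cosh(a y)/cosh(a b) in overflow-safe form (|y| <= b):
        #   exp(a(|y|-b)) (1 + e^{-2a|y|}) / (1 + e^{-2ab})
        ay = np.multiply.outer(np.abs(y), alpha)
        ab = alpha * b
        ratio = np.exp(ay - ab) * (1 + np.exp(-2 * ay)) / (1 + np.exp(-2 * ab))
        terms = (sign / i**3) * (1.0 - ratio) * np.cos(np.multiply.outer(zc, alpha))
        return self._scale * terms.sum(axis=-1)

    @property
    def mean_velocity(self) -> float:
        return self.fluid.flow_rate / (self.channel.width * self.channel.height)

    @property
    def max_velocity(self) -> float:
        return float(self.velocity(0.0, self.channel.height / 2))

    @property
    def hydraulic_diameter(self) -> float:
        w, h = self.channel.width, self.channel.height
        return 2 * w * h / (w + h)

    @property
    def reynolds(self) -> float:
        return (self.fluid.density * self.mean_velocity * self.hydraulic_diameter
                / self.fluid.viscosity)

    def to_frame(self, n_y: int = 51, n_z: int = 51) -> pd.DataFrame:
        """Cross-section velocity map (y, z, u) on a regular grid."""
        y = np.linspace(-self.channel.width / 2, self.channel.width / 2, n_y)
        z = np.linspace(0.0, self.channel.height, n_z)
        yy, zz = np.meshgrid(y, z, indexing="ij")
        u = self.velocity(yy.ravel(), zz.ravel())
        return pd.DataFrame({"y": yy.ravel(), "z": zz.ravel(), "u": u})


def solve_flow(channel: ChannelSpec, fluid: FluidSpec, n_terms: int = 51) -> FlowField:
    """Fully developed laminar velocity field for the given channel/fluid."""
    return FlowField(channel=channel, fluid=fluid, n_terms=n_terms)


def velocity_at(flow: FlowField, point: np.ndarray) -> np.ndarray:
    """Velocity vector (u, 0, 0) at a channel-local point (x, y, z).

    ``y`` must lie in [-W/2, W/2] and ``z`` in [0, H]; out-of-channel
    points raise with the violated bound named.
    """
    point = np.asarray(point, dtype=float)
    y, z = point[..., 1], point[..., 2]
    b = flow.channel.width / 2
    h = flow.channel.height
    if np.any(np.abs(y) > b):
        raise ValueError(f"point outside channel: |y| > {b}")
    if np.any((z < 0) | (z > h)):
        raise ValueError(f"point outside channel: z outside [0, {h}]")
    u = flow.velocity(y, z)
    out = np.zeros(point.shape, dtype=float)
    out[..., 0] = u
    return out
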