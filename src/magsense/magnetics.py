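"""Magnetostatics of planar spiral microcoils.

Every material in the device (copper, PDMS, water, a dilute nanoparticle
suspension) has relative permeability ~1, so the source field is the
free-space field of the coil currents and superposition applies: the
spiral is discretised into concentric circular filaments whose fields
are known in closed form through complete elliptic integrals.  The
particles' large permeability enters only the force they feel, never the
source field (one-way coupling).

Near-field work (the "rippling" of flux density at the wire pitch) needs
the finite 10x10 µm wire cross-section: a 3x3 sub-filament quadrature of
each turn resolves it.  Far-field quantities are insensitive to it and
default to single centreline filaments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.constants import mu_0
from scipy.special import ellipe, ellipk

from .config import ChannelSpec, CoilSpec, LoopSet, derive_loop_set

__all__ = [
    "FieldMap",
    "MeritResult",
    "loop_field",
    "segment_field",
    "coil_field",
    "grad_h2",
    "bz_profile",
    "ripple_metric",
    "coil_resistance",
    "power_merit",
    "expand_cross_section",
    "feed_segments",
]

#: Points closer than this to a filament are treated as singular (m).
SINGULAR_DISTANCE = 1e-9


class SingularFieldError(ValueError):
    """Requested field point lies on (or within 1 nm of) a conductor."""


@dataclass(frozen=True)
class FieldMap:
    """Magnetic field sampled on a set of points.

    ``B`` is the flux density (T); ``H = B/mu0`` outside magnetic media;
    ``grad_h2`` (optional) holds the gradient of |H|^2 in A^2/m^3.
    """

    points: np.ndarray
    B: np.ndarray
    grad_h2: np.ndarray | None = None
    quadrature: bool = False

    @property
    def H(self) -> np.ndarray:
        return self.B / mu_0

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "x": self.points[:, 0], "y": self.points[:, 1], "z": self.points[:, 2],
            "Bx": self.B[:, 0], "By": self.B[:, 1], "Bz": self.B[:, 2],
        }
        if self.grad_h2 is not None:
            for i, ax in enumerate("xyz"):
                cols[f"gradH2_{ax}"] = self.grad_h2[:, i]
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class MeritResult:
    """Power merit factor of a coil: peak field per watt dissipated."""

    b_max: float
    resistance: float
    voltage: float
    power: float
    merit: float


def loop_field(radius: float, current: float, points: np.ndarray, z0: float = 0.0,
               ) -> np.ndarray:
    """Flux density of a circular filament of given ``radius`` at ``z0``.

    Closed-form solution in complete elliptic integrals; exact for a
    filamentary loop, vectorised over ``points`` of shape (..., 3).

    Raises :class:`SingularFieldError` for points on the filament.
    """
    pts = np.asarray(points, dtype=float)
    scalar = pts.ndim == 1
    pts = np.atleast_2d(pts)
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2] - z0
    rho = np.hypot(x, y)

    d2 = (rho - radius) ** 2 + z**2
    if np.any(d2 < SINGULAR_DISTANCE**2):
        raise SingularFieldError("field point lies on the filament")

    a = radius
    denom = (a + rho) ** 2 + z**2
    m = 4 * a * rho / denom
    K = ellipk(m)
    E = ellipe(m)
    pref = mu_0 * current / (2 * np.pi * np.sqrt(denom))
    bz = pref * (K + (a**2 - rho**2 - z**2) / d2 * E)
    with np.errstate(invalid="ignore", divide="ignore"):
        brho = pref * (z / rho) * (-K + (a**2 + rho**2 + z**2) / d2 * E)
    on_axis = rho < 1e-15
    brho = np.where(on_axis, 0.0, brho)

    B = np.empty_like(pts)
    with np.errstate(invalid="ignore"):
        cos_phi = np.where(on_axis, 0.0, x / np.where(on_axis, 1.0, rho))
        sin_phi = np.where(on_axis, 0.0, y / np.where(on_axis, 1.0, rho))
    B[:, 0] = brho * cos_phi
    B[:, 1] = brho * sin_phi
    B[:, 2] = bz
    return B[0] if scalar else B


def segment_field(start: np.ndarray, end: np.ndarray, current: float,
                  points: np.ndarray) -> np.ndarray:
    """Flux density of a finite straight current segment (feed line).

    Uses the robust two-vector form of the Biot-Savart solution; exact
    for a filamentary segment carrying ``current`` from start to end.
    """
    a = np.asarray(start, dtype=float)
    b = np.asarray(end, dtype=float)
    pts = np.asarray(points, dtype=float)
    scalar = pts.ndim == 1
    pts = np.atleast_2d(pts)

    r1 = pts - a
    r2 = pts - b
    n1 = np.linalg.norm(r1, axis=1)
    n2 = np.linalg.norm(r2, axis=1)
    cross = np.cross(r1, r2)
    dot = np.einsum("ij,ij->i", r1, r2)
    denom = n1 * n2 * (n1 * n2 + dot)
    # denom -> 0 on the segment (singular) and on its axis extension
    # (where cross is 0 too and the field is legitimately zero)
    seg_len = np.linalg.norm(b - a)
    dist = np.linalg.norm(cross, axis=1) / max(seg_len, 1e-300)
    on_line = dist < SINGULAR_DISTANCE
    between = (dot < 0) | (np.minimum(n1, n2) < SINGULAR_DISTANCE)
    if np.any(on_line & between):
        raise SingularFieldError("field point lies on the segment")
    safe = np.where(on_line, 1.0, denom)
    B = mu_0 * current / (4 * np.pi) * cross * ((n1 + n2) / safe)[:, None]
    B[on_line] = 0.0
    return B[0] if scalar else B


def expand_cross_section(loops: LoopSet, n: int = 3,
                         ) -> tuple[np.ndarray, np.ndarray, float]:
    """Replace each filament by an n x n sub-filament grid over the wire
    cross-section, each carrying current/n^2.  Needed to resolve the
    near-field ripple at heights comparable to the wire size.

    Returns (radii, z positions, per-filament current).
    """
    offs = (np.arange(n) - (n - 1) / 2) / n
    dr = offs * loops.wire_width
    dz = offs * loops.wire_height
    base = np.asarray(loops.radii)
    radii = (base[:, None, None] + dr[None, :, None] + 0 * dz[None, None, :]).ravel()
    zs = (loops.z + 0 * base[:, None, None] + 0 * dr[None, :, None]
          + dz[None, None, :]).ravel()
    return radii, zs, loops.current / n**2


def _loops_and_z(loops: LoopSet, quadrature: bool, n_quad: int = 3):
    if quadrature:
        return expand_cross_section(loops, n_quad)
    return np.asarray(loops.radii), np.full(len(loops.radii), loops.z), loops.current


def _field_at(loops: LoopSet, pts: np.ndarray, quadrature: bool, n_quad: int = 3,
              feeds: list[tuple[np.ndarray, np.ndarray]] | None = None) -> np.ndarray:
    radii, zs, cur = _loops_and_z(loops, quadrature, n_quad)
    B = np.zeros_like(pts)
    for r, z in zip(radii, zs):
        B += loop_field(r, cur, pts, z0=z)
    if feeds:
        for start, end in feeds:
            B += segment_field(start, end, loops.current, pts)
    return B


def coil_field(loops: LoopSet, points: np.ndarray, *, quadrature: bool = False,
               n_quad: int = 3, with_grad_h2: bool = False, grad_step: float = 1e-6,
               feeds: list[tuple[np.ndarray, np.ndarray]] | None = None) -> FieldMap:
    """Superposed field of all coil filaments at ``points``.

    With ``quadrature`` each wire's cross-section is represented by an
    ``n_quad x n_quad`` sub-filament grid carrying I/n^2 each.  With
    ``with_grad_h2`` the gradient of |H|^2 is evaluated by central
    differences of the closed-form field with step ``grad_step``.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    B = _field_at(loops, pts, quadrature, n_quad, feeds)
    g = None
    if with_grad_h2:
        g = grad_h2(loops, pts, step=grad_step, quadrature=quadrature,
                    n_quad=n_quad, feeds=feeds)
    return FieldMap(points=pts, B=B, grad_h2=g, quadrature=quadrature)


def grad_h2(loops: LoopSet, points: np.ndarray, *, step: float = 1e-6,
            quadrature: bool = False, n_quad: int = 3,
            feeds: list[tuple[np.ndarray, np.ndarray]] | None = None) -> np.ndarray:
    """Central-difference gradient of |H|^2 (A^2/m^3) at ``points``."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))

    def h2(p):
        B = _field_at(loops, p, quadrature, n_quad, feeds)
        return np.einsum("ij,ij->i", B, B) / mu_0**2

    g = np.empty_like(pts)
    for i in range(3):
        dp = np.zeros(3)
        dp[i] = step
        g[:, i] = (h2(pts + dp) - h2(pts - dp)) / (2 * step)
    return g


def bz_profile(coil: CoilSpec | LoopSet, axis: str, *, fixed: dict[str, float],
               samples: np.ndarray, quadrature: bool = False,
               feeds: list[tuple[np.ndarray, np.ndarray]] | None = None,
               ) -> pd.DataFrame:
    """Flux-density profile along ``axis`` ('x' or 'z') at fixed other
    coordinates.  Returns a table (coordinate, Bz, Bx, Bmag)."""
    loops = derive_loop_set(coil) if isinstance(coil, CoilSpec) else coil
    if axis not in ("x", "z"):
        raise ValueError("axis must be 'x' or 'z'")
    samples = np.asarray(samples, dtype=float)
    pts = np.zeros((samples.size, 3))
    defaults = {"x": 0.0, "y": 0.0, "z": 0.0}
    defaults.update(fixed)
    for i, name in enumerate(("x", "y", "z")):
        pts[:, i] = samples if name == axis else defaults[name]
    fmap = coil_field(loops, pts, quadrature=quadrature, feeds=feeds)
    return pd.DataFrame({
        "coordinate": samples,
        "Bz": fmap.B[:, 2],
        "Bx": fmap.B[:, 0],
        "Bmag": np.linalg.norm(fmap.B, axis=1),
    })


def ripple_metric(coordinates: np.ndarray, bz: np.ndarray, pitch: float) -> float:
    """Relative peak-to-peak of the oscillatory flux-density component.

    The profile is smoothed with a moving average one wire pitch wide;
    the ripple is (max - min) of the residual divided by the mean of the
    raw profile over the valid span.  A uniform profile gives 0.
    """
    coordinates = np.asarray(coordinates, dtype=float)
    bz = np.asarray(bz, dtype=float)
    if coordinates.size != bz.size:
        raise ValueError("coordinate and Bz arrays must have equal length")
    span = coordinates.max() - coordinates.min()
    if span < 5 * pitch:
        raise ValueError("profile must cover at least 5 wire pitches")
    dx = np.mean(np.diff(coordinates))
    w = max(int(round(pitch / dx)) | 1, 3)  # odd window, >= 3 samples
    kernel = np.ones(w) / w
    smooth = np.convolve(bz, kernel, mode="valid")
    half = w // 2
    resid = bz[half:-half] - smooth
    baseline = np.mean(np.abs(bz[half:-half]))
    if baseline == 0:
        return 0.0
    return float((resid.max() - resid.min()) / baseline)


def coil_resistance(coil: CoilSpec) -> float:
    """DC resistance from the summed filament centreline lengths:
    R = sum_k 2 pi r_k / (sigma w h)."""
    if coil.conductivity <= 0 or coil.wire_width <= 0 or coil.wire_height <= 0:
        raise ValueError("coil conductivity and cross-section must be positive")
    loops = derive_loop_set(coil)
    length = 2 * np.pi * np.sum(loops.radii)
    return float(length / (coil.conductivity * coil.wire_width * coil.wire_height))


def power_merit(coil: CoilSpec, channel: ChannelSpec | None = None, *,
                current: float | None = None, n_rho: int = 600) -> MeritResult:
    """Power merit factor Mp = Bmax / P with P = U I = I^2 R.

    Bmax is the peak |B| over the plane of the channel floor
    (z = coil_separation), the field actually available to the fluidic
    domain; by axisymmetry the search is one-dimensional in radius.
    """
    current = coil.current if current is None else current
    if current <= 0:
        raise ValueError("current must be > 0")
    z = (channel or ChannelSpec()).coil_separation
    loops = derive_loop_set(coil)
    if current != coil.current:
        loops = LoopSet(radii=loops.radii, z=loops.z, current=current,
                        wire_width=loops.wire_width, wire_height=loops.wire_height)
    rho = np.linspace(0.0, 1.1 * coil.outer_radius, n_rho)
    pts = np.column_stack([rho, np.zeros_like(rho), np.full_like(rho, z)])
    B = _field_at(loops, pts, quadrature=False)
    b_max = float(np.max(np.linalg.norm(B, axis=1)))
    R = coil_resistance(coil)
    U = current * R
    P = U * current
    return MeritResult(b_max=b_max, resistance=R, voltage=U, power=P,
                       merit=b_max / P)


def feed_segments(coil: CoilSpec, reach: float | None = None,
                  ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Straight feed-line segments running under the coil along x.

    Models the supply/return traces to the spiral terminals; adding them
    to `coil_field` breaks the axisymmetry of the coil-only field, which
    is what makes channel placement relative to the vias matter.
    """
    reach = 1.2 * coil.outer_radius if reach is None else reach
    z = -coil.wire_height / 2
    return [
        (np.array([-reach, 0.0, z]), np.array([0.0, 0.0, z])),
        (np.array([0.0, 0.0, z]), np.array([reach, 0.0, z])),
    ]
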