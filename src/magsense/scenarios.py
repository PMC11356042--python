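"""Synthetic scenario generation: seeded inlet ensembles, randomized
in-range device configurations, and analytically constructed trapping
results for oracle-testing the outcome statistics.

Everything here is reproducible from (seed, parameters) alone, so every
downstream stage of the package can be exercised without external data.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .config import (ChannelSpec, DeviceConfig, config_hash, default_config)
from .flow import FlowField, solve_flow
from .transport import ESCAPED, FLOWING, TRAPPED, TrapResult

__all__ = ["sample_inlet", "random_device", "fixture_trap_result", "PARAMETER_RANGES"]

#: Designed parameter ranges for randomized configurations
#: (current A, particle diameter m, coil separation m, channel width m,
#: electrode height m).
PARAMETER_RANGES = {
    "current": (0.1, 0.7),
    "diameter": (10e-9, 60e-9),
    "coil_separation": (5e-6, 100e-6),
    "channel_width": (50e-6, 1000e-6),
    "electrode_height": (20e-6, 500e-6),
}


def sample_inlet(channel: ChannelSpec, flow: FlowField | None, n: int, seed: int,
                 weighting: str = "flux") -> np.ndarray:
    """Sample ``n`` inlet positions on the channel cross-section.

    Returns an (n, 2) array of channel-local (y, z) with y in
    (-W/2, W/2) and z in (0, H), keeping one particle radius of wall
    clearance implicitly by sampling the open interior.  ``flux``
    weighting draws positions with probability proportional to the local
    axial velocity (steady perfusion seeds particles per unit flux);
    ``uniform`` draws uniformly over the cross-section.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if weighting not in ("flux", "uniform"):
        raise ValueError(f"unknown inlet weighting {weighting!r}")
    if channel.width <= 0 or channel.height <= 0:
        raise ValueError("degenerate cross-section")
    rng = np.random.default_rng(seed)
    b, h = channel.width / 2, channel.height

    if weighting == "uniform":
        y = rng.uniform(-b, b, n)
        z = rng.uniform(0, h, n)
        return np.column_stack([y, z])

    if flow is None:
        raise ValueError("flux weighting needs a FlowField")
    u_max = flow.max_velocity
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        m = 2 * (n - filled) + 16
        y = rng.uniform(-b, b, m)
        z = rng.uniform(0, h, m)
        keep = rng.uniform(0, u_max, m) < flow.velocity(y, z)
        take = min(int(keep.sum()), n - filled)
        sel = np.flatnonzero(keep)[:take]
        out[filled:filled + take, 0] = y[sel]
        out[filled:filled + take, 1] = z[sel]
        filled += take
    return out


def random_device(seed: int, ranges: dict | None = None) -> DeviceConfig:
    """Uniformly sample a valid DeviceConfig inside the design ranges.

    Coil preset, drive current, particle diameter, coil separation and
    channel width are drawn; everything else keeps reference defaults.
    The result always passes full validation.
    """
    rng = np.random.default_rng(seed)
    rr = dict(PARAMETER_RANGES)
    if ranges:
        for k, v in ranges.items():
            if k not in rr:
                raise ValueError(f"unknown parameter range {k!r}")
            lo, hi = v
            if not (lo <= hi):
                raise ValueError(f"empty range for {k!r}: {v}")
            rr[k] = (float(lo), float(hi))

    name = ["R500", "R1000", "R1500", "R2000"][rng.integers(0, 4)]
    base = default_config(name)
    width = float(rng.uniform(*rr["channel_width"]))
    channel = dataclasses.replace(
        base.channel,
        width=width,
        coil_separation=float(rng.uniform(*rr["coil_separation"])),
    )
    stack = dataclasses.replace(base.stack, channel_thickness=width)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sampled current may touch range edges
        coil = dataclasses.replace(base.coil, current=float(rng.uniform(*rr["current"])))
    return DeviceConfig(
        coil=coil,
        channel=channel,
        fluid=base.fluid,
        particle=dataclasses.replace(base.particle,
                                     diameter=float(rng.uniform(*rr["diameter"]))),
        electrodes=dataclasses.replace(
            base.electrodes,
            height=float(rng.uniform(*rr["electrode_height"])),
            gap=stack.gap),
        stack=stack,
        simulation=dataclasses.replace(base.simulation, seed=int(seed)),
    )


def fixture_trap_result(pattern: str, *, n: int = 100, horizon: float = 60.0,
                        efficiency: float = 80.0, change_time: float = 20.0,
                        efficiency_before: float = 20.0,
                        resolve_delay: float = 1.0,
                        injection_window: float = 10.0) -> TrapResult:
    """Analytically constructed TrapResult with known statistics.

    Patterns:

    - ``none-trapped``: every particle escapes; efficiency 0 %.
    - ``constant-rate``: a fixed fraction of particles traps, uniformly
      in time, so the resolved trapping fraction is flat at
      ``efficiency`` percent from the first resolution onward.
    - ``step``: the per-particle trapping probability switches from
      ``efficiency_before`` to ``efficiency`` percent for particles
      resolving after ``change_time`` — the steady-state clock must
      start once the post-step mixture settles.

    Each particle resolves ``resolve_delay`` seconds after injection.
    """
    if pattern not in ("none-trapped", "constant-rate", "step"):
        raise ValueError(f"unknown fixture pattern {pattern!r}")
    t_inject = (np.arange(n) + 0.5) * (injection_window / n)
    t_event = t_inject + resolve_delay
    status = np.full(n, ESCAPED, dtype=np.int8)

    if pattern == "constant-rate":
        frac = efficiency / 100.0
        # deterministic low-discrepancy assignment: cumulative rounding
        cum = np.floor((np.arange(n) + 1) * frac + 1e-9)
        trapped_mask = np.diff(np.concatenate([[0.0], cum])) > 0
        status[trapped_mask] = TRAPPED
    elif pattern == "step":
        before = t_event <= change_time
        for mask, eff in ((before, efficiency_before), (~before, efficiency)):
            idx = np.flatnonzero(mask)
            frac = eff / 100.0
            cum = np.floor((np.arange(idx.size) + 1) * frac + 1e-9)
            tm = np.diff(np.concatenate([[0.0], cum])) > 0
            status[idx[tm]] = TRAPPED

    ts = np.arange(0.0, horizon + 0.5, 1.0)
    rows = []
    for t in ts:
        injected = int(np.sum(t_inject <= t))
        trapped = int(np.sum((status == TRAPPED) & (t_event <= t)))
        escaped = int(np.sum((status == ESCAPED) & (t_event <= t)))
        rows.append({"t": t, "injected": injected, "trapped": trapped,
                     "escaped": escaped, "flowing": injected - trapped - escaped})
    return TrapResult(
        config_hash="fixture-" + pattern, seed=0, n_particles=n, horizon=horizon,
        t_inject=t_inject, t_event=t_event, status=status,
        final_positions=np.zeros((n, 3)), series=pd.DataFrame(rows),
    )
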