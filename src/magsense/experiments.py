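"""Design-study drivers: field characterisation, trapping sweeps, and
capacitive-readout sweeps, each emitting seeded, hash-stamped CSV tables.

Every output file embeds the configuration hash, the seeds used, and the
package version in `#`-prefixed header lines, so any table can be traced
back to the exact run that produced it and re-running with the same
configuration and seeds reproduces it bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import (COIL_CATALOG, DeviceConfig, config_hash, default_config,
                     derive_loop_set)
from .flow import solve_flow
from .magnetics import bz_profile, power_merit, ripple_metric
from .readout import (OccupancyState, dynamic_trace, occupancy_capacitance,
                      sensitivity, stack_capacitance)
from .transport import (build_field_table, simulate_ensemble,
                        time_to_steady_state, trapping_efficiency)

__all__ = [
    "ExperimentRecord",
    "run_field_study",
    "run_trapping_study",
    "run_capacitance_study",
    "with_channel_width",
    "with_updates",
]

COIL_NAMES = ("R500", "R1000", "R1500", "R2000")

#: Declared sweep grids (the studies publish only ranges and endpoints).
WIDTH_GRID_UM = (50, 100, 200, 500, 1000)
SEPARATION_GRID_UM = (5, 10, 20, 30, 50, 100)
DIAMETER_GRID_NM = (10, 20, 30, 40, 50, 60)
CURRENT_GRID_MA = (100, 200, 300, 400, 500, 600, 700)


@dataclass
class ExperimentRecord:
    """Provenance and results of one experiment driver run."""

    name: str
    config_hash: str
    seeds: tuple[int, ...]
    results: dict[str, pd.DataFrame]
    outputs: list[Path] = field(default_factory=list)
    version: str = __version__
    wall_clock_s: float = 0.0


def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str, seeds) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    header = (f"# magsense {__version__}\n# config_hash: {cfg_hash}\n"
              f"# seeds: {list(seeds)}\n")
    path.write_text(header + df.to_csv(index=False))
    return path


def with_updates(config: DeviceConfig, **section_updates) -> DeviceConfig:
    """Replace spec sections while keeping the dependent dielectric
    geometry (stack channel thickness, electrode gap) consistent."""
    parts = {name: getattr(config, name) for name in
             ("coil", "channel", "fluid", "particle", "electrodes", "stack",
              "simulation")}
    for name, fields in section_updates.items():
        parts[name] = dataclasses.replace(parts[name], **fields)
    stack = dataclasses.replace(parts["stack"],
                                channel_thickness=parts["channel"].width,
                                eps_channel=parts["fluid"].relative_permittivity)
    electrodes = dataclasses.replace(parts["electrodes"], gap=stack.gap)
    return DeviceConfig(coil=parts["coil"], channel=parts["channel"],
                        fluid=parts["fluid"], particle=parts["particle"],
                        electrodes=electrodes, stack=stack,
                        simulation=parts["simulation"])


def with_channel_width(config: DeviceConfig, width: float) -> DeviceConfig:
    """Channel-width variant with a consistent dielectric stack."""
    return with_updates(config, channel={"width": width})


def run_field_study(config: DeviceConfig, out_dir: str | Path, *,
                    quick: bool = False) -> ExperimentRecord:
    """Field profiles, ripple decay, and power merit factors.

    Emits, for all four reference coils: Bz/Bx profiles along x at the
    channel-floor height and along z at the coil centre, mid-annulus and
    outer-edge radii; a ripple-versus-height table (wire cross-section
    quadrature on); and the merit factor over the drive-current grid.
    """
    t0 = time.time()
    out = Path(out_dir)
    cfg_hash = config_hash(config)
    z_floor = config.channel.coil_separation

    prof_rows = []
    zprof_rows = []
    for name in COIL_NAMES:
        coil = dataclasses.replace(default_config(name).coil,
                                   current=config.coil.current)
        outer = coil.outer_radius
        xs = np.linspace(-1.2 * outer, 1.2 * outer, 121 if quick else 361)
        prof = bz_profile(coil, "x", fixed={"z": z_floor}, samples=xs)
        prof.insert(0, "coil", name)
        prof_rows.append(prof)
        r_int = (coil.innermost_radius + outer) / 2
        for path_name, x0 in (("R0", 0.0), ("Rint", r_int), ("Rext", outer)):
            zs = np.linspace(5e-6, 200e-6, 40 if quick else 120)
            zp = bz_profile(coil, "z", fixed={"x": x0}, samples=zs)
            zp.insert(0, "path", path_name)
            zp.insert(0, "coil", name)
            zprof_rows.append(zp)
    profiles_x = pd.concat(prof_rows, ignore_index=True)
    profiles_z = pd.concat(zprof_rows, ignore_index=True)

    # ripple decay with height (small coil keeps the quadrature cheap)
    rip_coil = default_config("R500").coil if quick else config.coil
    rip_coil = dataclasses.replace(rip_coil, current=config.coil.current)
    pitch = rip_coil.pitch
    lo = rip_coil.innermost_radius + 2 * pitch
    hi = rip_coil.outer_radius - 2 * pitch
    xs = np.arange(lo, hi, 1e-6)
    rip_rows = []
    for z_um in (5, 10, 15, 20, 25, 30, 40, 50):
        prof = bz_profile(rip_coil, "x", fixed={"z": z_um * 1e-6}, samples=xs,
                          quadrature=True)
        rip_rows.append({"z_um": z_um,
                         "ripple": ripple_metric(xs, prof["Bz"].to_numpy(), pitch)})
    ripple = pd.DataFrame(rip_rows)

    merit_rows = []
    for name in COIL_NAMES:
        coil = default_config(name).coil
        for i_ma in CURRENT_GRID_MA:
            m = power_merit(coil, config.channel, current=i_ma * 1e-3)
            merit_rows.append({"coil": name, "current_ma": i_ma,
                               "b_max_mT": m.b_max * 1e3, "resistance_ohm": m.resistance,
                               "power_w": m.power, "merit_t_per_w": m.merit})
    merit = pd.DataFrame(merit_rows)

    rec = ExperimentRecord("field_study", cfg_hash, (),
                           {"profiles_x": profiles_x, "profiles_z": profiles_z,
                            "ripple_vs_z": ripple, "merit": merit})
    for key, df in rec.results.items():
        rec.outputs.append(_write_csv(df, out / f"{key}.csv", cfg_hash, ()))
    rec.wall_clock_s = time.time() - t0
    return rec


def _sweep_configs(sweep: str, config: DeviceConfig):
    if sweep == "coil":
        for name in COIL_NAMES:
            base = default_config(name)
            coil_fields = dataclasses.asdict(base.coil)
            coil_fields["current"] = config.coil.current
            yield name, with_updates(config, coil=coil_fields,
                                     channel={"length": base.channel.length})
    elif sweep == "width":
        for w in WIDTH_GRID_UM:
            yield w, with_channel_width(config, w * 1e-6)
    elif sweep == "separation":
        for k in SEPARATION_GRID_UM:
            yield k, with_updates(config, channel={"coil_separation": k * 1e-6})
    elif sweep == "diameter":
        for d in DIAMETER_GRID_NM:
            yield d, with_updates(config, particle={"diameter": d * 1e-9})
    else:
        raise ValueError(f"unknown sweep {sweep!r}; expected coil|width|"
                         "separation|diameter")


def run_trapping_study(sweep: str, config: DeviceConfig, out_dir: str | Path, *,
                       n_particles: int | None = None,
                       seeds: tuple[int, ...] = (1, 2, 3)) -> ExperimentRecord:
    """Trapping-efficiency sweep (efficiency at 60 s, mean/std over seeds)."""
    t0 = time.time()
    out = Path(out_dir)
    rows = []
    for value, cfg in _sweep_configs(sweep, config):
        table = build_field_table(cfg)
        runs = [simulate_ensemble(cfg, n_particles=n_particles, seed=s, table=table)
                for s in seeds]
        mean, std = trapping_efficiency(runs, 60.0 if cfg.simulation.horizon >= 60
                                        else cfg.simulation.horizon)
        taus = [time_to_steady_state(r) for r in runs] \
            if cfg.simulation.horizon >= 20 else [float("nan")]
        rows.append({"sweep": sweep, "value": value,
                     "efficiency_pct": mean, "efficiency_std_pct": std,
                     "t_steady_max_s": max(taus),
                     "n_particles": runs[0].n_particles, "n_seeds": len(seeds)})
    table_df = pd.DataFrame(rows)
    cfg_hash = config_hash(config)
    rec = ExperimentRecord(f"trapping_{sweep}", cfg_hash, tuple(seeds),
                           {"efficiency": table_df})
    rec.outputs.append(_write_csv(table_df, out / f"trapping_{sweep}.csv",
                                  cfg_hash, seeds))
    rec.wall_clock_s = time.time() - t0
    return rec


def run_capacitance_study(config: DeviceConfig, out_dir: str | Path, *,
                          n_particles: int = 200, seed: int = 1,
                          with_trace: bool = True) -> ExperimentRecord:
    """Capacitive-readout sweeps and the coil on/off dynamic trace."""
    t0 = time.time()
    out = Path(out_dir)
    cfg_hash = config_hash(config)
    el, stack = config.electrodes, config.stack

    eps_grid = np.arange(1.0, 101.0, 1.0)
    c_vs_eps = pd.DataFrame({
        "eps_r": eps_grid,
        "C_fF": [stack_capacitance(el, stack, eps_channel=e) * 1e15
                 for e in eps_grid],
    })

    sens_rows = []
    for eps_p in (10, 20, 30, 40):
        for phi in np.arange(0.10, 0.851, 0.05):
            occ = OccupancyState(phi=round(phi, 2), eps_particle=eps_p)
            sens_rows.append({
                "phi": round(phi, 2), "eps_particle": eps_p,
                "sensitivity_pct": sensitivity(el, stack, occ),
                "C_fF": occupancy_capacitance(el, stack, occ) * 1e15,
            })
    sens = pd.DataFrame(sens_rows)

    h_rows = []
    for h_um in (20, 50, 100, 200, 300, 400, 500):
        el_h = dataclasses.replace(el, height=h_um * 1e-6)
        h_rows.append({"height_um": h_um,
                       "C_fF": stack_capacitance(el_h, stack) * 1e15})
    heights = pd.DataFrame(h_rows)

    w_rows = []
    for w_um in WIDTH_GRID_UM:
        cfg_w = with_channel_width(config, w_um * 1e-6)
        w_rows.append({"width_um": w_um,
                       "C_fF": stack_capacitance(cfg_w.electrodes, cfg_w.stack) * 1e15})
    widths = pd.DataFrame(w_rows)

    ar_rows = []
    for ratio in (0.25, 0.5, 1.0, 2.0, 4.0):
        # vary H and W at fixed H*W (fixed frontal area footprint)
        area = el.height * config.channel.width
        h = float(np.sqrt(area * ratio))
        w = float(np.sqrt(area / ratio))
        cfg_r = with_updates(config, channel={"width": w},
                             electrodes={"height": h})
        ar_rows.append({"aspect_ratio_w_over_h": 1 / ratio, "height_um": h * 1e6,
                        "width_um": w * 1e6,
                        "C_fF": stack_capacitance(cfg_r.electrodes, cfg_r.stack) * 1e15})
    aspect = pd.DataFrame(ar_rows)

    results = {"c_vs_eps": c_vs_eps, "sensitivity_surface": sens,
               "height_sweep": heights, "width_sweep": widths,
               "aspect_ratio_sweep": aspect}
    if with_trace:
        results["dynamic_trace"] = dynamic_trace(
            config, schedule=[(0.0, 30.0)], n_particles=n_particles, seed=seed)

    rec = ExperimentRecord("capacitance_study", cfg_hash, (seed,), results)
    for key, df in results.items():
        rec.outputs.append(_write_csv(df, out / f"{key}.csv", cfg_hash, (seed,)))
    rec.wall_clock_s = time.time() - t0
    return rec


def acceptance_report(seed: int = 1, *, n_particles: int = 500,
                      n_seeds: int = 3) -> dict:
    """Recompute the headline design-point quantities from scratch.

    Returns a dict of {name: {"value": float, "n": int}} covering the
    deterministic readout figures (occupancy sensitivities and baseline
    capacitance at the default stack geometry) and the stochastic
    trapping figures (per-coil efficiency at 60 s and the slowest
    steady-state time), all computed by running the package.
    """
    cfg = default_config("R2000")
    el, stack = cfg.electrodes, cfg.stack
    report: dict[str, dict] = {}
    for key, phi in (("t1", 0.85), ("t2", 0.50)):
        occ = OccupancyState(phi=phi, eps_particle=10.0)
        report[key] = {"value": sensitivity(el, stack, occ), "n": 1}
    report["t3"] = {"value": stack_capacitance(el, stack) * 1e15, "n": 1}

    seeds = [seed + k for k in range(n_seeds)]
    taus = []
    for key, name in (("t4", "R2000"), ("t5", "R1500"), ("t6", "R1000"),
                      ("t7", "R500")):
        c = default_config(name)
        table = build_field_table(c)
        runs = [simulate_ensemble(c, n_particles=n_particles, seed=s, table=table)
                for s in seeds]
        mean, _ = trapping_efficiency(runs, 60.0)
        report[key] = {"value": mean, "n": n_particles * n_seeds}
        taus.extend(time_to_steady_state(r) for r in runs)
    report["t8"] = {"value": max(taus), "n": n_particles * n_seeds * 4}
    return report
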