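import dataclasses
import math

import numpy as np
import pytest

from magsense.config import FluidSpec, ParticleSpec, default_config
from magsense.scenarios import fixture_trap_result
from magsense.transport import (TRAPPED, build_field_table, clausius_mossotti,
                                drag_force, integrate_trajectory,
                                magnetophoretic_force, simulate_ensemble,
                                slip_velocity, time_to_steady_state,
                                trapping_efficiency)


@pytest.fixture(scope="module")
def strong_config():
    """Micron-scale particle, slow perfusion, small separation: a regime
    with decisive trapping, used to exercise the trapping machinery."""
    base = default_config("R500")
    return dataclasses.replace(
        base,
        particle=dataclasses.replace(base.particle, diameter=1e-6),
        channel=dataclasses.replace(base.channel, coil_separation=10e-6),
        fluid=dataclasses.replace(base.fluid, flow_rate=0.2e-9 / 60),
        simulation=dataclasses.replace(base.simulation, horizon=8.0,
                                       injection_window=3.0, atol=1e-7),
    )


@pytest.fixture(scope="module")
def strong_result(strong_config):
    return simulate_ensemble(strong_config, n_particles=15, seed=7)


class TestForces:
    def test_contrast_factor_vanishes_at_matched_permeability(self):
        particle = ParticleSpec(relative_permeability=1.0)
        f = magnetophoretic_force(particle, FluidSpec(), np.array([0, 0, 1e16]))
        assert np.all(f == 0.0)
        assert clausius_mossotti(1.0, 1.0) == 0.0

    def test_force_magnitude(self):
        particle = ParticleSpec(diameter=50e-9, relative_permeability=5000)
        f = magnetophoretic_force(particle, FluidSpec(), np.array([0, 0, 1e16]))
        assert f[2] == pytest.approx(1.233e-12, rel=1e-3)
        assert f[0] == f[1] == 0.0

    @pytest.mark.parametrize("scale", [2.0, 3.0])
    def test_force_scales_with_diameter_cubed(self, scale):
        g = np.array([1e14, -2e14, 5e15])
        f1 = magnetophoretic_force(ParticleSpec(diameter=20e-9), FluidSpec(), g)
        f2 = magnetophoretic_force(ParticleSpec(diameter=scale * 20e-9),
                                   FluidSpec(), g)
        assert np.allclose(f2, scale**3 * f1, rtol=1e-12)

    def test_drag(self):
        particle = ParticleSpec(diameter=50e-9)
        fluid = FluidSpec()
        assert np.all(drag_force(particle, fluid, np.ones(3), np.ones(3)) == 0)
        f = drag_force(particle, fluid, np.array([1e-3, 0, 0]), np.zeros(3))
        assert f[0] == pytest.approx(4.712e-13, rel=1e-3)
        # linear in the velocity difference
        f2 = drag_force(particle, fluid, np.array([3e-3, 0, 0]),
                        np.array([1e-3, 0, 0]))
        assert np.allclose(f2, 2 * f, rtol=1e-12)

    def test_slip_velocity(self):
        particle = ParticleSpec(diameter=50e-9, relative_permeability=5000)
        fluid = FluidSpec()
        v = slip_velocity(particle, fluid, np.array([0, 0, 1e16]), np.zeros(3))
        assert v[2] == pytest.approx(2.617e-3, rel=1e-3)
        assert np.all(slip_velocity(particle, fluid, np.zeros(3),
                                    np.array([1e-3, 0, 0]))
                      == np.array([1e-3, 0, 0]))

    @pytest.mark.parametrize("scale", [2.0, 6.0])
    def test_slip_scales_with_diameter_squared(self, scale):
        g = np.array([0, 0, 1e15])
        fluid = FluidSpec()
        v1 = slip_velocity(ParticleSpec(diameter=10e-9), fluid, g, np.zeros(3))
        v2 = slip_velocity(ParticleSpec(diameter=scale * 10e-9), fluid, g,
                           np.zeros(3))
        assert v2[2] == pytest.approx(scale**2 * v1[2], rel=1e-12)


class TestEnsemble:
    def test_zero_current_all_escape(self, r500):
        with pytest.warns(UserWarning):
            cfg = dataclasses.replace(
                r500, coil=dataclasses.replace(r500.coil, current=0.0))
        res = simulate_ensemble(cfg, n_particles=50, seed=3)
        c = res.counts_at(res.horizon)
        assert c["escaped"] == 50 and c["trapped"] == 0
        assert res.efficiency() == 0.0
        assert time_to_steady_state(res) <= cfg.simulation.injection_window + 2

    def test_deterministic_given_seed(self, r500):
        a = simulate_ensemble(r500, n_particles=80, seed=11)
        b = simulate_ensemble(r500, n_particles=80, seed=11)
        assert np.array_equal(a.status, b.status)
        assert np.array_equal(a.t_event, b.t_event, equal_nan=True)
        assert np.array_equal(a.final_positions, b.final_positions)

    def test_conservation_at_all_times(self, strong_result):
        s = strong_result.series
        assert (s.trapped + s.escaped + s.flowing == s.injected).all()
        assert (s.injected.iloc[-1] == strong_result.n_particles)

    def test_seed_variation_small(self, r500):
        a = simulate_ensemble(r500, n_particles=200, seed=1)
        b = simulate_ensemble(r500, n_particles=200, seed=2)
        assert abs(a.efficiency() - b.efficiency()) < 5.0

    def test_trapping_occurs_in_strong_regime(self, strong_result):
        assert strong_result.counts_at(strong_result.horizon)["trapped"] >= 3

    def test_trapped_wall_normal_force_into_wall(self, strong_config,
                                                 strong_result):
        table = build_field_table(strong_config)
        mask = strong_result.status == TRAPPED
        pos = strong_result.final_positions[mask]
        g = table.grad_cartesian(pos)
        r = strong_config.particle.radius
        ch = strong_config.channel
        at_floor = pos[:, 2] <= ch.coil_separation + 1.01 * r
        at_side = np.abs(pos[:, 1]) >= ch.width / 2 - 1.01 * r
        assert np.all(at_floor | at_side)
        assert np.all(g[at_floor, 2] < 0)
        side = at_side & ~at_floor
        assert np.all(g[side, 1] * np.sign(pos[side, 1]) > 0)

    def test_trapped_particles_never_move(self, strong_config):
        res = simulate_ensemble(strong_config, n_particles=15, seed=7)
        # trapped counts are non-decreasing without a release schedule
        assert (np.diff(res.series.trapped) >= 0).all()
        assert (np.diff(res.series.escaped) >= 0).all()

    def test_overdamped_vs_inertial_oracle(self, r500, r500_table):
        start = np.array([-0.3e-3, 5e-6, 40e-6])
        po = integrate_trajectory(r500, start, 0.05, table=r500_table)
        pi = integrate_trajectory(r500, start, 0.05, inertial=True,
                                  table=r500_table)
        dev = np.max(np.linalg.norm(po - pi, axis=1))
        assert dev < r500.particle.diameter


class TestStatistics:
    def test_all_trapped_is_100_percent(self):
        res = fixture_trap_result("constant-rate", efficiency=100.0, n=40)
        assert res.efficiency(res.horizon) == 100.0

    def test_constant_rate_fixture_efficiency_exact(self):
        res = fixture_trap_result("constant-rate", efficiency=80.0, n=100)
        mean, std = trapping_efficiency(res, 60.0)
        assert mean == 80.0 and std == 0.0

    def test_none_trapped(self):
        res = fixture_trap_result("none-trapped", n=50)
        assert res.efficiency(60.0) == 0.0
        assert time_to_steady_state(res) == 1.0

    def test_step_fixture_steady_state_hand_computed(self):
        # 100 particles injected over 10 s, resolving 1 s after injection;
        # trap probability steps 20% -> 80% for events after t = 6 s, so
        # the cumulative resolved fraction settles at 0.5; walking the
        # 1 s grid by hand gives 0.467 at t=10 and 0.500 from t=11 on.
        res = fixture_trap_result("step", n=100, change_time=6.0,
                                  efficiency_before=20.0, efficiency=80.0)
        assert res.efficiency(res.horizon) == pytest.approx(50.0)
        assert time_to_steady_state(res) == 11.0

    def test_efficiency_before_first_injection_raises(self):
        res = fixture_trap_result("none-trapped", n=10)
        with pytest.raises(ValueError, match="no particles injected"):
            res.efficiency(0.0)

    def test_multi_seed_mean_and_std(self):
        runs = [fixture_trap_result("constant-rate", efficiency=e, n=100)
                for e in (70.0, 80.0, 90.0)]
        mean, std = trapping_efficiency(runs, 60.0)
        assert mean == pytest.approx(80.0)
        assert std == pytest.approx(np.std([70, 80, 90]))

    def test_short_horizon_rejected(self):
        res = fixture_trap_result("none-trapped", n=10, horizon=15.0)
        with pytest.raises(ValueError, match="horizon"):
            time_to_steady_state(res)

    def test_result_frame_statuses(self, strong_result):
        df = strong_result.to_frame()
        assert set(df.status) <= {"trapped", "escaped", "flowing"}
        assert len(df) == strong_result.n_particles
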