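import numpy as np
import pytest
from scipy.constants import mu_0

from magsense.config import CoilSpec, default_config, derive_loop_set
from magsense.magnetics import (SingularFieldError, bz_profile, coil_field,
                                coil_resistance, feed_segments, grad_h2,
                                loop_field, power_merit, ripple_metric,
                                segment_field)


def biot_savart_quadrature(radius, current, points, z0=0.0, n=720):
    """Independent oracle: midpoint-rule line integral of dl x r / r^3."""
    th = (np.arange(n) + 0.5) * 2 * np.pi / n
    c = np.column_stack([radius * np.cos(th), radius * np.sin(th),
                         np.full(n, z0)])
    dl = radius * (2 * np.pi / n) * np.column_stack(
        [-np.sin(th), np.cos(th), np.zeros(n)])
    pts = np.atleast_2d(points)
    B = np.zeros_like(pts, dtype=float)
    for i, p in enumerate(pts):
        r = p - c
        rn = np.linalg.norm(r, axis=1)
        B[i] = mu_0 * current / (4 * np.pi) * np.sum(
            np.cross(dl, r) / rn[:, None] ** 3, axis=0)
    return B


def test_loop_center_field():
    B = loop_field(100e-6, 0.4, np.zeros(3))
    assert B[2] == pytest.approx(mu_0 * 0.4 / (2 * 100e-6), rel=1e-12)
    assert B[0] == B[1] == 0.0


def test_zero_current_zero_field():
    pts = np.array([[50e-6, 20e-6, 30e-6], [0, 0, 10e-6]])
    assert np.all(loop_field(120e-6, 0.0, pts) == 0.0)


def test_loop_vs_line_integral_oracle(rng):
    """Elliptic-integral closed form vs 720-point numerical Biot-Savart
    line integral at 100 seeded random points: rel. error < 1e-5."""
    radius, current = 300e-6, 0.4
    rho = rng.uniform(0, 900e-6, 100)
    phi = rng.uniform(0, 2 * np.pi, 100)
    z = rng.uniform(15e-6, 300e-6, 100) * rng.choice([-1, 1], 100)
    pts = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    # keep a safe distance from the filament itself
    keep = (rho - radius) ** 2 + z**2 > (15e-6) ** 2
    pts = pts[keep]
    B = loop_field(radius, current, pts)
    B_ref = biot_savart_quadrature(radius, current, pts)
    scale = np.linalg.norm(B_ref, axis=1)
    assert np.max(np.linalg.norm(B - B_ref, axis=1) / scale) < 1e-5


def test_singularity_raises():
    with pytest.raises(SingularFieldError):
        loop_field(100e-6, 0.4, np.array([100e-6, 0.0, 0.0]))


def test_field_linear_in_current(r500):
    loops = derive_loop_set(r500.coil)
    pts = np.array([[80e-6, -40e-6, 30e-6], [300e-6, 10e-6, 55e-6]])
    b1 = coil_field(loops, pts).B
    loops2 = type(loops)(radii=loops.radii, z=loops.z, current=2 * loops.current,
                         wire_width=loops.wire_width, wire_height=loops.wire_height)
    b2 = coil_field(loops2, pts).B
    assert np.allclose(b2, 2 * b1, rtol=1e-12)


def test_superposition_additivity(r500):
    loops = derive_loop_set(r500.coil)
    pts = np.array([[100e-6, 0.0, 40e-6]])
    total = coil_field(loops, pts).B
    parts = sum(loop_field(r, loops.current, pts, z0=loops.z)
                for r in loops.radii)
    assert np.allclose(total, parts, rtol=1e-12)


def test_divergence_free(r500, rng):
    """Central-difference div B vanishes relative to |B|/h off the wires."""
    loops = derive_loop_set(r500.coil)
    h = 1e-6
    pts = np.column_stack([rng.uniform(-400e-6, 400e-6, 20),
                           rng.uniform(-400e-6, 400e-6, 20),
                           rng.uniform(25e-6, 90e-6, 20)])
    div = np.zeros(len(pts))
    for i in range(3):
        dp = np.zeros(3)
        dp[i] = h
        div += (coil_field(loops, pts + dp).B[:, i]
                - coil_field(loops, pts - dp).B[:, i]) / (2 * h)
    bmag = np.linalg.norm(coil_field(loops, pts).B, axis=1)
    assert np.max(np.abs(div) * h / bmag) < 1e-4


def test_coil_strength_ordering():
    """Larger coils are pointwise at least as strong over the small
    coil's span, and strictly stronger at the centre."""
    z = 30e-6
    xs = np.linspace(-450e-6, 450e-6, 31)
    pts = np.column_stack([xs, np.zeros_like(xs), np.full_like(xs, z)])
    bz = {}
    for name in ("R500", "R1000", "R1500", "R2000"):
        loops = derive_loop_set(default_config(name).coil)
        bz[name] = coil_field(loops, pts).B[:, 2]
    center = len(xs) // 2
    assert (bz["R500"][center] < bz["R1000"][center]
            < bz["R1500"][center] < bz["R2000"][center])
    assert np.all(bz["R2000"] >= bz["R500"])


def test_profile_symmetry_and_z_decay(r500):
    xs = np.linspace(-400e-6, 400e-6, 81)
    prof = bz_profile(r500.coil, "x", fixed={"z": 30e-6}, samples=xs)
    assert np.allclose(prof["Bz"].to_numpy(), prof["Bz"].to_numpy()[::-1],
                       rtol=1e-9)
    zs = np.linspace(10e-6, 300e-6, 40)
    on_axis = bz_profile(r500.coil, "z", fixed={"x": 0.0}, samples=zs)
    assert np.all(np.diff(on_axis["Bz"].to_numpy()) < 0)


def test_ripple_decays_with_height(r500):
    coil = r500.coil
    pitch = coil.pitch
    xs = np.arange(coil.innermost_radius + 2 * pitch,
                   coil.outer_radius - 2 * pitch, 1e-6)
    ripples = []
    for z_um in (5, 10, 15, 20, 25, 30, 35, 40, 45, 50):
        prof = bz_profile(coil, "x", fixed={"z": z_um * 1e-6}, samples=xs,
                          quadrature=True)
        ripples.append(ripple_metric(xs, prof["Bz"].to_numpy(), pitch))
    assert all(a >= b for a, b in zip(ripples, ripples[1:]))
    assert ripples[0] > 10 * ripples[5]  # strong near-field decay


def test_ripple_degenerate_cases():
    xs = np.linspace(0, 200e-6, 201)
    assert ripple_metric(xs, np.full_like(xs, 1.0), 20e-6) == 0.0
    with pytest.raises(ValueError, match="5 wire pitches"):
        ripple_metric(xs[:30], np.ones(30), 20e-6)


def test_segment_infinite_wire_limit():
    B = segment_field([-1.0, 0, 0], [1.0, 0, 0], 0.4, [0.0, 1e-3, 0.0])
    assert B[2] == pytest.approx(mu_0 * 0.4 / (2 * np.pi * 1e-3), rel=1e-5)
    assert abs(B[0]) < 1e-18 and abs(B[1]) < 1e-18


def test_segment_axis_extension_zero():
    B = segment_field([0, 0, 0], [1.0, 0, 0], 0.4, [2.0, 0.0, 0.0])
    assert np.all(B == 0.0)


def test_segment_singularity():
    with pytest.raises(SingularFieldError):
        segment_field([0, 0, 0], [1.0, 0, 0], 0.4, [0.5, 0.0, 0.0])


def test_feed_lines_break_symmetry(r500):
    loops = derive_loop_set(r500.coil)
    ys = np.linspace(-25e-6, 25e-6, 11)
    pts = np.column_stack([np.full_like(ys, 100e-6), ys,
                           np.full_like(ys, 30e-6)])

    def asymmetry(B):
        m = np.linalg.norm(B, axis=1)
        return np.max(np.abs(m - m[::-1])) / np.mean(m)

    plain = asymmetry(coil_field(loops, pts).B)
    fed = asymmetry(coil_field(loops, pts, feeds=feed_segments(r500.coil)).B)
    assert fed > plain + 1e-3


def test_coil_resistance_values():
    # 97 turns, radii 75..1995 µm: sum r = 97*1035 µm
    expected = 2 * np.pi * 97 * 1035e-6 / (59.6e6 * 1e-10)
    assert coil_resistance(default_config("R2000").coil) == pytest.approx(
        expected, rel=1e-12)
    assert expected == pytest.approx(105.8, rel=1e-3)

    single = CoilSpec(outer_radius=1e-3 + 5e-6, n_turns=1)
    assert coil_resistance(single) == pytest.approx(
        2 * np.pi * 1e-3 / (59.6e6 * 1e-10), rel=1e-12)

    wide = CoilSpec(outer_radius=1e-3 + 10e-6, n_turns=1, wire_width=20e-6)
    # same centreline radius, doubled cross-section -> half the resistance
    assert coil_resistance(wide) == pytest.approx(
        coil_resistance(single) / 2, rel=1e-12)


def test_power_merit_scaling_and_ordering(r500, r2000):
    m1 = power_merit(r500.coil, r500.channel, current=0.2)
    m2 = power_merit(r500.coil, r500.channel, current=0.4)
    assert m2.merit == pytest.approx(m1.merit / 2, rel=1e-9)
    assert m2.power == pytest.approx(m2.voltage * 0.4, rel=1e-12)

    small = power_merit(r500.coil, r500.channel)
    large = power_merit(r2000.coil, r2000.channel)
    assert small.merit > large.merit
    assert large.b_max > small.b_max


def test_power_merit_peak_in_interior(r2000):
    coil, ch = r2000.coil, r2000.channel
    loops = derive_loop_set(coil)
    rho = np.linspace(0.0, 1.1 * coil.outer_radius, 600)
    pts = np.column_stack([rho, np.zeros_like(rho),
                           np.full_like(rho, ch.coil_separation)])
    bmag = np.linalg.norm(coil_field(loops, pts).B, axis=1)
    k = int(np.argmax(bmag))
    assert 0 < k < len(rho) - 1
    assert rho[k] < coil.outer_radius


def test_grad_h2_richardson(r500):
    loops = derive_loop_set(r500.coil)
    pts = np.array([[60e-6, 10e-6, 32e-6], [250e-6, -30e-6, 45e-6],
                    [480e-6, 0.0, 35e-6]])
    g1 = grad_h2(loops, pts, step=1e-6)
    g2 = grad_h2(loops, pts, step=0.5e-6)
    rel = np.linalg.norm(g1 - g2, axis=1) / np.linalg.norm(g2, axis=1)
    assert np.max(rel) < 1e-3
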