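# Methods

This note records the model, its assumptions, the numerical choices,
and the known limits of validity, in the order the physics flows through
the package.

## Coordinate and unit conventions

SI units everywhere inside the package. `z = 0` at the top surface of
the coil wires, so the filament plane lies at `z = −h/2` and the channel
floor at `z = K_coil`; the channel axis runs along `x` over the coil
centre and `y` is lateral. Config files use bench units (µm, mA, nm,
µL/min) with unit-suffixed keys; conversion to SI happens on load and is
exactly invertible (the loader divides by integer-valued scale factors,
the writer multiplies and rounds to 9 decimals in file units).

## Coil magnetostatics

**Model.** The spiral is replaced by concentric circular filaments at
radii `(R_out − w/2) − k·(w+s)`, carrying the full coil current in the
wire mid-plane. This is exact superposition — every material present has
µᵣ ≈ 1, so there is no magnetisation feedback and the nanoparticles'
large permeability enters only the force on the particles (one-way
coupling). Each filament's field is the closed-form elliptic-integral
solution; a polygonal Biot–Savart line integral serves as an independent
oracle in the tests (agreement < 1e−5 relative).

**Turn counts.** Only the largest coil's turn count is published (97 at
2 mm outer radius, 20 µm pitch), which places its innermost filament at
75 µm radius. The catalogue fixes that inner radius for all four coils
and fills turns outward: R500→22, R1000→47, R1500→72, R2000→97. This is
a declared convention, chosen for consistency with the one published
count, not a recovered design drawing.

**Wire cross-section.** A single centreline filament per turn is exact
in the far field but misses the near-field "ripple" — the oscillation of
flux density at the wire pitch, which decays like exp(−2πz/pitch). A
3×3 sub-filament quadrature of the 10×10 µm cross-section (current I/9
per sub-filament) resolves it; the ripple metric is the peak-to-peak of
the profile residual about a one-pitch moving average, relative to the
mean field, and decays monotonically over z = 5…50 µm in the tests.

**∇H².** Computed by central differences of the closed-form |H|² with a
1 µm step (Richardson-checked against a 0.5 µm step to < 1e−3); no
symbolic differentiation. For transport, |H|² and its gradient are
pre-tabulated on an axisymmetric (ρ, z) grid (2 µm × 1 µm) covering the
channel footprint and interpolated bilinearly — the field varies on
~30 µm scales inside the channel, so the tabulation error is far below
the other model uncertainties.

**Merit factor.** `Mp = B_max/P` with `P = I²R`,
`R = Σ 2πr_k/(σwh)`. B_max is searched on the channel-floor plane
`z = K_coil` — the field actually available to the fluid — because the
original study does not state its evaluation surface. B ∝ I and P ∝ I²
make Mp ∝ 1/I exactly in this model, which reproduces the qualitative
finding (efficiency collapses at high drive) without any thermal model.

**Feed lines.** Straight-segment Biot–Savart feeds under the coil are
available to reproduce the observation that channel placement relative
to the supply vias matters: the coil-only field is axisymmetric (|B|
mirror-symmetric across the channel), and adding the feeds breaks that
symmetry.

## Channel flow

Steady, fully developed, unidirectional pressure-driven flow: at
Re ≈ 0.33 (50×50 µm channel, 1 µL/min) entrance lengths are ~µm and the
time-derivative and convective terms of the momentum equation are
negligible, so the classical Fourier-series duct solution applies. The
series (51 terms by default, overflow-safe cosh ratios) is scaled so the
integrated flux equals Q exactly via the closed-form flux integral;
against a 201² finite-difference Poisson oracle the profile agrees to
< 0.5 %. The magnetic body force on the (non-magnetic) fluid and
particle back-reaction are set to zero.

The width sweep holds Q fixed at 1 µL/min (so widening the channel slows
the mean flow); holding mean velocity fixed instead is a one-line config
change (`fluid.flow_rate`), and the study being reproduced does not say
which convention it used.

## Particle transport

**Overdamped reduction.** The momentum relaxation time of a 50 nm
magnetite particle is τ = m/(6πηr) ≈ 7e−10 s, so the inertial equation
is a singular perturbation of the slip equation
`dx/dt = u + F_map/(6πηr)`; the package integrates the latter with a
vectorised adaptive Bogacki–Shampine RK23 pair (all particles advanced
on a shared adaptive step, error-controlled per particle with
atol = 1e−8 m, rtol = 1e−5; trapping outcomes are unchanged from
atol = 1e−7 to 1e−9). A full inertial integrator (implicit Radau) exists
as an oracle; trajectories agree to picometres over 0.05 s, far inside
the one-diameter acceptance bound.

**Injection.** Particles enter continuously over the first 10 s at the
inlet (x = −L/2, domain length L = 2.4·R_out), at cross-section
positions sampled with probability proportional to the local axial
velocity (flux weighting — a steady perfusion seeds particles per unit
flux, and it makes "steady state" well defined). Sampling is seeded;
identical (config, n, seed) runs are bit-identical.

**Trapping rule.** A particle is trapped when (i) it is within one
particle radius of the channel floor or a side wall, (ii) the
wall-normal component of the magnetic force points into that wall, and
(iii) the local advection speed is below 1 % of the mean flow. Trapped
particles are frozen and exert no forces on others (dilute limit, no
dipolar interactions). The ceiling cannot trap (the force there points
away from the coil only in sign-reversed geometries). Escape is leaving
the domain through either end. Efficiency at time t is
100·trapped(t)/injected(t); the steady-state time is the earliest time
after which the rolling 1 s resolved-trapping fraction (trapped among
trapped + escaped) stays within ±2 pp of its final value.

**Brownian motion is omitted** — the force model being reproduced is
deterministic. For 50 nm particles the diffusion coefficient
(kT/6πηr ≈ 9 µm²/s) is not negligible against the ~µm/s magnetophoretic
slip, so real ensembles will be noisier than these simulations; adding a
stochastic force would change the quantitative efficiencies and is
deliberately out of scope.

**Magnitudes, honestly.** With the saturated dipole force (the
Clausius–Mossotti factor is ≈ 1 for µᵣ,ₚ = 5000 — the particle cannot
concentrate more field than the contrast limit allows), the peak slip at
the channel floor at K_coil = 30 µm and 400 mA is ≈ 2.7 µm/s against a
6.7 mm/s mean flow. Crossing the coil takes < 1 s, so only particles
entering within ~1 µm of the floor can be captured and the 60 s
efficiencies at the reference operating point are below 1 % for every
coil (R500 0.27 %, R1000 0.47 %, R1500 0.47 %, R2000 0.60 % at
500 × 3 particles; the coil ordering is preserved but adjacent coils are
within sampling noise of each other). High capture fractions of
sub-100 nm particles under these conditions would require a force 3–4
orders of magnitude larger — e.g. an unsaturated χ_eff = µᵣ,ₚ in place
of the Clausius–Mossotti value 3, micron-scale particles (slip ∝ D²), or
~100× slower perfusion. The package keeps the stated force law exact and
reports what it implies; the steady-state timing (≈ 1 s to a stationary
resolved fraction) is insensitive to this magnitude question.

## Capacitive readout

Ideal-conductor electrostatics of a PDMS/channel/PDMS series stack;
with zero wall thickness it reduces exactly to the single-layer plate
formula, and the implementation is tested against an independently
composed harmonic combination of three plate capacitors.

**Wall thickness.** The PDMS wall between electrode and channel is
never published. The default is dPDMS = 5 µm, a typical thin spin-cast
wall that places the baseline capacitance of the 50 µm channel /
50×500 µm electrode zone at 51.1 fF; it is an exposed config parameter
(`stack.wall_thickness_um`), and every capacitance figure shifts with
it.

**Occupancy model.** Default is the parallel-column plug: the
particle-rich phase spans the full gap over a length fraction φ of the
electrodes, so C(φ) is affine in φ. Volumetric alternatives (linear
mixture, Maxwell–Garnett with spherical inclusions) are selectable;
they bound plausible trapped-layer geometries from the other side.
Sensitivity is defined as 100·(C(0) − C(φ))/C(0) — the only definition
consistent with treating a capacitance *drop* as a positive response.

**Dynamic trace.** The coil-schedule trace couples the trapping
simulation (trapped particles release when the coil switches off) to
occupancy through a packing-fraction parameter (default 0.01 particle
volume fraction in the plug). With nm-scale particles at the honest
trapping rates the modelled φ is ~1e−8 and the trace depression is
correspondingly tiny; the trace exists to demonstrate the
trap-and-release dynamics (depression only while the coil is on, prompt
return to baseline), not to predict an absolute ΔC.

## Scope limits

- No magnetic materials, saturation, eddy currents or AC drive; no
  thermal or electromigration limits on coil current.
- No electrode-material dependence of capacitance (ideal conductors);
  no double-layer, electrode polarisation or fringing fields.
- No biomarker binding kinetics — the simulated species is the bare
  MNP, as in the study being reproduced.
- No particle–particle interactions or aggregation; trapped particles
  do not perturb the field or the flow.
- Printed point values of flux density at specific probe positions are
  not reproduced: the original FEM geometry (inner radii of the three
  smaller coils, probe conventions) is under-specified, and the
  filament model gives values ~2× the printed ones at the same nominal
  positions while preserving every published ordering and trend.

## Problem sizes used

The shipped studies run at 500 particles × 3 seeds per design point
(≥ 1500 samples per efficiency estimate, binomial standard error
≤ 1.3 pp at 50 % efficiency and ≤ 0.2 pp at the sub-1 % rates actually
observed), field tables at 2 µm × 1 µm resolution, and 51-term flow
series. A full four-coil acceptance run completes in well under a
minute on one core.
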