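# Methods

thrombosim models venous clotting at three nested levels of description.
This note records the model equations, the parameter choices that matter,
the numerical schemes, and the limits of what the packaged tests
demonstrate.

## 1. Thrombin generation in motionless plasma (`generation`)

Four stiff ODEs for [Xa], [II], [IIa], [ATIII] describe a thrombin
generation assay triggered by a trace of tissue factor:

    d[Xa]/dt    = a1 TF [VIIa]([X]0-[Xa]) + (a2 + a3 phi0)[IIa]([X]0-[Xa])
                  - a4 [Xa][ATIII]
    d[II]/dt    = -(b1[Xa] + k3[IIa] + k4[IIa]^2 + k5[IIa]^3)[II]
    d[IIa]/dt   = +(same conversion) - b2[ATIII][IIa]
    d[ATIII]/dt = -a4[Xa][ATIII] - b2[IIa][ATIII]

The platelet count `phi0` is carried in units of 1e9/L (so `phi0 = 350`
means 350e9 platelets per litre), matching a3's per-density units.  The
trigger path (a1 term) is trimolecular in (TF, VIIa, X).

**Calibration of a3, b2, k4.**  Three of the published constants for this
tier are typographically broken (conflicting units and ambiguous
exponents), and with any literal reading the model ignites through the
quadratic feedback at [IIa] of about 2 nM and converts essentially all
prothrombin within seconds, independent of platelet count — the opposite of
the assay behavior the model was built to reproduce.  The working `table1`
set therefore fixes these three values by calibration against the tier's
quantitative anchors: a thrombin peak of 141.4 nM at `phi0 = 350`, a linear
peak-vs-platelet-count relation (R^2 >= 0.98 over 0..400), and an
increasing, concave (hyperbolic-looking) ETP-vs-count relation.  The
resolved values are a3 = 7e-7 nM^-1(1e9/L)^-1 s^-1, b2 = 3e-4 nM^-1 s^-1,
k4 = 1e-6 nM^-2 s^-1; every other entry is used as published.  The
as-printed values remain loadable as `table1-printed`, with per-entry
source annotations, so both readings are always inspectable.  At these
constants the packaged peak at `phi0 = 350` is 134 nM.

**Numerics.**  LSODA with rtol 1e-8, atol 1e-12 nM; output on a 1 s grid
over a 2000 s horizon.  ETP is the trapezoidal integral of the whole curve;
peak and time-to-peak come from the discrete maximum (sample at 0.5 s or
finer if sub-percent peak accuracy matters — the peak is a few seconds
wide); the lag time is the first upward crossing of 2 nM, a common assay
convention (the threshold is configurable, and no published value exists
for this model).

## 2. Amplification cascade and its lumping (`cascade`)

Six reaction-diffusion equations describe the thrombin-driven activation of
factors Va, VIIIa, XIa, IXa, Xa, with the tenase (VIIIa-IXa) and
prothrombinase (Va-Xa) complexes entering as bilinear terms.  Under
detailed equilibrium of the intermediates the system collapses to one
thrombin equation with cubic production `(K3 T + K4 T^2 + K5 T^3) P`, where
K3, K4, K5 are products/quotients of the elementary rates
(`lump_constants`).

**Supply closure.**  With a constant prothrombin supply the cubic
production term blows up in finite time (already `K4 P T^2` alone), so no
traveling-front speed exists.  Both the full and the lumped systems
therefore use P = max(P0 - T, 0): prothrombin is consumed one-for-one as
thrombin appears, which is exactly the (P0 - T) factor the reduced wave
model of tier 3 carries.  This makes the clotted state finite (just below
P0) and the kinetics genuinely bistable for sinks sigma > K3 P0.

**Default elementary rates.**  Only the lumped K3, K4, K5 are published
(1.5e-5, 8e-6, 1e-10 in nM-s units); the elementary set behind them is
underdetermined.  The packaged default fixes all five inhibition rates to
h = 10 s^-1, sets kh2 = kh1, chooses round activation rates, and solves the
remaining 2x2 system for the two complex rates in closed form
(`rates_from_lumped`; the larger quadratic root keeps both positive).  The
inhibition scale matters: intermediates must relax fast compared with the
front transit time (~2 s) for the reduction to be faithful.  At h = 10 s^-1
the full/lumped front-speed discrepancy is about 12%; at h = 0.1 s^-1 (a
relaxation time of 10 s) it grows to ~75%, which is why the slower scale
was rejected.  `scale_equilibration` accelerates kh1..kh5, kh55 and h1..h5
jointly — a map that provably leaves K3, K4, K5 unchanged — and the
discrepancy falls to 0.3% (x10) and 0.01% (x100), confirming the detailed-
equilibrium limit.

**Front speeds** are measured by linearly fitting the outermost position of
the T = level set (default: half the clotted plateau) over the second half
of the run, after the seed transient.  Both models start from the same
localized thrombin seed with the intermediates placed on the equilibrium
manifold, so no relaxation transient pollutes the fit.

## 3. Reduced 1D thrombin wave (`wave`)

One equation for thrombin T(y, t) on 0 <= y <= 1 mm from the injured wall:

    dT/dt = D d2T/dy2 + (k1 phi0 + k2 Ba(y) + k3 T + k4 T^2 + k5 T^3)(P0 - T)
            - (k6 A0 + a gamma) T

with Ba(y) = B0 exp(-Ba_decay y) the stationary boundary layer of
surface-activated FIXa/FXa.  The published model overloads one symbol for
both the thrombin sink and the Ba decay; here the decay constant is an
independent parameter `Ba_decay`, defaulting to 23.03 mm^-1 so the layer
falls to 1% of its wall value at 0.2 mm, the patch-width scale.

Phi(T, y) is a quartic polynomial, so equilibria come from a dense sign
scan plus bisection (resolution 1e-3 P0, verified against companion-matrix
roots), the propagation integral between the quiescent (T0) and clotted
(T2) states is evaluated from the exact antiderivative, and the shear
threshold gamma* is the bisected root in gamma of that integral with T0, T2
recomputed at every gamma.  A printed closed form for gamma* exists but
contains an undefined velocity factor and holds T2 fixed; it is shipped
only as `shear_threshold_closed_form` (the T0 = 0 approximation) and agrees
exactly with the numeric root when fed the clotted state evaluated at that
root — the criterion itself is always the integral.

Monostable regimes are handled by convention: if only the clotted state is
stable the wave trivially invades (sign +1); if only the quiescent state
survives, it retreats.  This matters because 10-15% above the stall shear
rate the clotted equilibrium is typically destroyed in a saddle-node rather
than merely disfavored.

**Initiation and occlusion.**  T(y, 0) = 0; initiation emerges from the
k2 Ba + k1 phi0 sources.  Initiation time is the first moment max_y T
crosses T* = 200 nM; the occluded fraction at time t is the trapezoid-
weighted measure of {y : T > T*} divided by the vessel diameter.
Platelet-rich plasma is phi0 = 300 (the published experimental density);
normal pooled plasma is taken as phi0 = 0 since no count is published
for it.

**Grid warning.**  The intrinsic front width sqrt(D / reaction rate) is a
few micrometres — far below the 20 um reference grid.  Initiation and
occlusion diagnostics are insensitive to this, but front-speed and
stall-point studies are run on h = 2.5 um with a fixed-step Heun scheme
(`method="rk2"`, step chosen from the diffusion and reaction stability
bounds); on the coarse grid a near-stall front pins to the lattice.

## 4. 2D channel flow with a growing clot (`channel`)

A planar channel (height H = 1 mm = the vessel diameter, default length
8 mm; desk-scale studies use 4 mm) with a TF patch of width 0.2 mm on the
bottom wall.  The tier couples:

* **Quasi-steady Stokes-Brinkman flow** on a MAC staggered grid, solved as
  one sparse saddle-point system with Dirichlet pressure at inlet/outlet
  and no-slip walls.  Plasma inertia is neglected: the Reynolds number is
  ~2 and the flow relaxes in milliseconds while the clot evolves over
  minutes, so the flow is re-solved only when the drag field has moved by
  more than 1%.  The inlet pressure 2 L gamma mu / H imposes a clot-free
  wall shear of exactly gamma in the plane channel (the cylindrical form
  4 L gamma mu / D is retained for reference).  The discrete solution
  reproduces the Poiseuille parabola to 0.2% and the configured shear to
  well under 2% (the wall-shear readout 2 u0 / h is exact for the
  mirror-ghost discretization).
* **Transport-reaction** of P, T, Ba, A, Fg, F (first-order upwind
  advection, central diffusion, Patankar semi-implicit reactions — all
  concentrations provably nonnegative without clipping), immobile fibrin
  polymer Fp, and two platelet classes phi_f, phi_c whose face fluxes are
  scaled by the saturating mobility tanh(pi(1 - phi/phi_max)).  Inlet
  Dirichlet for P, A, Fg, phi_f; zero flux elsewhere.
* **The TF patch**: a saturating Robin flux
  alpha1 (B0 - Ba)/(1 + beta1 (B0 - Ba)) feeds Ba through the patch faces,
  integrated implicitly per cell (an exact quadratic solve, unconditionally
  stable, capped at B0).  With the published alpha1 = 7.7e4 the patch is
  effectively saturated at B0; the printed units of alpha1 are inconsistent
  with the flux balance and the value is used as a number, exposed for
  sensitivity runs.  Bound platelets are held at phi_c0 on the patch
  (skipped entirely when phi_c0 = 0).
* **Clot drag**: the Davies fibrous-media law
  1/K_f = (16/alpha^2) Fp~^{3/2}(1 + 56 Fp~^3)(phi_max + phi_c)/(phi_max - phi_c),
  Fp~ = min(0.7, Fp/7000), read as 16/alpha^2 (the printed "16 alpha 2" is
  dimensionally consistent only as a division; the reference isosurface
  1/K_f = 10 mm^-2 is then reachable).

**Events.**  Initiation is declared when 1/K_f reaches 10 mm^-2 near the
patch (the published isosurface level; configurable) — at the Davies law's
steepness this corresponds to only ~0.3 nM of fibrin polymer, yet a Darcy
screening length comparable to the channel height.  Occlusion requires a
clot band at that level spanning the full height plus a flow rate below 1%
of the clot-free value.

**Time stepping.**  dt = min(0.005 s, 0.8 h/u_max, 0.2 h^2/D).  Desk-scale
studies use h = 0.04 mm and a 4 mm channel with the patch at 1 mm; the
reference resolution h = 0.02 mm is used for convergence checks only, since
the cost scales with gamma (CFL) as well as with the cell count.

**What the 2D tier shows, and does not.**  It reproduces the qualitative
gating: clotting initiation is fast (seconds to tens of seconds) below a
critical shear rate, slows steeply near it, and is absent above it
(e.g. NPP: initiation at 11 s at gamma = 10, 51 s at gamma = 25, none by
150 s at gamma = 60); a critical TF patch width separates clotting from
non-clotting at fixed shear.  The platelet effect acts on the
ignition/occlusion stage, not on the slow pre-ignition fibrin accumulation
that trips the 1/K_f = 10 detector: below the thrombin-ignition shear
threshold, clot-bound platelets recruit free ones and the vessel occludes —
at a critical shear rate of 25-30 1/s for platelet-rich plasma against
20-25 1/s for platelet-poor plasma (PRP occludes at gamma = 25 in 109 s,
within a factor ~1.5 of the 3D reference occlusion time at the same shear),
while above it the recruited platelets are washed downstream before
thrombin reaches the nanomolar level recruitment needs, and the two plasmas
become indistinguishable.  Absolute occlusion times of the 3D cylindrical
experiments are not desk-reproducible: geometry factors, the boundary-layer
resolution (0.009 mm wall cells in 3D vs 0.04 mm here) and the neglected
inertia all shift the clock.  Red blood cells, non-Newtonian rheology,
pulsatility and wall elasticity are outside the model by construction.

## 5. Experiments, parameters, CLI

All constants live in named, unit- and source-annotated parameter sets
(`table1`, `table1-printed`, `table2`, `table2-wave`) that validate against
per-tier schemas, reject unknown keys, and round-trip through YAML/JSON.
Canned sweeps (`fig3`, `fig6`, `fig7`, `fig8`) mirror the four quantitative
studies and emit a stable long-format table (CSV/JSON) in which every row
carries the parameter-set name it used; failed runs become error rows
without aborting the sweep.  Sweeps are deterministic — identical specs
yield byte-identical exports.  The `thrombosim` CLI wraps single runs of
each tier plus the sweeps.

## 6. Known limitations

* The tier-1 calibration fixes three broken constants against two printed
  anchors and two trend constraints; other (a3, b2, k4) triples may fit
  equally well.  The peak lands 5% below the 141.4 nM anchor.
* gamma* from the wave criterion is O(600 s^-1) with the published removal
  coefficient a = 5.6e-3 s mm^-1 — an order of magnitude above measured
  venous thresholds; only its trends (in phi0, P0, A0) are meaningful.
* The platelet count enters the 2D tier only through clot platelets
  recruited after thrombin appears, so the NPP/PRP separation shows in the
  occlusion threshold and occlusion times, not in the pre-ignition
  initiation detector, which is platelet-blind at desk resolution.
* First-order upwinding is diffusive; sharp clot boundaries are smeared
  over a few cells at desk resolution.
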