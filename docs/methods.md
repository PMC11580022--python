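# Methods

Models, parameter defaults, numerical choices and known limitations of
the memtide package. Units are fixed package-wide: pN, µm, s (tension
pN/µm; bending modulus κ pN·µm; 2D viscosity pN·s/µm; 3D viscosity
pN·s/µm²; density pN·s²/µm⁴). Bead sizes are quoted in the field as
diameters; every API that needs one takes a radius and says so, to avoid
a silent factor-of-two error.

## Tether mechanics

A membrane tether behaves as a fluid lipid nanotube: minimizing bending
plus tension energy gives the holding force f = 2π√(2κσ) and radius
r = 2πκ/f = √(κ/(2σ)). All conversions in `mechanics` are exact algebraic
inverses of one another (round-trip tested to 1e−12 relative). The
default bending modulus κ = 0.27 pN·µm is the neuronal growth-cone value,
within the 0.18–0.32 pN·µm range reported across cell types. The
force–tension relation assumes cytoskeleton-free tethers, which holds for
the cell types this package targets but must be re-checked for cells with
actin-filled protrusions.

Trap stiffness is calibrated hydrodynamically: oscillating the stage
sinusoidally drags fluid past the trapped bead with peak force
f_hydro = γ·ω_d·A_pp/2 (γ = 6πηR, Stokes drag), and k_trap is the inverse
slope of bead amplitude versus f_hydro. This is valid only in the
low-frequency regime ω_d·γ/k_trap ≪ 1; `TrapCalibration` warns when the
ratio exceeds 0.1. Inertia is negligible throughout (Re ~ 1e−6 for µm
beads at µm/s in water).

The force noise floor is the bead-tracking RMS error times the trap
stiffness — 17 nm × 75 pN/µm ≈ 1.3 pN per sample at the default settings
— and propagates to a tension detectability threshold
δσ = f·δf/(4π²κ) at resting force f (≈1.2 pN/µm at f = 10 pN). This is a
single-sample threshold; trace averaging in a real analysis detects
smaller changes, so it is deliberately conservative.

Step-extension responses are normalized to f̃ = (f−f₀)/(f_max−f₀) and fit
with 1 − a₁e^(−t/τ₁) − a₂e^(−t/τ₂), amplitudes constrained non-negative
with a₁+a₂ ≤ 1.05 (the 5% headroom absorbs noise at the endpoints),
initialized from a single-exponential half-rise time. Time constants are
reported sorted ascending. The slower constant (~1 s for typical tethers)
is the "tether lag" reused by the probe-response and activity models.

## Tension diffusion

With immobile obstacles hindering membrane flow, small tension
perturbations obey ∂σ/∂t = D_σ∇²σ + E·Q(t)·δ²(x), where Q(t) =
2π·r_t·dL/dt is the membrane-area extraction rate of a pulling tether
with length program L(t). The pull protocol defaults to the double-tether
program: extend at 1 µm/s for 40 µm, hold 30 s, retract at 1 µm/s
(110 s total). Q uses a fixed tether radius (default: the radius at a
typical 10 pN holding force, ~0.17 µm) rather than coupling r_t to the
local σ; this keeps the forward model linear, and the coupling is noted
as an extension point.

Because L(t) is piecewise linear, Q is piecewise constant and the
infinite-plane solution is closed-form: with β = d²/(4D_σ) and
s = t − t′, each constant-Q segment contributes
(E·Q/4πD_σ)·[E1(β/s_hi) − E1(β/s_lo)] with E1 the exponential integral.
No quadrature is involved, so there are no convergence failures and the
forward model is cheap enough to sit inside a fitting loop.

The second backend is a conservative finite-volume Crank–Nicolson solver
on a radial grid (cell faces at multiples of dr, source deposited in the
innermost cell, no-flux boundaries; defaults dr = 0.02 µm, dt = 0.02 s).
It is exactly area-conserving by construction and agrees with the
analytic kernel to ~1e−5 of peak amplitude for d ≥ 1 µm, far inside the
1% tolerance asserted in the tests. It also provides the bounded
`ReflectingDisc` geometry (default radius 5 µm, a terminal-scale domain):
the infinite plane and the reflecting disc bracket the physical
situation, and on a bounded domain extracted area accumulates, so probe
responses are much larger than on the plane — the reason a pull on a
~10 µm terminal is easily sensed when D_σ is large.

Darcy permeability uses the random-cylinder-array form
f(φ) = (−ln φ − 1.476 + 2φ − 1.774φ² + 4.076φ³)/(8φ), restricted to
0 < φ ≤ 0.3 where the dilute-array expansion is meaningful. The obstacle
radius default a = 2.3 nm is a *calibration*: it is the single value that
makes the permeabilities implied by the three measured obstacle fractions
(φ = 0.093, 0.096, 0.150) mutually consistent with published k values
within 5%; it is not an independently measured quantity. The obstacle
fraction itself is the measured immobile membrane-protein fraction times
an assumed 25% transmembrane-protein area coverage.

E (2D stretch modulus) and η (membrane viscosity) are not measured by the
experiments this package models; the defaults E = 40 pN/µm and
η = 1e−3 pN·s/µm are order-of-magnitude effective values for cell plasma
membranes, where membrane reservoirs buffer the bare lipid stretch
modulus down by orders of magnitude. E = 40 pN/µm also makes a 10% area
addition drop tension by ~40% of a 10 pN/µm resting value, matching the
stimulation phenomenology. Quantities compared across cell types
(permeability ratios, D_σ fold differences) are constructed so E, η and a
cancel. Scenario presets set D_σ directly (24 µm²/s for the fast
bipolar regime, 0.01 for chromaffin, 0.024 for the slow literature
reference) rather than deriving it from E·k/η, because with nm²-scale
permeabilities no plausible (E, η) pair produces the fast observed
regime — which is precisely the scientific point the presets encode.

t_sense is the first threshold crossing of the probe response, measured
from protocol start, with linear interpolation between samples; the
default threshold is the δσ noise floor above. Under pure diffusion
t_sense scales as d² (the tests assert log–log slope 2 ± 0.1). D_σ
fitting runs a coarse log-grid search (10⁻²–10³ µm²/s) followed by
bounded least squares on log₁₀D; a fit explaining < 5% of the variance of
a zero model is flagged non-identifiable rather than returned silently
(the slow-diffusion regime at ~8 µm distances carries no information
within a 110 s protocol). The probe-tether first-order lag (~1 s) is
applied by synthetic-data generation and can be included in fits via
`lag_tau`; it is off by default in fitting.

## FRAP

Recovery curves are normalized with F = (f − f_o)/(f_pre − f_o) and fit
to the hyperbolic model F(t) = (F₀ + F∞·t/t½)/(1 + t/t½), whose midpoint
identity F(t½) = (F₀+F∞)/2 defines the half-time. Initialization is
deterministic (F₀ from the first postbleach point, F∞ from the tail
mean, t½ from the first midpoint crossing). D_t = A_bleach/(4t½) with
A_bleach defaulting to 2.04 µm² (a 2.4 µm bleach spot through a ~0.85 µm
optical section; whether an effective circular area would be more
appropriate is unresolved, so the rectangle product is the configurable
default). The mobile fraction is F∞ − F₀; values outside [0, 1] are
clipped with a warning. The hyperbolic form assumes a single mobile
species and no reaction binding; bleach-profile deconvolution and
multi-component diffusion are out of scope.

## Tether drag

The tracked cell outline is interpolated with a periodic cubic spline;
the smoothing condition defaults to the squared per-point tracking error
(17 nm)² so the tangent is not slaved to point jitter. θ is the angle
between the contour normal at the spline point nearest the tether base
and the base→bead segment, folded into [0, π/2] (the force decomposition
uses |sinθ|; drag direction is tracked separately by the kinematics).
A base farther than 0.5 µm from the contour raises a geometry error.

Base kinematics smooth the coordinate traces with a discrete Gaussian
(σ = 1 s by default; "width" may alternatively be interpreted as FWHM via
a flag, since the convention is ambiguous), truncated at 4σ and
reflect-padded, then sum frame-to-frame displacements and differentiate
centrally. Smoothing positions *before* the distance sum matters: summing
raw jittered displacements of a stationary base accumulates a
Rayleigh-mean drift (~0.9 µm/s at 17 nm / 30 Hz) that no amount of
after-the-fact smoothing removes, whereas the smoothed-coordinate route
keeps a stationary base well below the 0.5 µm/s velocity noise floor.

Stalls are maximal runs with |v_t| < 0.5 µm/s, each reporting its peak
tangential force. Segments shorter than three smoothing widths are
flagged `short` (boundary placement is uncertain at that scale) rather
than merged or dropped; the synthetic stick-slip generator holds each
stall's peak force for a 1.5 s plateau so that ±1 s boundary blur cannot
clip the programmed peak.

## Activity

The exo/endocytosis model is a deliberately minimal linear area balance:
exocytosis ramps in a fixed area fraction (default 10% of terminal area
over 0.25 s); endocytosis retrieves efficiency × added area with
first-order kinetics (default τ = 10 s, placing 95% recovery at ~30 s,
consistent with tension recovery over tens of seconds); tension is
σ₀ − E·(added − endocytosed) filtered through the ~1 s tether lag. Both
branches of the ODE are solved in closed form. Dose→efficiency for the
endocytosis blocker MiTMAB is a lookup (0, 10, 30 µM → 1.0, 0.49, 0.29),
not a pharmacological model.

The recovered fraction is (σ(t_on+50 s) − σ_min)/(σ_baseline − σ_min),
clipped to [0, 1.1], computed on the raw trace by default with optional
Gaussian pre-smoothing and a configurable baseline window (the exact
convention used upstream of the printed values is not documented, so
both are exposed). It is affine-invariant and approximately equals the
endocytic efficiency at the default time constants. A trace whose dip
does not exceed the noise floor raises an undefined-statistic error
rather than returning a number.

## Synthetic data

Generators emulate: probe-tether force traces (forward diffusion model +
tether lag + tracking noise, per-sample force noise = k_trap × 17 nm ≈
1.3 pN), FRAP curves on the two-phase acquisition schedule (30 frames at
1.29 s, then per-minute frames), drag tracks on a circular cell with
programmed stick-slip force profiles, and coupled calcium/tension
stimulation traces at 1 frame/s per channel. All randomness flows from a
single integer seed through named child streams, so output is
bit-identical across runs and platforms. What they do **not** emulate:
image formation (tracking noise is injected directly on coordinates),
drift (optional linear term only), heterogeneous obstacle spatial
arrangements, resting-tension variability between cells, and stochastic
single-vesicle fusion. Passing recovery tests therefore demonstrate
correctness of the analysis chain under the stated noise model, not
robustness to every artifact of real microscopy data.

## Problem sizes

Default test and pipeline sizes: 30 Hz force traces over ~130 s (~3900
samples); finite-volume grids of 2–4k radial cells and ~5k time steps;
20 seeded refits for the D_σ recovery suite; 12-combination FRAP grids;
~800-frame drag tracks with 72-point contours. The full test suite runs
in well under a minute on one CPU.
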