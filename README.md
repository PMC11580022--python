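# memtide

Membrane tension propagation analysis for cell-surface mechanics
experiments: optical-trap tether pulling, diffusive tension-propagation
modelling, FRAP-derived obstacle fractions, tether-drag kinematics, and
activity-driven tension dynamics. Built for quantitative cell biologists
and membrane biophysicists analysing bead/force/fluorescence time series
from tether experiments — and for testing those analysis chains end to end
on synthetic data with known ground truth.

## The science

A thin membrane tether pulled from a cell by a trapped bead reports the
local membrane tension σ (pN/µm) through its holding force,

    f = 2π √(2κσ),        κ ≈ 0.27 pN·µm (bending modulus),

with tether radius r = 2πκ/f. Whether a tension perturbation created at
one point (e.g. by extending a second, "pulling" tether, or by a burst of
exocytosis) is felt elsewhere depends on how easily the membrane flows
past immobile, cytoskeleton-anchored transmembrane obstacles. For a random
array of obstacles of radius *a* covering an area fraction φ, tension
obeys a diffusion equation with

    D_σ = E·k/η,    k = a²·f(φ),
    f(φ) = (−ln φ − 1.476 + 2φ − 1.774φ² + 4.076φ³)/(8φ),

where E is the 2D stretch modulus, η the 2D membrane viscosity and k the
Darcy permeability. The package implements:

- **mechanics** — force/tension/radius conversions, hydrodynamic trap
  calibration (k_trap from A_bead vs f_hydro), Reynolds-number checks,
  double-exponential step-response fits, fluorescence-based tension
  (σ ∝ 1/I²);
- **diffusion** — the tension-diffusion forward model (exact
  exponential-integral kernel on the plane, conservative finite-volume
  solver on a bounded disc), t_sense and amplitude–distance readouts, and
  least-squares D_σ fitting;
- **frap** — recovery normalization, the hyperbolic fit
  F(t) = (F₀ + F∞·t/t½)/(1 + t/t½), D_t = A_bleach/(4t½), mobile/immobile
  fractions, and the bridge φ = immobile × 0.25;
- **drag** — tether-base angle θ from tracked contours, tangential force
  f∥ = f·sinθ, Gaussian-smoothed kinematics, and stall detection
  (|v| < 0.5 µm/s);
- **activity** — ΔF/F₀ calcium processing, a linear exo/endocytosis
  area-balance tension model, the recovered-fraction statistic, and
  calcium–tension anticorrelation;
- **synth** — seeded generators for all of the above, with scenario
  presets for fast-flow neuronal terminals, somas, slow-flow chromaffin
  cells, and the slow literature reference value.

## Worked example

Run the full synthetic pipeline (generate → analyse all four experiment
types) at a fixed seed:

```
$ memtide run --seed 1
```

Key numbers from the output (seed 1):

```json
{
  "double_tether": {
    "true_D_sigma_um2_s": 24.0,
    "fit_D_sigma_um2_s": 25.79,
    "identifiable": true
  },
  "frap": {
    "true_t_half_s": 26.84,
    "fit_t_half_s": 27.72,
    "fit_D_t_um2_s": 0.0184,
    "immobile_fraction": 0.408
  },
  "drag": {
    "stall_peaks_pN": [8.55, 24.26],
    "true_stall_peaks_pN": [8.0, 24.0]
  },
  "stimulus": {
    "recovered_fraction": 1.03,
    "calcium_tension_r": -0.70
  }
}
```

Reading this: a probe trace generated with tension diffusivity
D_σ = 24 µm²/s is refit to within ~7% despite 1.3 pN per-sample force
noise; the FRAP half-time (truth 26.8 s, i.e. D_t = 0.019 µm²/s for the
2.04 µm² bleach area) is recovered within fit error; the two programmed
stick-slip stall peaks (8 and 24 pN — terminal-like vs chromaffin-like
resistance) are both detected; and with full endocytic efficiency the
stimulus-induced tension drop recovers completely within 50 s while
calcium and tension anticorrelate.

Individual steps are available as subcommands (`memtide gen`,
`simulate-probe`, `fit-dsigma`, `frap-fit`, `drag-analyze`,
`stim-analyze`, `calibrate-trap`) or directly from Python via
`memtide.mechanics`, `memtide.diffusion`, etc.

## Layout

```
src/memtide/     library modules (mechanics, diffusion, frap, drag,
                 activity, synth, io, config, cli)
tests/           pytest suite (unit, property and end-to-end tests)
scripts/         acceptance script
docs/methods.md  model assumptions, parameter defaults, numerics
```
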