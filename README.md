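# uteroacoustics

Computational modelling of fetal exposure to external airborne sound.

External noise — traffic, machinery, music, occupational noise — reaches the
fetus after crossing the air/abdomen interface and propagating through
maternal tissue. This package quantifies that transmission by solving the
time-harmonic **Helmholtz transmission problem** across nested
piecewise-homogeneous acoustic regions (air exterior ⊃ abdomen ⊃ {uterus,
spine}) for a unit-amplitude incident plane wave, and reports in-utero sound
pressure levels across the human audio range. It is aimed at researchers in
computational bioacoustics and fetal-medicine acoustics who need transfer
characteristics and field maps at audio frequencies, where wavelengths are
comparable to anatomical dimensions and volumetric solvers suffer pollution
effects.

## What is inside

* **`media`** — tissue acoustic material models. Each region is a fluid with
  sound speed `c0`, density `ρ`, and power-law attenuation
  `α(f) = α_ref (f/1 MHz)^b` (Np/m, `b = 1` for soft tissue and bone, `b = 2`
  for water-like amniotic fluid). Soft-tissue attenuation at audio
  frequencies derives from the viscoelastic loss tangent:
  `α(f) = (2π√cos δ / c0) sin(δ/2) f` with `δ = arctan(tan δ)`. Complex
  wavenumbers `k = 2πf/c0 + iα(f)` (time convention `e^{−iωt}`, so lossy
  media decay). Ships the four-tissue material library plus air.
* **`phantom`** — synthetic nested phantoms standing in for MRI-derived
  anatomy: watertight icosphere/ellipsoid surfaces at anatomical scale,
  meshed by an elements-per-wavelength rule; interior Cartesian evaluation
  grids with a 0.5-steradian near-surface exclusion; volume centroids
  ("barycentres"); Gmsh `.msh` and STL IO.
* **`layered_sphere`** — analytical plane-wave transmission through
  concentric layered spheres (spherical-harmonic series with complex-argument
  radial functions), the validation oracle and fast full-audio-range solver.
* **`bem`** — a dense multi-domain **PMCHWT** boundary-element solver:
  P1 Galerkin elements, Maue-regularised hypersingular operator, analytic
  static integrals for singular element pairs, unrestarted GMRES
  (tolerance 1e-4), interior field evaluation via potential operators.
* **`metrics` / `sweeps`** — the exposure metrics and sweep protocol:
  12th-octave band grids anchored at 1 kHz; impact SPL
  `L_RMS = 20 log₁₀ √(N⁻¹ Σ|p_i|²)` (ISO 10052 §3.7 spatial RMS); worst-case
  `L_∞ = 20 log₁₀ max|p_i|`; complex barycentre pressure. SPL is re 1 Pa, so
  0 dB means "equal to the incident wave".
* **`auralize`** — turns the barycentre transfer function into a causal FIR
  filter (spline-interpolated magnitude/unwrapped phase on 16 385 points at
  44.1 kHz, 200-sample linearising delay, least-squares fit) and convolves
  WAV audio for listening impressions.

## Worked example

The canonical benchmark is two concentric spheres — a 0.25 m
abdominal-tissue "abdomen" around a 0.15 m amniotic-fluid "uterus" in air —
for which the analytical series is exact:

```python
import numpy as np
from uteroacoustics.media import get_medium
from uteroacoustics.metrics import twelfth_octave_grid, highlight_resonances
from uteroacoustics.phantom import nested_sphere_phantom
from uteroacoustics.sweeps import run_sweep

topo = nested_sphere_phantom(0.25, 0.15, elements_per_wavelength=5.0, f=1000.0)
sweep = run_sweep(topo, twelfth_octave_grid(20.0, 20000.0), solver="analytic")
peaks = highlight_resonances(sweep.frequencies, sweep.spl_rms, n=2)
lo = sweep.frequencies < 1000.0
print(np.round(peaks, 1), round(sweep.spl_rms[lo].min(), 2))
```

prints

```
[2996.6 4237.9] -9.43
```

i.e. the sampled inner-sphere RMS-SPL curve peaks at the 2 996.6 Hz and
4 237.9 Hz bands — the lowest cavity modes of the tissue ball, whose
continuous-frequency resonances sit at 3.03 kHz and (strongest upper mode)
8.67 kHz — and the response below 1 kHz stays within 9.4 dB of the incident
level, dipping towards the first antiresonance after being essentially flat
(> −6 dB) up to ~530 Hz.

Running the same phantom with the dense BEM (meshed at 5 triangular elements
per wavelength, GMRES tolerance 1e-4) against the analytical reference:

```bash
python analysis/03_validate_bem.py
```

reports a maximum RMS-SPL disagreement of **0.11 dB** over 12th-octave
centres up to 2 kHz and a maximum relative ℓ2 error of the pressure
magnitudes of **1.4%** at 4.5 elements per wavelength — within the 0.5 dB
and 7.5% agreement targets of the validation protocol.

The numbered drivers under `analysis/` run the full study sequence
(material tables → exposure sweeps → BEM validation → field maps →
auralization), writing tables under `results/`.

## Command line

```bash
uteroacoustics sweep            --config cfg.yaml        # exposure sweep CSV
uteroacoustics validate-spheres --config cfg.yaml        # BEM vs analytic
uteroacoustics map --frequency 3000 --axis z             # SPL plane map
uteroacoustics auralize --response sweep.csv --wav-in in.wav --wav-out out.wav
```

## Limitations

Compressional waves only (no shear-wave conversion or viscoelastic BEM); the
dense solver targets desk-scale problems (≲ 3 kHz full-phantom meshes) with
the analytical series covering the remaining audio range on spherical
geometries; phantoms are idealised nested spheres/ellipsoids, not
subject-specific anatomy. See `docs/methods.md` for the model, numerical
choices and their rationale.
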