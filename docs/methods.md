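# Methods

This note records the physical model, the numerical choices and their
rationale, what the synthetic phantoms do and do not emulate, and the known
limitations. Everything quantitative stated here is computed by the test
suite or the analysis drivers; nothing is quoted from elsewhere.

## Physical model

Sound propagation is modelled as time-harmonic linear acoustics in
piecewise-homogeneous fluid regions: the unbounded air exterior, the
abdominal soft-tissue region, and the uterine region (optionally a spine
region as a sibling inclusion). In each region the pressure satisfies the
Helmholtz equation with the region's complex wavenumber; across each
interface the pressure `p` and the normal velocity — proportional to
`(1/ρ) ∂p/∂n` — are continuous. The exterior field satisfies the Sommerfeld
radiation condition; the excitation is a unit-amplitude plane wave
(1 Pa), so a reported SPL re 1 Pa of 0 dB means "as loud as the incident
wave" and positive values indicate constructive build-up.

**Time convention.** Fields oscillate as `e^{−iωt}`; outgoing waves are
`e^{+ikr}/r` and lossy media have `Im k > 0` so that plane waves decay along
propagation. With the opposite (engineering) convention every sign of the
imaginary part flips; the decay requirement is the invariant contract, and
the library enforces it (`media.complex_wavenumber`).

### Materials

Each medium carries `(c0, ρ, α_ref, b)` with attenuation
`α(f) = α_ref (f / 1 MHz)^b` in Np/m. The bundled library:

| region | c0 (m/s) | ρ (kg/m³) | α at 1 MHz (Np/m) | b |
|---|---|---|---|---|
| Abdominal tissue | 1489 | 950 | 0.1 | 1 |
| Spine bone | 4020 | 2700 | 0.2 | 1 |
| Uterine tissue (high-attenuation uterus) | 1500 | 1000 | 585.3 | 1 |
| Amniotic fluid (low-attenuation uterus) | 1500 | 1000 | 15e-3 | 2 |
| Air (exterior) | 343 | 1.2 | 0 | – |

Air is not part of the published table; the standard dry-air values are
used and air absorption is neglected (fractions of a dB over metre-scale
paths at audio frequencies).

Soft-tissue attenuation at audio frequencies is poorly characterised
directly; it is derived from quasi-static viscoelastic measurements through
the loss tangent of the complex bulk modulus. With loss angle
`δ = arctan(tan δ)` the attenuation is exactly linear in frequency,
`α(f) = (2π√cos δ / c0) sin(δ/2) f`. Evaluating this at `c0 = 1500 m/s`,
`tan δ = 0.3` (muscle at ~100 Hz) gives 595.3 Np/m at 1 MHz, close to but
not equal to the library's 585.3 Np/m entry for uterine tissue; the
parameter set behind the published constant is not recoverable, so the
library keeps the published constant and the loss-tangent path is exposed
separately (`alpha_from_loss_tangent`). The two attenuation models
(uterine tissue vs amniotic fluid) bracket the real uterus as
worst-case/best-case damping scenarios.

## Phantoms (synthetic anatomy)

The study-scale anatomy is emulated by nested closed triangulated surfaces:
concentric icospheres (abdomen 0.25 m radius, uterus 0.15 m — the benchmark
configuration with an exact analytical reference), optionally with an
ellipsoidal spine sibling. What the phantoms deliberately do **not**
emulate: non-spherical subject-specific shape, fetal body substructure,
truncated torso boundaries, tissue heterogeneity. Consequently passing
validation on phantoms demonstrates correctness of the *solvers and
metrics*, not of any subject-specific prediction; anatomical conclusions
require anatomical meshes, which the pipeline accepts through the same
Gmsh/STL interfaces.

**Mesh density** follows an elements-per-wavelength rule: each surface is
refined until its mean edge length is at most `λ_min / epw` (default
`epw = 5`), where `λ_min` is the wavelength in the *slower-sounding*
adjacent medium — air for the outer surface, tissue for interior ones. This
is the conservative reading of "density varied with the media on both
sides"; it is what makes sub-0.5 dB agreement with the analytical reference
achievable, because the air-side field oscillates on the 17 cm scale at
2 kHz. A floor of 2 icosphere subdivisions (320 triangles) preserves
geometric sphericity at low frequencies where the wavelength rule alone
would allow a crude polyhedron; a ceiling of 8 subdivisions guards against
accidentally requesting beyond-desk-scale meshes.

**Evaluation grids.** Exposure metrics are computed on an axis-aligned
Cartesian grid inside the target region (default spacing: 1/20 of the
region's bounding-box extent, ~1000–3000 points for the benchmark uterus).
Points are kept if (a) the generalised winding number says they are inside
and (b) no single triangle subtends more than 0.5 sr at them. The
per-triangle maximum is a deliberate interpretation of the near-surface
exclusion: boundary-element potentials degrade per nearby element, and the
rule is monotone in the threshold and cheap to audit. The exclusion is
evaluated against a *fixed reference meshing* of the region (subdivision 3
for spheres) so that metric values do not depend on the solver's per-band
mesh density; for BEM bands, points additionally falling in the exclusion
zone of that band's own coarser mesh are dropped from the metrics rather
than extrapolated.

**Barycentre** means the centroid of the enclosed volume (divergence
theorem over the surface), not the vertex mean — independent of mesh
grading.

## Analytical layered-sphere solution

For concentric spherical layers the field in every region is expanded as
`Σ i^n (2n+1) P_n(cos θ) [A_n j_n(k_m r) + B_n h_n^{(1)}(k_m r)]` with θ
measured from the propagation direction. Per order, interface continuity of
`p` and `(1/ρ) ∂p/∂r` yields a small linear system (2L unknowns for L
interfaces); columns are magnitude-equilibrated before solving because
`j_n`/`h_n` diverge in opposite directions once `n > |k|r`. Truncation
`N = ⌈max_m Re(k_m) a⌉ + 12` (a Wiscombe-style margin; raising N by 8
changes fields by < 1e-6, a tested invariant). Complex arguments (lossy
media) use scipy's spherical Bessel routines; audio-range attenuation keeps
`|Im(kr)| ≲ 2`, far from overflow. Points exactly on an interface evaluate
from the inner side. Verified against machine-precision interface
residuals, an independently coded sound-hard-sphere series (near-rigid
limit), and the optical-theorem energy balance in the lossless case.

## Boundary-element solver

The multi-domain PMCHWT formulation is derived by combining, per interface,
the Calderón trace identities of the two adjacent regions so that the
unknown jump terms cancel; the unknowns are the continuous traces
`(φ, w) = (p, (1/ρ)∂p/∂n)` per interface, and each region contributes
single-layer, double-layer, adjoint double-layer and hypersingular operator
blocks with its own wavenumber (see the `bem` module docstring for the
block equations). Incident-trace operator terms on the exterior interface
fold into plain right-hand sides via the interior Calderón identity of the
entire incident wave.

Discretisation choices:

* continuous piecewise-linear (P1) elements with Galerkin testing;
* hypersingular operator in the integration-by-parts (Maue) form
  `∬ G (curl_Γ ψ · curl_Γ φ) − k² ∬ G (n·n) ψφ`, which needs only the
  weakly singular kernel;
* regular element pairs: 6-point symmetric Gauss rules on both triangles;
* touching pairs (shared vertex/edge/self) and near pairs (centroid
  distance below 1.5× the summed circumradii): a hybrid scheme — the
  static `1/(4πr)` kernel parts are integrated in closed form over the
  inner triangle (line-integral reductions of the potential-of-a-triangle
  formulas, unit-tested to machine precision against refined quadrature)
  and the bounded oscillatory remainders `(e^{ikr}−1)/4πr` etc. by a
  12-point rule, under a 7-point outer rule;
* the operator implementation is validated by the plane-wave Calderón
  identities `V g_N − K g_D = g_D/2`, `K' g_N + W g_D = g_N/2`, whose
  Galerkin residuals shrink at the expected O(h²) under refinement (they
  are dominated by the faceting of the sphere), and by a point-source
  representation check converging the same way.

**Solver.** Unrestarted GMRES to a relative residual of 1e-4 within at most
2000 iterations, preconditioned by interface-local block-Jacobi — the LU
factors of each interface's diagonal `(φ, w)` operator block. A plain
mass-matrix preconditioner is retained as an option but stalls near 2000
iterations at ≥ 1 kHz across the high-contrast air/tissue interface
(impedance ratio ~3700), while block-Jacobi converges in ~4 iterations;
with dense desk-scale systems (≤ ~3000 unknowns) the factorisation cost is
negligible. A dense direct solve is available as the reference path and is
tested to agree with GMRES to 1e-4.

**Accuracy at the study's mesh density** (benchmark phantom, analytical
reference): max |ΔRMS SPL| = 0.11 dB over 12th-octave centres ≤ 2 kHz at 5
elements per wavelength; max relative ℓ2 error of pressure magnitudes 1.4%
at 4.5 elements per wavelength. Pointwise relative errors are reported as
an ℓ2 aggregate because the interior field has deep interference nulls
(|p| ~ 0.016 Pa at 500 Hz) where a pointwise ratio is meaningless even
though both solvers agree to ~1% of the ambient level.

**Cost.** Dense assembly is O(N²) in elements and the 2 kHz benchmark band
(1280 + 320 triangles, 1608 unknowns) takes ~1 minute on one CPU; this is
why BEM sweeps default to a ≤ 2 kHz cap and full-audio-range curves use the
analytical solver on spherical phantoms. Validation runs use a 7-band
spread of 12th-octave centres over 250 Hz – 2 kHz (densest where meshes are
finest) rather than all 80 in-range bands; the agreement figures are
insensitive to this choice because the error varies smoothly off-resonance.

## Sweep protocol and metrics

Band centres are `1000 · 2^{n/12}` Hz for all integers n with centres
inside [20 Hz, 20 kHz] — 119 bands, 20.9 Hz to 19.03 kHz. Strict in-range
enumeration is the only reproducible policy; the sometimes-quoted count of
128 bands for this range is not derivable from any anchored 12th-octave
enumeration and is treated as a band-edge-policy ambiguity. Metrics per
band: impact SPL (spatial RMS of |p|, phase-blind by construction), l∞
SPL, and the complex barycentre pressure (used downstream for FIR design).
`L_∞ ≥ L_RMS` always; both shift by exactly `20 log₁₀ g` under incident
amplitude scaling g (linearity, tested). Solver failures at individual
bands are recorded and surfaced as NaN rather than aborting a sweep.

### Benchmark behaviour worth knowing

* The benchmark system's resonances are the cavity modes of the 0.25 m
  tissue ball with a nearly pressure-release (air) boundary: a monopole
  family at 2.996 / 5.99 / 8.98 kHz (`j_0(ka) = 0` with c ≈ 1490 m/s)
  plus higher-order modes at 4.27, 5.48, 6.65, 7.35, 8.67 kHz, …
  A continuous-frequency scan puts the lowest strong resonance at 3.03 kHz
  and the strongest upper one at 8.67 kHz.
* These modes are radiation-limited and *much narrower than a 12th-octave
  band*, so the sampled peak positions and heights depend acutely on how
  band centres align with resonances: on the 1 kHz-anchored grid the two
  most prominent sampled RMS-SPL maxima are the 2 996.6 Hz and 4 237.9 Hz
  bands, while the 8.67 kHz resonance falls between bands and surfaces only
  as a modest maximum at 8 979.7 Hz. `highlight_resonances` therefore
  reports sampled-grid peaks and the documentation flags which
  continuous-scan resonance each is nearest to.
* Replacing the amniotic-fluid core by uterine tissue (585.3 vs 0.015 Np/m
  at 1 MHz) damps every resonance peak — a tested monotonicity property.
* Below ~530 Hz the phantom transmits within −6 dB of the incident level;
  between ~560 Hz and 1 kHz the response descends into the first
  antiresonance, reaching −9.4 dB at 944 Hz. A spherical phantom is *more*
  resonant than real anatomy, so low-frequency quasi-flatness up to 1 kHz —
  reported for anatomical geometries — holds here only up to ~530 Hz.

## FIR auralization

The barycentre transfer function, sampled on the sweep grid, becomes a
causal FIR filter: magnitude and unwrapped phase are cubic-spline
interpolated onto 16 385 uniform points over [0, 22.05 kHz] (unwrapping on
the coarse grid, where it is stable — after interpolation it is not), a
constant 200-sample delay linearises the phase, and the least-squares fit
is obtained by inverse real FFT (the design grid is exactly the
positive-frequency grid of a 32 768-point DFT, so truncating the full
impulse response at a given order *is* the least-squares solution at that
order, by DFT orthogonality). The order doubles from 800 until the relative
frequency-domain MSE is ≤ 1e-4 (default; cap 8192 taps, error carrying the
achieved MSE beyond it). Out-of-band policy: magnitude held constant below
the lowest band (the transfer characteristic is flat into the infrasound
range), raised-cosine roll-off from the highest band to Nyquist, phase
continued linearly. A flat unit response yields an impulse at sample 200
with mean group delay 200.0 samples over 100 Hz – 10 kHz; a real phantom
response adds its own propagation delay (~225 samples total for the
benchmark). Output audio is peak-normalised to −1 dBFS with the gain
recorded; un-normalised output is exactly linear in the input.

## Determinism

There is no randomness anywhere in the pipeline: meshes, quadratures,
solvers and the FIR design are all deterministic functions of their
configuration, and repeated runs produce byte-identical outputs (tested).

## Known limitations

* Compressional waves only; shear-wave conversion in tissue/bone would
  require a viscoelastic boundary-element formulation.
* Dense BEM without compression or high-frequency preconditioning: fine
  above ~3 kHz only for reduced geometries; the analytical solver covers
  the full audio range on spherical phantoms.
* The loss-tangent attenuation model extrapolates ~100 Hz viscoelastic
  data linearly across the audio range; the two-material bracket (amniotic
  fluid vs uterine tissue) is the uncertainty treatment.
* Exterior-region field evaluation subtracts nodally interpolated incident
  traces, adding an O(h²) error near coarse surfaces (interior evaluation
  is unaffected).
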