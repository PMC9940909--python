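# Methods

## The system and the model

During germband extension (GBE) in the *Drosophila* embryo, anisotropic
junctional myosin II drives convergent extension by cell intercalation.
Pair-rule gene (PRG) stripes — the candidate genetic instruction for
that anisotropy — are carried passively with the flowing tissue, while
the myosin anisotropy direction stays close to the embryo's static
dorsal-ventral (DV) axis, deflecting only transiently where the flow is
rotational.  The package implements the static-source relaxation model
that reconciles these observations, together with the measurement chain
needed to test it.

All analysis happens on a 2D cylindrical pullback chart: x along the
anterior-posterior (AP) axis (posterior right), y along the DV
circumference, periodic, with the ventral midline at y = 0 and the
dorsal midline at half the circumference.  Orientations are *nematic*
(defined modulo 180°), stored as angles to the DV axis in (−90°, +90°],
positive counterclockwise.  All nematic averages are computed in
double-angle space, which makes every statistic invariant under
θ → θ + 180°.

The model: a junction with orientation θ carries myosin m obeying

    dθ/dt = ρ(x, t)            — junctions rotate with the local tissue
                                 rotation rate ρ = ω/2 (half the curl of
                                 the tissue velocity)
    dm/dt = s(θ) − m/τ         — myosin is recruited by a source peaked
                                 where junctions are parallel to the DV
                                 axis, and unbinds with rate 1/τ

At the population level the intensity-weighted mean deflection θ̄ of the
anisotropy from the DV axis follows a one-parameter relaxation law,

    dθ̄/dt = ρ(t) − θ̄/τ,

whose steady state under constant rotation is θ̄ = ρτ and whose response
lags a slowly varying drive by τ.  θ̄ depends only on the direction of
maximal recruitment, not on the source's amplitude, angular width or
spatial modulation.  The only free parameter is the effective myosin
lifetime τ — the persistence time of the *total* myosin level on a
junction, which can exceed the single-motor residence time measured by
FRAP if recruitment-controlling factors outlive individual motors.

## Parameters that matter

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| chart extent | 450 × 500 | μm | wild-type egg: AP length × DV circumference; the Fat2-RNAi preset scales the circumference ×1.3 and shortens AP |
| germband mask | DV distance ≤ 175, AP margin 30 | μm | junctional myosin is detectable to ~175 μm from the ventral furrow |
| peak rotation rate | 5 (posterior), <2 (anterior) | °/min | the printed calibration of the tissue-flow vorticity |
| vortex core radius σ_v | 70 | μm | the posterior vorticity peak is broad; this width also makes the τ fit statistically identifiable at the ensemble sizes used (see below) |
| flow envelope | 0 → ramp 10–20 → plateau → decay by 35 | min | flow onset ~10 min post ventral-furrow initiation, plateau 20–25 min, recovery by 35 min |
| effective lifetime τ | 5 (WT), 2.5 (eve preset) | min | the model's single fitted parameter |
| source width σ_s | 15 | deg | Gaussian angular recruitment profile; the model's predictions do not depend on it |
| source DV decay ℓ_m | 76 | μm | e-folding of recruitment amplitude away from the ventral midline; puts the 10% amplitude point at ≈ 175 μm |
| anisotropy radius | 20 | μm | "three cell diameters" at 6–7 μm per cell |
| smoothing σ | 10 | μm | ≈ 1.5 cell diameters: gradients measure cell–cell expression differences |
| Radon window | 12 | μm | about two cell diameters; windows overlap 50% |
| FRAP timescales | f_mob 0.5, τ_f 8 s, τ_s 60 s | — | ≈50% immediate recovery, fast phase <30 s, complete recovery by 210 s |

## What the generator emulates — and what it does not

The synthetic embryo reproduces the statistical structure the analysis
relies on: seven DV-parallel PRG stripes with expression fading toward
the dorsal pole and per-gene AP phase offsets; a tissue flow built from
two mirror pairs of Gaussian-core vortices (strong posterior, weak
anterior, giving two hyperbolic stagnation points) plus a
DV-convergent/AP-extending component, all sharing one time envelope so
the flow direction pattern is static while its magnitude varies;
junction ensembles obeying the model exactly; blurred noisy line-segment
images; and two-timescale FRAP traces.

It does **not** emulate: cell packing and junction topology (junctions
are independent segments, not a polygonal tiling), curved-surface
metrics, tissue strain (junctions rotate with vorticity only — the pure
rotation assumption), myosin oscillations except as an optional additive
term in FRAP traces, or any imaging physics beyond Gaussian blur and
additive noise.  Passing tests therefore demonstrate that the analysis
measures what it claims on data with the assumed structure; they do not
validate the biological assumptions themselves against real embryos.

Two generator choices deserve emphasis:

* **Cell-intrinsic recruitment amplitude.**  The angular source
  direction is fixed in the embryo frame (the model's core hypothesis),
  but the recruitment *amplitude* at a junction is treated as a property
  of its cell: it is evaluated from the ventral-maximal DV profile at
  the junction's birth position and then carried with the junction.
  This mirrors how gene-expression-dependent sensitivities advect with
  cells.  Evaluating the amplitude at the instantaneous lab-frame
  position instead would make m lag its local equilibrium as junctions
  advect through the profile, contaminating the effective lifetime by
  ~5% — an artifact of the profile, not part of the model.
* **Identifiability calibration.**  With very compact vortices the
  deflection signal lives in a small tissue domain and the τ fit from a
  2000-junction ensemble is noise-limited beyond ±0.5 min for *any*
  estimator; the 70 μm core radius makes the rotational domain a
  realistic fraction of the posterior germband and renders τ
  identifiable at that ensemble size, while the peak rotation rates
  remain at their calibrated values.

## Numerical choices

* Integrators: fixed-step RK4 for all advection and orientation ODEs
  (0.1 min for junction ensembles, 0.25 min for point advection and
  deflection fields, ≤0.02 min for the scalar relaxation law, matching
  closed forms to 10⁻⁶ deg).  The myosin level uses an exact
  exponential (integrating-factor) step with a Simpson average of the
  source along the step — stable even for τ far below the step size.
* Interpolation: bilinear in space (DV-periodic, AP-clamped), linear in
  time.
* Vortices are summed over ±1 periodic DV images so the velocity field
  is smooth across the seam.
* The Radon detector thresholds sinogram bins at 4.5 robust σ, with the
  per-bin noise scaled by the square root of the ray length through the
  window and σ estimated from the global image MAD; peaks undergo
  non-maximum suppression (±2 px offset, ±10° angle, with the angle
  axis wrapped through the offset-flip symmetry), back-projected lines
  are trimmed to their bright run and validated against the noise
  floor, duplicates from overlapping windows are merged using
  perpendicular distance and nematic angle, wrong-angle ghosts whose
  span lies inside a stronger segment's tube are suppressed, and each
  surviving segment is re-fitted on the full image by intensity-weighted
  principal axes.  On fixtures this gives zero detections on pure noise,
  ≤1° error on clean single segments, and recall 1.0 with ~3° RMS angle
  error at SNR 5.
* Local anisotropy fields are disk averages (FFT convolution, periodic
  in DV).  The plain double-angle circular mean systematically shrinks
  skewed deflection distributions (arctan(2ρτ)/2 < ρτ), so the τ fit
  uses a *recentered* estimator: a second pass averages arithmetic
  deviations wrapped around the first-pass circular mean.  Degenerate
  disk means (nematic order parameter < 0.05) are reported as missing,
  never as arbitrary angles.
* The τ objective is the intensity-weighted mean absolute
  rotation-rate-adjusted angle over the germband and the 10–35 min
  window (L2 available); the pointwise model prediction is disk-averaged
  with the observation weights before comparison, so the model predicts
  the measured observable.  The grid argmin (0.5–20 min) is refined by
  golden-section search; fields are subsampled (stride 3) because disk
  smoothing makes neighbouring pixels redundant.  A flat objective (no
  vorticity signal) is flagged unidentifiable rather than defaulted.
* The deflection prediction defaults to the eulerian frame (pointwise
  at fixed chart positions, matching per-location deflection maps); a
  lagrangian mode integrating along trajectories is provided, and on
  the synthetic embryo the two agree closely because myosin turns over
  faster than junctions traverse the vorticity pattern.
* Stripe segmentation is threshold + DV-periodic connected components,
  keeping components spanning at least half the germband DV extent — a
  deliberate, simple stand-in for classifier-based segmentation of real
  images.
* Regional (per-stripe) statistics are computed on one lateral half of
  the embryo; the two halves are mirror images with opposite rotation
  sense, so whole-circumference means cancel by symmetry.
* FRAP fits run nonlinear least squares from a 3 × 3 multi-start over
  the two timescales, with the plateau fixed at 1 (complete recovery)
  unless requested otherwise; timescales are ordered afterwards.

## Design choices where the ground was open

* The recruitment source is Gaussian in angle.  Nothing downstream
  depends on this (the relaxation law is independent of the source's
  shape and magnitude — verified by a rescaling invariance test).
* The angle-dependent *lifetime* alternative (uniform recruitment,
  faster detachment away from the DV axis) is implemented side by side;
  it produces a uniform angular distribution when the lifetime is
  angle-independent and deflections that deviate from the ρτ law when
  it is DV-peaked.  The package reports the comparison rather than
  asserting an effect size.
* The regression uses gradient magnitudes as regressors by default
  (signed components are available), no intercept, and resolves
  collinearity by the minimum-norm solution with an explicit
  rank-deficiency flag.
* Genotype presets encode only documented differences: `twist` halves
  the flow amplitude; `eve` reduces τ to 2.5 min, halves the flow,
  halves the recruitment amplitude and switches to an abrupt envelope
  at 10 min (illustrative functional form); `fat2` enlarges the DV
  circumference by 30%, shortens the AP axis and reduces the flow while
  the recruitment zone keeps its wild-type DV extent.
* The vorticity-to-deflection delay is measured as the argmax of the
  Pearson cross-correlation at 1-minute sampling.  For the default
  ramp/plateau/decay envelope with τ = 5 min this estimator yields a
  4-minute lag (the lag approaches τ exactly only for slowly varying
  drives, which the property tests verify separately on a broad
  Gaussian drive).

## Problem sizes

Default analyses run on the full 450 × 500 chart at 1 μm spacing with
2000-junction ensembles over 35 simulated minutes; the end-to-end
pipeline tests use a 2 μm grid and 800 junctions, and detector fixtures
use 200 × 200 px images with 100 segments.  These sizes keep every
result reproducible on a single CPU in minutes.

## Known limitations

* The detector's angular accuracy degrades below SNR ≈ 3 (recall drops
  rather than hallucinating segments — by design).
* Junction ensembles are not a cell tiling; packing constraints,
  vertices and junction birth/death are absent, so detector fixtures
  place segments with realistic spacing rather than sampling real
  topology.
* The τ fit's precision at n = 2000 junctions is ≈ ±0.3 min (1σ); a
  single unlucky realization can land near the edge of that band.
* Advection of stripe label images is semi-Lagrangian with incremental
  resampling and accumulates mild smoothing; late-time regional
  statistics for strongly deformed posterior stripes degrade
  accordingly.
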