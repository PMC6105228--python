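# Methods

## The model

A rod-like plant organ (an etiolated hypocotyl) clamped at its base and
turned to 90° from the vertical bends back by differential growth.  Writing
`A(s,t)` for the local deflection angle from the vertical (degrees; `s` =
arc length from the base, mm), `C = ∂A/∂s` for the curvature (mm⁻¹, with A
in radians), the graviproprioception (GP) law is

    ∂C(s,t)/∂t = −β·sin A(s,t) − γ·C(s,t),      β, γ > 0

The first term is graviception (the classical sine law); the second is
proprioception — the organ senses and counteracts its own curvature, which
produces autostraightening (de-curving before the vertical is reached).
`γ = 0` reduces the law to the pure sine law.  The clamped base fixes
`A(0,t)` and the angle field is recovered as `A(s) = A(0) + ∫₀ˢ C ds′`.

## Simulation and rendering (`gravikine.simulate`)

The law is integrated by explicit Euler on a fixed s grid (default step
19.9 µm, matching the downstream sampling) with inner step 0.005 h and a
stability guard on |C|; halving the inner step changes C by < 0.5%.  Frames
are emitted every 0.170 h over 6.10 h — the imaging cadence the pipeline is
designed for.  Default organ: length 4 mm (3–5 mm typical), diameter
0.25 mm, `β = 0.4 mm⁻¹h⁻¹`, `γ = 1.5 h⁻¹`.  An optional response kernel
g(A) replaces sin A so that validation runs can stamp the bending response
at a designed angle, and optional process noise makes the dynamics
stochastic (off by default; every random draw is seeded).

Rendering produces a bright-field silhouette — a constant-width band swept
along the midline, anti-aliased over one pixel so sub-pixel positions
survive binarization — and a luminescence count raster on 512×512 pixels at
16 µm/pixel (the sensor geometry of a 1× macro-zoom EM-CCD setup; the
instrument scale is a declared default, not an inferred one).  The
luminescence model is a longitudinal intensity bump drifting basipetally
toward s ≈ 1.2 mm (emulating the reporter-activity pattern of a growing
dark-grown seedling) times a transverse profile that is log-linear across
the organ width and pinned so that the log₁₀ intensity ratio of the two
1/8-diameter inset points equals `lrl_true(s,t)` exactly before noise.  The
default ground truth is a delayed sine response,
`lrl_true = −0.5·sin A(s, t−1.5 h)` (zero before the delay has elapsed,
since the organ was vertical before turning).  Noise: Poisson counting
noise plus Gaussian read noise (sd 2 counts).  Each rendering also jitters
the whole recording by a seeded sub-pixel offset — real specimens land
arbitrarily on the sensor grid, and replicate renderings should sample
different rasterizations.

What the generator does *not* emulate: optics (PSF, vignetting, EM-gain
statistics), cotyledon/hook geometry, elongation-driven advection of
material points (uniform elongation is available but off by default, since
the analysis uses partial derivatives at fixed s), or biological variability
between specimens.  Passing tests therefore demonstrate correctness of the
measurement chain on an idealized organ, not robustness to everything real
microscopy produces.

## Midline extraction (`gravikine.midline`)

Per frame: Otsu binarization, largest connected component, hole filling;
the organ outline is traced as the iso-intensity contour at the threshold
(sub-pixel, using the gradual edge falloff) restricted to the component,
and split into the two flank polylines at the contour vertices nearest the
two ends of the mask's geodesic diameter (robust for bent or partially
hooked organs, where the Euclidean diameter can connect two flank points).
Midpoints between the flanks are built by nearest-point correspondence in
both directions; pairings across the rounded end caps of the silhouette are
recognized by their reduced flank separation (< 0.85 of the median width)
and dropped, because they lie beyond the organ's true ends and would flex
the curve fit.  A principal curve (Hastie–Stuetzle: project onto the
current curve, smooth each coordinate against the arc-length ordinate with
a cubic smoothing spline at equivalent df, iterate to tolerance 1e-4) is
fitted at df 10 (df 20 for the clean synthetic contours of the validation
studies; both reproduce the midline to sub-pixel accuracy) and resampled
every 19.9 µm from the base; the base is the end nearest a caller-supplied
anchor, and each frame anchors on the previous frame's base so orientation
cannot flip mid-series.  Midline tangents are evaluated analytically from
the coordinate splines — finite differences of the resampled points would
reintroduce chord-scale noise the spline already removed.

## Smoothing splines (`gravikine.splines`)

All smoothing uses cubic smoothing splines parameterized by equivalent
degrees of freedom (edf = trace of the smoother matrix, the R
`smooth.spline` convention; one unit test cross-checks fitted values
against R).  Implementation: penalized cubic B-spline regression with the
exact ∫f″² penalty; `df → λ` is solved by root finding on
`tr[N(NᵀN+λΩ)⁻¹Nᵀ]`, with sites rescaled to [0,1] for conditioning and
factorizations cached per grid (the per-position time-series fits reuse one
factorization).  The profile/curvature smoothing rule throughout is
df = n/2 — half the sample count.

## Kinematics (`gravikine.kinematics`)

A(s) comes from the midline tangents (signed angle to the upward vertical,
positive toward the turning side, unwrapped along s).  C(s) is the first
derivative of the df = n/2 spline of A(s) (radians internally).  At each s,
C(t) is smoothed at df = n/2 to give the predicted C, ∂C/∂t as its
derivative and SEE = √(RSS/(n−df)); the SEE-ratio map is
log₁₀(SEE(s)/|C(s,t)|), masked where C = 0.  SEE is global in t (not
windowed).  Validity masking: rows beyond a frame's length, plus the last
0.3 mm of each frame, where the principal curve's free end has little data
leverage and tangents are unreliable; the clamped base is kept valid (so
validity stays monotone in s) and fits exclude it through `s_min` instead.

Troughs/heights of a t–s field are per-row temporal extrema below
depth_frac (default 0.3) of the global extreme, linked across adjacent rows
by nearest-t continuity (gaps ≤ 2 rows, ties to the deeper extremum), kept
if spanning ≥ 0.5 mm.  Each path is aligned with the deflection-angle field:
A is read bilinearly at the vertices, the aligned angle is the median
rounded to 5°, the residual the RMS deviation from it.

## Luminescence (`gravikine.luminescence`)

The convex flank is fixed once per recording from the sign of the
|C|-weighted mean curvature.  Each flank is moved inward along the local
normal by 1/8 of the local diameter (the flank separation at the nearest
midline point) and smoothed by a principal curve at df 60.  At every
midline point the normal line is intersected with both inset curves
(nearest crossing within 2× the local width; rows without both crossings
are masked, never extrapolated); L_m, L_v, L_c are bilinear raster samples
normalized by exposure, smoothed along s at df = n/2, and
LRL = log₁₀(L_c) − log₁₀(L_v) (computed as a difference of logs so that
swapping flanks negates it exactly).

## Model fitting (`gravikine.model_fit`)

Per timepoint, OLS of the response on (−sin A, −C) [GP] or (−sin A) [sine
law], no intercept by default (matching the model form; configurable).
AIC = n·ln(2πRSS/n) + n + 2(k+1) with k regression coefficients (+1 for the
profiled variance); both models share the convention, and only differences
matter.  Adjusted R² for intercept-free fits uses the uncentered total sum
of squares — values are not comparable to centered R².  Coefficients with
p > 0.05 are flagged insignificant.  The sine-law segment scan fits
LRL ~ a + b·(−sin A) on every grid window ≥ 0.76 mm and keeps windows with
centered R² > 0.95, merging them into maximal segments refit for their β.
(A through-origin uncentered R² would also accept constant-LRL stretches,
because sin A varies little over short windows; the centered statistic
rejects them.)

## Validation studies (`gravikine.studies`) and their design

- Curvature oracle: circle arcs (r = 0.5–10 mm, 19.9-µm sampling, arcs
  capped at 3 mm) give |C − 1/r| < 1% of 1/r.
- Consistency: on every analyzed frame ∫C ds rebuilds A − A(0) to < 0.5°.
- Linearization: with γ = 0 and t ≤ 0.1/β, C ≈ −β·t·sin A₀ within 2%.
- Field-level recovery: noiseless fields give β, γ to machine precision
  (the response is exactly linear in the regressors); with Gaussian
  response noise of sd = 10% of the response sd, the median relative error
  over 50 seeds is ≪ 5%.
- End-to-end recovery: at the default β = 0.4, γ = 1.5 the organ reaches
  quasi-equilibrium (C ≈ −(β/γ)·sin A) within about an hour, after which
  the regressors are nearly collinear and ∂C/∂t ≈ 0: the identifying
  signal is the small departure from that manifold (rms ≈ 0.013 mm⁻¹),
  comparable to the imaging-chain curvature error of a single recording.
  The study therefore (i) renders ten replicate recordings of the same
  trajectory (sub-pixel placement jitter + fresh noise) and averages the
  measured A / predicted-C / ∂C/∂t fields — replicate imaging of one
  specimen; the errors-in-regressor attenuation shrinks with the averaged
  error — and (ii) pools one GP regression over the autostraightening
  onset window, t ∈ [1.0, 2.5] h (positive ∂C/∂t cells appear at ≈1.2 h;
  later frames are pure quasi-equilibrium and only add noise), s > 0.5 mm.
  This recovers β and γ within 20% (typically within 10%) across seed
  blocks.  Single-recording per-timepoint fits are reported by the
  analysis scripts but are not expected to resolve the parameters in this
  regime — an identifiability limit of the scenario, not of the code.
- AIC selection: at a single early transient timepoint (regressors not yet
  collinear) with 10% response noise, AIC picks GP for γ = 1.5 data in
  ≥ 95% of seeds and the sine law for γ = 0 data in the majority (the
  2-unit parameter penalty decides near-ties).
- Trough alignment: the bending response kernel is a narrow Gaussian peak
  at a designed A* riding on a 0.15·sin A baseline — the baseline keeps
  every row descending steadily through all angles, the peak stamps the
  ∂C/∂t trough exactly at the A = A* crossing, and rows that never reach
  A* fall below the depth threshold.  With curvature noise of 0.01 mm⁻¹
  (the scale of extraction error), the aligned angle lands within one 5°
  step of A* in ≥ 95% of replicates (A* = 45–60°; at A* = 75° the crossing
  happens so early that temporal-spline boundary lag biases the estimate by
  one 5° step).
- LRL fidelity: full chain (render → extract → insets → sampling →
  smoothing) reproduces the ground-truth LRL map with RMS ≈ 0.013 (< 0.05)
  under default noise.
- Segment scan: on piecewise fixtures (sine-law LRL on the apical half,
  constant on the basal half, angle profile kept below ~80° so sin A varies
  appreciably everywhere) the detected segment boundary lands within 2 grid
  steps of the construction and β within 10% (medians over seeds).

## Numerical choices and limitations

- Basis thinning: principal-curve fits use ~2.5·df knots; all df = n/2
  smoothers use the full basis.  A tiny relative ridge (1e-12) guards the
  normal equations near λ = 0.
- Degenerate inputs: < 8 samples → masked curvature; blank frames, masks
  touching ≥ 3 borders, non-rod-like masks (aspect < 3), crossing flanks,
  insets crossing the midline, and never-bending recordings all raise
  typed errors.
- Tie-breaks: trough linking prefers the deeper extremum at equal |Δt|;
  duplicate midpoints within a quarter vertex-spacing are merged.
- The first ~0.5 mm near the base and early times (t ≲ 0.75 h) carry the
  largest ∂C/∂t estimation error (mirrored in the SEE-ratio map); fits
  should exclude the basal zone via `s_min`.
- Lengths in mm, times in h, angles in degrees at every interface (radians
  internally), intensities in counts per minute.
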