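# gravikine

Space–time analysis of gravitropic bending in rod-like plant organs.

When an etiolated seedling is turned on its side, the hypocotyl bends back
toward the vertical — and characteristically begins to *straighten* before
it gets there (autostraightening).  Two competing laws describe the local
bending rate along the organ: the classical **sine law**,
`∂C/∂t = −β·sin A`, and the **graviproprioception (GP) model**,

    ∂C(s,t)/∂t = −β·sin A(s,t) − γ·C(s,t)

where `A(s,t)` is the local deflection angle from the vertical, `C = ∂A/∂s`
the curvature along arc length `s`, `β` the graviceptive gain and `γ` the
proprioceptive (curvature-sensing) decay that produces autostraightening.

`gravikine` implements the full measurement chain needed to test these laws
on time-lapse recordings, for researchers doing quantitative plant tropism
work:

- **simulate** — forward-integrate GP bending of a clamped organ and render
  bright-field + luminescence frames with exact ground truth (the package's
  recordings are synthetic; no raw data from the original experiments is
  public);
- **midline** — recover the organ median per frame: binarize, split the
  outline into flank contours, midpoints, principal-curve fit
  (Hastie–Stuetzle, df 10), resample every 19.9 µm from the base;
- **kinematics** — A(s,t), C(s,t) (smoothing-spline derivative at
  df = n/2), temporally smoothed ∂C/∂t and SEE maps on the t–s plane;
  trough/height tracing and their deflection-angle alignment at 5°
  resolution;
- **luminescence** — sample a ratiometric reporter at the median and at
  1/8-diameter inset points on the convex/concave flanks and map
  `LRL = log10(L_c/L_v)`, a measure of differential promoter activity
  across the organ;
- **model_fit** — per-timepoint OLS of ∂C/∂t (or LRL) on sin A and C,
  GP-vs-sine selection by AIC and adjusted R², and a scan for organ
  segments (> 0.76 mm, R² > 0.95) where LRL follows the sine law.

## Worked example

Run the analysis scripts in order (each is a thin driver over the library):

```
python analysis/01_simulate_recording.py
python analysis/02_extract_midlines.py
python analysis/03_kinematics_maps.py
python analysis/05_model_selection.py
```

which prints, for the default recording (β = 0.4 mm⁻¹h⁻¹, γ = 1.5 h⁻¹,
4-mm organ, default noise):

```
simulated 36 frames; tip deflection 90.0 -> 38.0 deg (min 38.0 deg)
peak |C| = 0.267 mm^-1; fixture written to results/recording/
extracted 36 midlines; median RMS distance to ground truth 0.72 px (worst 0.75 px)
turning side sign +1; 1 trough path(s), 0 height path(s)
  trough: s span 0.48-3.78 mm, aligned A = 90 deg (residual 0.9 deg)
dC/dt fits: GP selected at 27/36 timepoints
pooled GP fit over t in [1.0, 2.5] h: beta = 0.174 +/- 0.013, gamma = 0.596 +/- 0.053
```

Reading this: the simulated organ bends from horizontal (90°) to 38° in
6 h; midlines are recovered to sub-pixel accuracy; the bending-response
trough in the ∂C/∂t map follows the A = 90° contour (with these parameters
the response is strongest immediately after turning); AIC prefers the GP
model at most timepoints.  The pooled single-recording estimate of (β, γ)
is attenuated — after the first hour the curvature locks onto its
quasi-equilibrium `C ≈ −(β/γ)·sin A`, so a single noisy recording carries
little information that separates β from γ.  Averaging the measured fields
over ten replicate recordings restores the estimate
(`analysis/06_validation_studies.py`):

```
end-to-end recovery (10 replicate recordings, window 1.0-2.5 h): beta = 0.391 (true 0.400), gamma = 1.443 (true 1.500)
```

The same pipeline runs from a single YAML config via the CLI:

```
gravikine run -c config.yaml --seed 11 -o run_dir
gravikine report run_dir
```

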