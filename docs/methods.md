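# Methods

This document records the models, parameter choices, and numerical
decisions behind each module, including what the synthetic generators do
and do not emulate.

## Kinetic model

Degradation of a tagged protein after inducer addition at time `t0` is
modelled as a two-pool first-order decay of normalized fluorescence:

```
F(Δt) = A · [ f · exp(−Δt/τ₁) + (1 − f) · exp(−Δt/τ₂) ],  Δt = t − t0 ≥ 0
```

with `τ₁ ≤ τ₂`. Traces are normalized to the last pre-inducer time point,
so the amplitude is fixed at `A = 1` during fitting; this removes one free
parameter and makes fits comparable across cells. The **major pool** is
the component with fraction ≥ 0.5 (ties resolve to the faster component);
its time constant is the reported headline τ. Optional washout at
`t_washout` switches the model to a saturating exponential recovery toward
the pre-inducer level with time constant `recovery_tau`.

### Grid-search fitter (`kinetics.fit_biexponential`)

- τ grid: logarithmic, 40 steps per decade over 0.1–1000 h (161 nodes);
  f grid: 0 to 1 in steps of 0.01. Every `(τ₁ ≤ τ₂, f)` combination is
  scored; there is no local optimization, so the result is the global grid
  optimum by construction.
- The SSR is quadratic in `f`, so the whole grid is evaluated from two
  Gram matrices (`E Eᵀ` and `E y` with `E[i,k] = exp(−Δt_k/τ_i)`); an
  exhaustive fit takes ~20 ms on one CPU.
- Only points with `t ≥ t0` enter the fit; at least four are required.
  NaN pairs are dropped, never interpolated.
- **Component merge**: if the optimal `τ₂/τ₁` is within one grid step, the
  two pools are not identifiable at this resolution and are collapsed to a
  single pool at the fraction-weighted geometric time constant with
  `f = 1`. Without this, a pure single exponential whose τ falls between
  grid nodes fits marginally better as a mixture of the two adjacent
  nodes, which would misreport `f_major ≈ 0.9` for truly monoexponential
  data.
- **Flags**: `boundary_hit` when an active component sits on a grid edge;
  `non_decaying` when the OLS slope of the fitted window is ≥ −1e−12 ×
  max(1, |y|ₘₐₓ) (a constant trace otherwise parks τ at the upper bound).
- Accuracy: for identifiable parameters the fit lands within one grid
  step (factor 10^(1/40) ≈ 1.059 in τ, 0.01 in f) of the continuous
  optimum; `GridSpec.refine()` halves the step for follow-up fits.

### Averaging and statistics

Population traces are built in two levels — synapses are averaged within
each neuron, then neuron means are averaged — so heavily imaged neurons do
not dominate. Initial rates are the OLS slope over the first five
post-inducer points. Group comparisons use Welch's unequal-variance t-test
or the two-sided Mann–Whitney rank-sum test; correlations are Pearson,
pooled and per-group (mean ± SD across groups with ≥ 3 pairs).

## Culture quantification

- **Detection** runs on per-time-point maximum-intensity z-projections:
  scale-normalized Laplacian of Gaussian (−σ²·∇²G, maximized over σ in
  1.0–2.5 px), thresholded at mean + 4 SD of the response, with greedy
  minimum-separation suppression (4 px) keeping the stronger peak.
- **Tracking** is greedy nearest-neighbour linking within a 4 px search
  radius, processed in descending detection strength. Tracks are labelled
  `persistent`, `formed`, `disappeared`, `merged`, or `split`; only
  persistent puncta enter kinetic analysis. `max_gap` controls coasting:
  with `max_gap=None` (the pipeline default) a track that temporarily
  falls below the detection threshold keeps its last position and stays
  measurable — necessary because degrading puncta fade below detectability
  long before the end of the movie, and excluding them would censor
  exactly the fast-degrading population. `max_gap=0` (the function
  default) gives strict exclusion semantics.
- **Measurement** is the mean over a fixed 9×9 px square ROI centred on
  the tracked position. ROIs extending past the image are an error, not
  silently cropped.
- **Background**: `median` (default) uses the image median, which is
  robust to the sparse bright puncta and unbiased under symmetric noise;
  `auto` (mean of the lowest-percentile pixels) is biased low by about one
  noise SD under Gaussian noise and is kept only for compatibility with
  darkest-region protocols; `user` takes an explicit background ROI.
- **Known bias**: on max projections of noisy z-stacks, background-like
  pixels carry the expected maximum of the per-plane noise while pixels
  inside a bright punctum do not (the signal plane dominates their
  maximum). Background subtraction therefore slightly over-corrects the
  punctum core, which biases recovered τ low by ~5–15 % at SNR 10. This is
  inherent to quantifying on max projections and is covered by the 15 %
  end-to-end tolerance.
- **Unmixing** inverts a square mixing matrix per pixel and clips
  negatives (count reported). Singular matrices are rejected.

## In-vivo quantification

- **FOV selection**: given an acquired stack's plane spacing and the
  surface plane, `select_fovs` returns 13 planes starting 60 µm below the
  surface in 10 µm steps (all parameters overridable); requesting planes
  beyond the stack is an error unless truncation is explicitly allowed.
- **FOV re-identification** across sessions uses SIFT keypoints with
  mutual-nearest-neighbour ratio matching (max ratio 0.8); the score is
  the validated-match fraction, with a normalized-cross-correlation
  fallback for feature-poor images. Scores below threshold flag the FOV
  as unmatched rather than guessing.
- **Nucleus detection**: Gaussian blur (σ = 2 px) → Otsu foreground →
  scale-normalized blob detection restricted to the foreground, with the
  blob σ range derived from the expected nuclear radius.
- **Registration** estimates a translation by phase cross-correlation
  (falling back to the median displacement of mutual nearest neighbours),
  then refines a full 2×3 affine by least squares on mutual-NN centroid
  pairs within 8 px. Fewer than 3 pairs or a rank-deficient system falls
  back to translation-only, flagged on the transform record.
- **Quantification**: cytosolic signal is the mean over a half-open
  annulus `r ∈ [4, 8)` px around the mapped nucleus centre (half-open so
  adjacent rings partition pixels exactly); the nuclear reference is the
  disk mean at radius 4. Normalization divides ring means by the mean
  nuclear signal of the same session (`session` mode; `per_cell`
  available), cancelling session-to-session gain and depth changes while
  preserving the degradation signal.
- **Inclusion filters**: cells closer than 3 px to another cell (both
  removed — either could contaminate the other) or with first-session
  normalized signal < 0.3 are excluded; counts of each exclusion are
  reported.
- **Histology**: the neuropil/background ratio is the across-ROI mean of
  neuropil ROI means divided by the across-ROI mean of background ROI
  means.

## Synthetic generators

What they emulate: diffraction-limited puncta as 2-D Gaussians
(σ = 1.5 px) whose peak follows the per-punctum kinetic model, axial
intensity falloff across z-planes, constant background, spectral mixing,
Poisson shot noise and Gaussian read noise, photobleaching, punctum
appearance/disappearance events, correlated two-channel amplitudes,
in-vivo nuclear disks with cytosolic annuli under per-session
translation + mild affine transforms, and histology ROIs.

What they do **not** emulate: realistic neuronal morphology (dendrites,
axons), punctum motility or shape changes, z-drift within a session,
detector artefacts (fixed-pattern noise, saturation), scattering or
depth-dependent aberrations, or biological heterogeneity beyond
per-punctum amplitude/kinetics variation. Conclusions that depend on
those factors cannot be validated against these generators.

All generators are seeded and return exact ground truth (clean kinetics,
tracks, transforms, masks), which is what the test suite fits and
measures against.

## Acceptance problem sizes

`scripts/acceptance.py` and `tests/test_acceptance.py` use: 100 noiseless
fitter traces; a 30-punctum, 192×192 px, 3-plane culture movie at SNR 10
sampled hourly from −2 to 16 h; an 8-session, 40-nucleus, 256×256 px
in-vivo scene with translations up to 10 px plus ~1° affine jitter; and
per-construct trace tables of 12 neurons each. These sizes were chosen to
finish in seconds while leaving the estimators' statistical error well
inside the stated tolerances; they are this package's own validation
design. The per-construct source tables used for the headline
recomputation are generated at the documented parameter values because
the original measurement tables are not redistributable with this
repository.
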