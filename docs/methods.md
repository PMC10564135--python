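# Methods

## The measurement model

A membrane pilin observed by single-molecule tracking at frame interval
Δt = 30 ms yields tracks whose frame-to-frame jump distances r carry two
contributions: genuine diffusion with coefficient D and localization error σ
per coordinate per frame.  For 2-D Brownian motion the displacement in each
coordinate is Gaussian with variance 2·D·Δt + 2·σ², so the squared
displacement u = r² is exponential with mean 4·(D·Δt + σ²) = 4·D_app·Δt
where

    D_app = D + σ²/Δt .

All headline numbers are *apparent* coefficients: an immobile molecule
observed with σ = 35.5 nm at Δt = 30 ms has D_app = σ²/Δt ≈ 0.042 μm²/s,
which is exactly the scale reported for the "static" pilin pool.  Reporting
apparent D is the default; `sigma_mode='corrected'` additionally reports
D − σ²/Δt floored at zero, as an explicit opt-in.

A k-population sample is a mixture of such exponentials (equivalently, of
Rayleigh distributions for r).  The assumptions this rests on: populations
do not exchange within a track (state switching negligible at track length
scales), displacements are pooled as exchangeable draws, and motion blur
within the 30 ms exposure is absorbed into the apparent coefficient.

## Estimators

**SQD CDF fit (primary).**  Least squares of the model CDF
P(u) = 1 − Σ fᵢ·exp(−u/(4DᵢΔt)) against the empirical CDF at Hazen plotting
positions (i − ½)/n.  Weights are parameterized by softmax logits and
coefficients by log(τᵢ), τᵢ = 4DᵢΔt, so the constraints Σfᵢ = 1, Dᵢ ≥ 0 hold
by construction.  Optimization is Nelder–Mead from a quantile-spread start
plus 10 seeded random restarts; the best SSE wins and exact ties go to the
smaller D₁.  For n > 2000 steps the ECDF is compressed onto 2000
equal-probability quantile points; the fitted CDF is smooth, so the
compressed objective tracks the full one to well below optimizer tolerance.
R² is reported on the CDF.

**JD histogram fit (cross-check).**  The same mixture fitted as a Rayleigh
density to the Freedman–Diaconis histogram of r.  Fits agree with the SQD
route within joint uncertainties on common data; an error is raised when
half the bins are empty.

**Model selection.**  Candidate k are compared by the F-test on nested
least squares (α = 0.01) combined with a required improvement in the
quantile–quantile maximum deviation.  The F-test assumes roughly independent
residuals, which holds for histogram (JD) residuals but *not* for ECDF
residuals — successive ECDF values share a Brownian-bridge correlation, and
an F-test computed on them is wildly anti-conservative (it rejects a true
single population essentially always).  `select_components` therefore runs
on JD-domain fits in the pipeline; this calibration was verified by
simulation (50/50 single-population replicates choose k = 1 at α = 0.01,
while reference two-population mixtures choose k = 2 decisively).

**Confidence intervals.**  Linearized intervals propagate the residual
variance through the numerical Jacobian at the optimum (delta method to
fractions and Ds).  On CDF objectives the correlated residuals make these
optimistic, sometimes severely; the percentile bootstrap over resampled
steps (default 200 resamples, each refit started at the optimum) is the
honest choice and is what the worked example uses.  A singular Jacobian
falls back to the bootstrap automatically.

**Simultaneous (shared-D) fits.**  Across conditions measured at the same
Δt, the summed SQD SSE is minimized with the Dᵢ constrained equal and the
fractions free per condition — the standard way to test whether a treatment
shifts population sizes rather than mobilities.  When the conditions truly
differ in D, the shared fit shows detectable lack of fit (summed SSE well
above independent fits).

## Localization error and confinement

The time- and ensemble-averaged MSD over lags 1..4 (all within-track pairs
per lag, weighted linear fit) gives slope = 4D and intercept = 4σ².  Short
lags are used deliberately: they maximize pair counts and avoid confinement
curvature biasing the intercept.  A negative fitted intercept is floored at
zero and flagged.  The confinement radius is defined as 3σ — with
σ = 36.23 nm this is the 108.7 nm radius used for classification.

Tracks are classified by sliding a window of 5 displacements
(6 localizations, the minimum admissible track) along the track: a window is
*inside* when the largest distance of its localizations from the window
centroid is at most the radius.  All windows inside → confined; none →
mobile; mixed → transition.  The centroid rule is symmetric and invariant
under global rotation/translation.  Design notes, since the choice was
genuinely open:

- "radius" (not diameter) is adopted for the 108.7 nm threshold, matching
  the 3σ definition; the alternative diameter reading would make true
  confined molecules (whose excursions are ~σ-scale around an anchor)
  essentially undetectable at 3σ.
- window length equals the minimum track length so every kept track forms
  at least one window; longer windows sharpen the mobile/confined contrast
  but silently drop short tracks.
- with this rule, a fixed-length 20-step Brownian track at D = 0.5 μm²/s is
  labelled mobile with probability ≈ 0.984 (noise-free) to ≈ 0.99 (with
  36 nm noise) — the residual percent are tracks with one accidental
  low-excursion window, labelled transition.  Under bleaching-limited track
  lengths (mean ≈ 11 steps) the mobile rate exceeds 99%.

## Standardized-cell projection

Localizations from differently sized and oriented cells are compared by
mapping each cell onto a standardized 3 × 1 μm spherocylinder: rotate into
the cell frame, centre on the centroid, scale the long axis to 3 μm and the
short axis to 1 μm.  For cells whose aspect ratio differs from 3:1 this
axis scaling cannot map the outline exactly onto the standard silhouette;
points landing outside (also caused by localization noise at the boundary)
are clamped onto the silhouette and flagged, and the clamped fraction is
reported.  Density maps are plain 2-D histograms, default 50 nm bins
(60 × 20 grid), optionally restricted to confined tracks.

## The synthetic-data generator

`simulate_trackset` implements the minimal generative model consistent with
the two-population analysis: each molecule starts slow (tethered to an
anchor; immobile by default, or reflected Brownian within a configurable
confinement radius) or fast (Brownian with per-coordinate step variance
2·D·Δt) with probability `slow_fraction`; optional two-state Markov
switching generates transition tracks (off by default, matching the static
population assumption of the mixture fits); independent Gaussian noise σ is
added to every coordinate of every frame; track length is
1 + Geometric(1 − p) steps with per-frame survival p = 0.9 (mean ≈ 11
steps), and tracks below 5 steps are discarded — the bleaching-limited
track-length regime of stream acquisition.  Geometry is a 3 × 1 μm
spherocylinder, either diffusion on the 3-D surface orthographically
projected to the focal plane (`surface3d`, the membrane default, which
reproduces the peripheral enrichment of confined molecules in projections)
or reflected 2-D diffusion inside the silhouette (`planar2d`).

Whether the "static" pool is perfectly immobile or confined within a small
radius is not observable at these settings; the immobile anchor is the
default and the confined-tether option is exposed for sensitivity checks.

The defaults encode the reference study conditions: Δt = 30 ms,
slow fraction 0.324, σ = 35.5 nm (so the slow apparent D is 0.042 μm²/s),
fast true D = 0.468 μm²/s (apparent 0.51).  `recovery_config` builds the
matching configurations for the two documented conditions
(−DNA: 32.4% / 0.042 / 0.51; +DNA: 47.3% / 0.038 / 0.22, with σ set per
condition so σ²/Δt equals the slow apparent D).  Parameter-recovery
simulations use `planar2d` geometry with an effectively unconfined
100 × 100 μm cell, so the sampled displacement distribution carries exactly
the configured apparent coefficients; the rod geometry is for the spatial
mapping stages, where boundary reflection and surface projection are the
point rather than a bias.

What the generator does **not** emulate: blinking and other photophysics,
PSF shape and camera noise, motion blur within the exposure, tracking
(linking) errors, z-dependent localization bias, and cell-to-cell parameter
variability.  Passing recovery tests therefore demonstrate estimator
correctness under the stated model, not robustness to those real-data
effects.

`simulate_filaments` draws surface-anchored polylines whose arc length is
Normal(mean, sd) truncated at zero (defaults 505 ± 155 nm; the
low-induction condition uses 539 ± 40 nm), heading outward with a
per-node heading perturbation (0.1 rad default).  `simulate_bleach_trace`
is the exponential-decay-plus-noise curve used to exercise the trimming
rule, which cuts a movie at the first frame where the trailing-window
relative decline drops below 10% (window length 1 frame by default; the
smoothing window of the original rule is unstated, so this is a documented
choice).

## Problem sizes and numerical details

Recovery experiments use 5000 simulated molecules (≈ 3650 tracks surviving
the 5-step filter, ≈ 50 000 pooled steps), which resolves the −DNA slow
fraction to about ±1 percentage point and both Ds to a few percent;
model-selection calibration uses 50 replicates of 400 molecules.  These
sizes were chosen so the whole analysis runs in seconds on a laptop while
keeping sampling error well inside the tolerances quoted for each check.
Degenerate inputs fail loudly rather than silently: empty simulated track
sets, all-zero bleach traces, duplicate (track, frame) rows, missing cell
outlines and sub-window tracks all raise errors naming the offender.
Seeds: every generator takes an explicit seed; the CLI derives per-stage
seeds from one root seed by hashing the stage name, so stages are
independently reproducible.

## Known limitations

- Fractions estimated from pooled steps weight molecules by track length;
  with state-independent bleaching this is unbiased for the molecule-level
  fraction, but state-dependent bleaching would bias it.
- The linearized CIs inherit the ECDF correlation problem (see above); use
  the bootstrap when the interval matters.
- k is limited to 1–3 components; mixtures beyond three exponentials are
  rarely identifiable from CDF data at these sample sizes.
- The projection's axis scaling distorts cells whose aspect ratio is far
  from 3:1; the clamped-point fraction is the diagnostic to watch.
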