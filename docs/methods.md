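# Methods

This note documents the models, estimators and numerical choices behind
smlmq, and what the synthetic-data validation does and does not establish.

## Coordinate and data conventions

Coordinates are continuous nanometres, origin at the top-left corner of the
field, x rightward, y downward; camera pixel (i, j) spans
[j·p, (j+1)·p) × [i·p, (i+1)·p) nm with its centre at ((j+0.5)·p, (i+0.5)·p).
Frames are 0-based. Histogram bins everywhere are half-open [lo, hi), so an
event exactly on an interior boundary belongs to the higher bin. The
localization table (CSV with `# key: value` metadata header) is the currency
between all stages; a reader shim accepts the common bracketed-unit headers
(`x [nm]`, `intensity [photon]`), converting `[px]` columns by the camera
pixel size.

## Synthetic data: what it emulates

The generators target a TIRF PALM/STORM acquisition of a membrane protein:
a 25×25 µm illuminated field at 100 nm camera pixels, 30 000 frames, mean
localization precision 20 nm (photoconvertible-protein regime) or 12 nm
(organic-dye regime), and membrane point patterns that are either
homogeneous Poisson (CSR) or Thomas-clustered.

- **Molecule patterns.** The clustered generator is a Thomas (Neyman–Scott)
  process — Poisson parents of intensity κ, Poisson offspring counts of
  mean ρ/κ, isotropic Gaussian displacements of scale s — because its pair
  correlation has the closed form g(r) = 1 + exp(−r²/4s²)/(4πκs²), usable
  as an exact oracle. Parents are drawn on a field extended by 5s so the
  restricted pattern is exactly stationary. The analysis-side cluster model
  is exponential (see below); the two are deliberately different so that
  curve-level fits can be validated exactly against their own model while
  point-level behaviour is validated as an ordering (fitted ξ monotone in
  s), not as a numeric identity.
- **Blinking.** Each molecule emits B localizations with B geometric on
  {1, 2, …} of mean m (memoryless switching; one parameter; the standard
  photophysics null). Blinks are assigned uniformly to frames; consecutive
  -frame bursts and explicit on/off rate constants are out of scope. Each
  blink is displaced by an isotropic Gaussian of the target precision; the
  per-row precision column is jittered (clipped Gaussian, ±20%) and
  rescaled so its table mean equals the target exactly, and photons/widths
  are drawn so the precision formula round-trips per row.
- **Raw frames.** Events are rendered as integrated 2D Gaussians (error
  -function pixel integrals) over a constant background with per-pixel
  Poisson noise. No EMCCD excess-noise factor and no 3D PSF model.
- **Time courses.** Endogenous density starts at steady state 1 and relaxes
  toward its production/degradation ratio; exogenous starts at 0; total is
  their sum before multiplicative Gaussian noise. Default ratios 0.84/1.40
  (summing to 2.24) with a 40 h half-life mirror the competitive
  -transfection scenario the kinetics module addresses.

Passing tests on these generators show the estimators are correct for
stationary patterns with Gaussian localization error and geometric
blinking. They do not establish robustness to fixation artefacts,
antibody-label displacement, sample-dependent photophysics, astigmatic 3D
PSFs, or non-uniform illumination — real-data features the generator does
not emulate.

## Localization

Background is a per-pixel sliding temporal median (default window 101
frames, mirror-padded at the stack edges so an event on an edge frame
enters its own window only once). Candidate detection thresholds local
maxima at a multiple (default 5) of the frame's robust noise scale,
1.4826×MAD of the background-subtracted frame computed before zero
-clipping; greedy suppression keeps the brighter of any pair closer than
the minimum separation, ties broken in row-major order. Each candidate
patch (9×9 px) is fitted with a symmetric 2D Gaussian plus offset,
sampled at pixel centres, by trust-region least squares with tolerances at
machine precision (noise-free patches recover positions to <1e-6 nm).
Detected photons are defined as the fitted volume above offset,
2πA(σ/p)², which is what the precision formula's "detected photons" most
defensibly means; users comparing with raw pixel sums should expect small
differences. Precision is FWHM/√N = 2√(2 ln 2)·σ_fit/√N. Rows are rejected
when the optimizer fails, photons fall below a floor, or σ_fit leaves
[50, 300] nm (a noise fit typically pairs low amplitude with a large
width); every rejection is counted in the log.

Drift correction bins the acquisition (default 1000 frames — 30 bins over
a 30 000-frame acquisition balances signal per bin against temporal
resolution), renders each bin at 20 nm, and estimates each bin's offset
against the first by FFT cross-correlation. The correlation peak is
refined by the centroid of its 3×3 neighbourhood after subtracting the
median of the surrounding 5×5 ring — the ring median estimates the broad
cross-pair plateau, whose tilt otherwise biases the centroid; histograms
are pre-smoothed by a 1-pixel Gaussian for the same reason. Bins with
fewer than 50 localizations are interpolated from their neighbours.
Per-frame displacements interpolate linearly between bin centres. On the
synthetic acquisition this recovers a 300 nm linear drift to within
~7 nm and is idempotent to ~2 nm.

## Pair-correlation analysis

**Estimators.** The production estimator bins localizations (default 5 nm),
computes the 2D autocorrelation of the zero-padded count image by FFT,
normalizes by n(n−1)/N_W² and by the autocorrelation of the window mask
(translational edge correction), and radially averages with ratio-of-sums
weighting; the zero offset (self-pairs) is excluded, and bins with no
admissible offsets are dropped. The oracle estimator histograms exact pair
distances and divides by the closed-form expectation from the isotropised
set covariance of the rectangle, γ̄(r) = ab − 2(a+b)r/π + r²/π. The two
agree to max|Δg| ≲ 0.02 on dense 2000-point patterns at 2 nm grids. Both
share one known property of ratio estimators: normalizing by the realized
count couples numerator and denominator, biasing g low by a few percent
when the window holds only a few hundred clusters; oracle tests therefore
normalize by the generator's true intensity, and real-data users should
prefer windows containing many clusters.

**Models.** The random (blinking-only) model is
g(r) = exp(−r²/4σ²)/(4πσ²ρ) + 1; the clustered model adds an exponential
cluster term convolved with the unit-mass PSF pair kernel
g_PSF(r) = exp(−r²/4σ²)/(4πσ²):
g(r) = g_stoch(r) + (A e^{−r/ξ} + 1) ⊛ g_PSF. The convolution is split by
linearity: the constant convolves to exactly 1 (g_PSF has unit mass), so
only A e^{−r/ξ} ⊛ g_PSF needs quadrature — a 1D radial integral using the
Bessel identity for the angular part, evaluated with the exponentially
scaled i0e for stability, step min(σ, ξ)/10 floored at 0.4 nm. This makes
the A = 0 reduction to the random model exact to machine precision and
matches a 2D grid convolution to <1%. Treating the printed composition as
multiplication instead of convolution would break that nested-model
reduction.

**Fitting and model choice.** Weighted least squares (per-bin Poisson-style
standard errors when available), σ initialized from the table's mean
precision, ξ from the 1/e decay radius of the excess, bounds A ≥ 0,
ξ ∈ (dr, r_max), σ ∈ [2, 500] nm. ρ can be fixed (e.g. localization
density / mean blinks) or fitted; fitting ρ is the default in analysis
examples because blink-count dispersion rescales the effective amplitude
of g_stoch (for geometric blinks by 2(1−1/m)), which a fixed ρ cannot
absorb and which would otherwise masquerade as clustering. Model choice is
a nested F-test on the residual sums of squares (the clustered model adds
two parameters; ties go to the random model by parsimony). The F-test
assumes quasi-independent residuals; blink clouds correlate neighbouring
fine bins, so selection runs use an interior window (≥100 nm inside the
simulated field, avoiding edge-truncation uplift of the baseline) and
40 nm correlation bins, under which the type-I rate is at the nominal
level (98/100 null acquisitions select the random model). Fine 5 nm bins
remain the default for parameter estimation, where no distributional
assumption is needed.

## Density quantification

Per-image statistic: mean of 5 ROI densities (events/µm², mean of means);
ROI areas 0.7–2.5 µm². Automatic ROI placement is a heuristic
operationalizing "avoid voids and borders": square candidates on a grid
are accepted iff their density is ≥25% of the median candidate density and
they lie ≥1 µm inside the bounding box of all localizations; the n most
internally uniform (lowest quadrant CV) are kept greedily without overlap,
deterministically for a given seed. Manual ROIs bypass the heuristic.
Group summaries report mean, SEM (SD/√n, ddof 1) and percent of control;
groups are compared by one-way ANOVA on per-image means (n = cells, not
ROIs — using ROIs as replicates would pseudo-replicate within cells).
Densities are localized events, not molecules: blinking multiplicity is
unknown for real data, so molecular conversion is deliberately out of
scope. The axial profile is a 100 nm-step histogram of z from the
coverslip, normalized to sum to 1.

## Kinetics

D(t) = (1 − P/k) e^{−kt} + P/k with k = ln 2/t_half (default 40 h, the
literature membrane half-life for the Na,K-ATPase α1 pump, surfaced in
output metadata); the exogenous compartment uses D0 = 0. Rate inversion is
closed-form, P/k = (D − e^{−kt})/(1 − e^{−kt}), valid for D > e^{−kt}, and
round-trips with the forward solution to 1e-12. Because both compartments
share k, their sum equals a single compartment with summed P/k — asserted
numerically. Competition decomposition works on the percent-of-control
scale: endogenous = total − exogenous, reduction = 100 − endogenous.
Time-course fitting is bounded least squares with standard errors from the
Jacobian; with the half-life fixed only P/k is estimated.

## Problem sizes in tests

The test suite runs the pipeline at reduced but statistically meaningful
sizes chosen so each check retains its power: 3.2–10 µm fields,
5000–30 000 frames, 10³–10⁵ points per pattern, 20–100 seeded replicates
for Monte-Carlo checks. These sizes keep the full suite to a few minutes
while leaving every acceptance margin (e.g. ≥95/100 model selections,
10% median recovery error) comfortably resolved.

## Known limitations

- No multi-emitter fitting; overlapping events in dense frames are
  rejected, not resolved.
- No 3D PSF model: 3D synthetic points carry z directly.
- The F-test calibration is demonstrated for the generator's geometric
  blink statistics; heavier-tailed photophysics would require recalibrating
  the bin width or a resampling-based test.
- ROI auto-selection is a stand-in heuristic; published analyses should
  report manually verified ROIs.
- The brute-force g(r) estimator is quadratic and capped at 5000 points.
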