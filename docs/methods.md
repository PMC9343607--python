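# Methods

This note documents the models, estimators, parameter choices, and numerical
decisions behind `spherosort`, and what its synthetic-data tests do and do
not establish about real spheroid data.

## Spheroid geometry and sorting statistics

The spheroid core is represented as an ellipse. Two fitting routes are
provided, matching the two kinds of input a spheroid assay produces:

- **Binary mask** (thresholded brightfield slice): moment-based equivalent
  ellipse — centroid plus second central moments, the same construction as
  Fiji's *Fit Ellipse*. Pixel centers sit at integer, 0-based coordinates
  with x = column; a 1/12 px² sheppard correction on the diagonal moments
  makes a rasterized disc of radius R return semi-axes R rather than the
  slightly smaller point-sample value.
- **Point set** (≥ 5 non-collinear boundary points): direct least-squares
  conic fit (Fitzgibbon's constrained eigenproblem) on standardized
  coordinates for conditioning, followed by conic-to-geometric conversion.
  Collinear or insufficient points raise a geometry error.

**Distance Index.** `DI = d/a` with `d` the Euclidean distance to the
center — the assay's literal definition — is the default
(`normalization="major-axis"`). Because a boundary point on the minor axis
then scores `b/a < 1`, an alternative elliptical normalization
`sqrt((x'/a)² + (y'/b)²)` (exactly 1 on the whole boundary) is provided and
recorded in outputs. Neither is asserted to be "the" definition; the flag
travels with the numbers. ΔDI is DI at a track's last spot minus DI at its
first, evaluated against per-frame geometry when one is supplied (growing
spheroids imaged daily) and against the single static geometry otherwise.

**Compartments.** The edge compartment is the 30 µm ring (≈ two cell
layers) adjacent to the spheroid–matrix interface. Membership uses the true
Euclidean point-to-ellipse distance, not a shrunken-ellipse approximation:
the distance is obtained by solving the ellipse normal equation
`(a x0/(t+a²))² + (b y0/(t+b²))² = 1` for the Lagrange parameter `t` by
safeguarded bisection on the first-quadrant reduction (Eberly's robust
formulation), which is monotone and converges to ~1e-12·max(a,b). Axis
points are handled through the evolute criterion. Acceptance testing checks
it against a 10⁶-point boundary-sampling oracle to < 0.01 µm over random
ellipses. Tracks are labelled edge/core from their **first** spot only;
later compartment switches never relabel.

## Track curation

Reading supports the TrackMate `<Model><AllSpots>/<AllTracks>` schema
(spots resolved through edge source/target IDs; unknown attributes
ignored) and tidy CSV. Pixel coordinates are multiplied by the calibration
(µm/px); times are `frame × dt`, with any explicit file times honored only
when consistent. z coordinates are accepted and dropped with a warning —
the analysis is planar (single median slice).

Curation order is: **filter on raw spot count (≥ 5), then close gaps**.
Interpolated spots therefore never rescue a short track. Gap closing fills
every missing interior frame on the linear segment between the bracketing
spots and flags inserted frames; endpoints are never altered.

## Polar MSD analysis

Tracks are transformed to `(r, ϕ)` about the spheroid center; `ϕ` is
unwrapped (±2π shifts whenever a step exceeds π) so the angular coordinate
is continuous; a spot exactly at the center keeps the previous angle.

The primary estimator is the **origin-referenced ensemble MSD**: at lag t,
`⟨(value(t) − value(0))²⟩` averaged with equal weight over every track that
reaches that lag. This matches the definition of the power laws in terms of
each trajectory's origin `(r0, ϕ0)`. A **time-averaged** variant (all
windows of each track contribute) is available behind a flag and recorded
in the output; it has far lower variance and is the right tool for
estimating diffusion coefficients from long tracks, at the price of mixing
time points. Angular MSD is reported in rad² on the unwrapped angle, with
no r-weighting — the natural unit for the polar power law; note this choice
when comparing against arc-length-based conventions.

**Power-law fit.** `msd = Γ·t^α` is fit by Levenberg–Marquardt nonlinear
least squares on the linear scale over lags in [0, 3 h]; lag 0 is excluded
(the model is degenerate there) and the fit is initialized from the log–log
linear regression, making it insensitive to starting values (exact data are
recovered to 1e-6 relative from random initializations). Standard errors
come from the fit covariance.

Those covariance-based errors are **anti-conservative on stochastic
ensembles**: squared displacements of the same track are strongly
correlated across lags, so the curve sits smoothly off its expectation and
residuals understate parameter uncertainty. `bootstrap_power_law` resamples
whole tracks (the independent unit, 200 resamples by default) and replaces
the standard errors with bootstrap ones; motility classification of noisy
data should use it, and the CLI does.

**Classification.** Diffusive when the 95% CI of α̂ contains 1; otherwise
super-/sub-diffusive. A fixed ±ε band around 1 would misbehave as sample
size varies; the CI rule adapts.

**Effective diffusion.** `D_eff(t) = (Γ/2)·t^(α−1)`, so that
`MSD = 2·D_eff(t)·t` holds identically (verified to < 1e-12 relative).
For non-diffusive motion this time-dependent coefficient is the only way to
express a diffusivity with correct units; data sets must be compared at the
same time point (3 h is used throughout).

## Simulator

Each cell follows an Ornstein–Uhlenbeck persistent random walk on velocity:

    v(t+dt) = v(t)·exp(−dt/τ) + ξ,   ξ ~ N(0, σ²(1−exp(−2dt/τ)))  per axis,

with σ = s/√2 so the stationary RMS speed is `s`, plus an optional constant
outward drift of magnitude `radial_bias·s` along the local boundary normal.
The OU process has the classic ballistic→diffusive crossover, so the same
machinery produces α ≈ 1 (τ ≪ lag range), α ≈ 2 (drift-dominated or
noiseless), and everything between. Positions advance by Euler–Maruyama at
the frame interval.

Boundary handling at the core ellipse: **sticky** cancels the outward
velocity/step component (projection onto the boundary tangent — the cell
slides and stays in the edge ring, emulating matrix affinity without an
adhesion energy model); **reflecting** mirrors it; **absorbing-free** lets
cells leave. For sticky/reflecting modes no position is ever outside the
ellipse (a final radial projection guards round-off).

Determinism: every cell gets its own `SeedSequence(master, spawn_key)`
stream keyed by global cell index, so output is byte-identical for a fixed
seed and independent of population order.

Default conditions mirror the assay design: 10-min frames over 44 h
(264 steps), a core of a few hundred µm, and a persistent:diffusive mix
(the 1:50 seeding ratio is available via `mixing_ratio`). The motility
magnitudes are free parameters of the model, not measured values: defaults
of `s = 0.5 µm/min`, τ = 2 min for the diffusive population and τ = 60 min
with `radial_bias = 0.5` for the persistent one were chosen once as
plausible for epithelial cells in dense spheroids and produce clear regime
separation inside the 3 h fit window. For statistical tests the simulated
cohorts use 40 persistent vs. 200 diffusive tracks — desk-scale counts with
enough power for the sorting comparison; the seeding ratio of a real
experiment governs how many cells get *tracked*, which is what these counts
emulate.

What the simulator does **not** model: cell–cell mechanics, proliferation,
volume exclusion, matrix degradation fields, 3D geometry (the analysis is
planar, as for median-slice imaging), or measurement noise on positions.
Passing tests therefore demonstrate the correctness of the estimators under
the stated stochastic model, not biological fidelity of any parameter.

Image fixtures: degradation images are dark discs (holes) stamped on a
bright uniform gelatin background with optional seeded Gaussian noise; the
exact union area of the rasterized discs is returned as ground truth.
Nuclei-like blob images are the bright-on-dark counterpart.

## Image quantification

Degradation: global automatic threshold (Otsu default; Li/Yen/mean/triangle
selectable, method recorded in the output), dark pixels below threshold are
holes, 8-connected components smaller than 4 px² are discarded as noise,
areas convert by (µm/px)² and divide by the manually counted cell number.
Stacks are max-intensity projected first. A constant (blank) image returns
zero area rather than thresholding noise. Foreground area quantification is
the same machinery with bright-side polarity; boolean masks are counted
directly.

Junction/cytosol ratio: a 10 µm segment centered on the junction is sampled
every 0.1 µm by bilinear interpolation (pixel centers at integer
coordinates); the intensity at arc position 0 is "cytosol", at 5 µm
"junction", and the ratio is junction/cytosol, undefined for zero cytosol
signal. The measurement is rotation-equivariant to within ~1%
interpolation error on smooth scenes.

## Two-sample statistics

`compare_groups` implements the decision tree: Shapiro–Wilk per sample at
the 0.05 gate — rejection in **either** sample (the conservative OR rule)
routes to the Wilcoxon rank-sum test (exact for n ≤ 20, asymptotic above);
otherwise a two-sided variance-ratio F test chooses between the pooled
Student t-test and the Welch t-test. All comparisons are unpaired and
two-sided. Constant samples (Shapiro–Wilk undefined) fall through to
Wilcoxon with a warning. Under a Gaussian null the empirical type-I error
at the 0.05 gate calibrates to [0.03, 0.07] over 2000 replicates. No
multiple-testing correction is applied by default, matching
per-comparison reporting; a Benjamini–Hochberg helper is available.

## Problem sizes

The test suite and acceptance script use: 200 tracks × 264 frames for
diffusive-exponent recovery, 100 × 60 for the drift regime, 500 Brownian
tracks for diffusion-coefficient recovery, 240 mixed tracks over 44 h for
sorting emergence, 10⁴ random point–ellipse pairs against a 10⁶-point
boundary oracle, 256² px image fixtures, and 2000 null replicates for the
statistics calibration. Everything runs in well under a minute per stage on
a single CPU.

## Known limitations

- The ensemble MSD at 200 tracks has ~8–10% relative noise in α̂; exponent
  bands in tests reflect that.
- The sticky boundary is a kinematic projection, not an adhesion model;
  edge-retention strength is not a fitted biophysical parameter.
- The moment-based mask fit assumes one dominant connected component;
  multi-blob masks keep the largest with a warning.
- The TrackMate dialect covers the `AllSpots`/`AllTracks` schema (v6+);
  spot detection and linking quality are out of scope — tracks are taken
  as given.
- Angular MSD units (rad²) make Γ_ϕ incomparable to Γ_r in magnitude;
  compare exponents, not amplitudes, across directions.
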