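# Methods

This note records the models implemented in `cellmech`, the parameter
choices that matter, what the synthetic generators do and do not emulate,
and the numerical decisions taken where the design was genuinely open.

## Particle morphometry

Segmentation is a global auto-threshold (default Otsu; IsoData, Li, mean,
triangle and Yen are selectable), binary hole filling, optional removal of
border-touching components, and 8-connected labelling. Border particles
are excluded by default because partially imaged cells bias area downward.

Descriptors per particle:

- area A = pixel count × pixel_size² (µm²);
- perimeter P by the Crofton multi-direction estimator. Naive boundary-pixel
  counting overestimates P by ~10% and drags the circularity of a digitized
  circle to ≈0.8; the Crofton estimate keeps rendered disks at C ≈ 0.97–1.
- circularity C = 4πA/P², clipped at 1 (digitization can push it above);
- inverse aspect ratio = minor/major axis of the moment-equivalent ellipse
  (second-order central moments, the "fit ellipse" convention);
- solidity = A / convex-hull area;
- equivalent diameter d = √(4A/π).

The particle filter retains 300–1,250 px² and circularity 0.65–1 by
default — the windows used for suspended-cell/bead images to excise debris
and touching aggregates; both are configurable per call and on the CLI.

The bead-sizing validation (300 disks, diameters ~ N(9.94, 1.01²) µm
truncated at zero, 0.3 µm/px) recovers the generating mean within 2%. Two
systematic effects are worth knowing: (i) rasterization error on a ~17 px
radius disk is far below 1%; (ii) at 0.3 µm/px the 1,250 px² ceiling of the
particle filter corresponds to an 11.97 µm diameter, so the top ~2% of the
batch distribution is excluded, biasing the measured mean down by ≈0.5%.
The real phase-contrast workflow has the opposite, larger systematic (halo
overestimation), which the renderer deliberately does not model.

## Persistent-random-walk migration model

Cell paths are modelled as a 2D Ornstein–Uhlenbeck velocity process:
each velocity component has stationary variance D/τ and correlation time
τ, and position is the exact integral of velocity. The ensemble MSD is the
Fürth form MSD(t) = 4D[t − τ(1 − e^(−t/τ))], ballistic (2D/τ)t² at short
lags and diffusive 4Dt at long lags.

The generator samples the exact joint Gaussian transition of
(position increment, velocity) per step — with θ = dt/τ, E = e^(−θ),
σ² = D/τ:

    Var(Δx) = σ²τ²(2θ − 3 + 4E − E²),  Var(v') = σ²(1 − E²),
    Cov(Δx, v') = σ²τ(1 − E)²

— rather than an Euler step, so the Fürth form holds exactly at the
discrete sampling times for any dt and no step-size bias enters recovery
tests. Velocities start in the stationary distribution, making increments
stationary.

MSD estimation uses all overlapping ordered pairs at each lag (a time
average; n_pairs = N − k at lag k), by default up to 50% of the track
duration — longer lags average too few pairs to be useful.

Fitting is trust-region least squares over (D, τ) with positivity bounds.
The residuals are *relative*, weighted by √n_pairs: the sampling
fluctuation of a time-averaged MSD estimate is proportional to its mean
(squared-displacement summands have variance of order their mean squared),
so Var(MSD_k) ∝ msd_k²/n_pairs_k. With absolute residuals the diffusive
tail — large, noisy, strongly autocorrelated — swamps the short-lag
curvature that identifies τ, and recovery degrades several-fold.
Initialization: D from the slope of the last quartile of lags / 4, τ from
the first lag. Non-convergence is flagged on the result, never silent.

Identifiability: τ is resolvable only when dt ≲ τ/2. The parameter-recovery
study (D ∈ {1, 10, 50} µm²/min × τ ∈ {2, 10} min; 200 tracks × 100 steps)
therefore samples at dt = 1 min; at a 5-min interval a 2-min persistence
time sits below the sampling scale and no estimator can recover it. Both
parameters come back within 15% on that grid (typically within 5–12%),
and within ~1% for well-resolved cases (τ = 5 min, dt = 1 min).

Speed is path length / elapsed time at the native sampling interval —
"speed" for tracked cells conventionally means the path-based quantity;
the displacement-based alternative is the chemotactic numerator instead.
The chemotactic index is net displacement projected on the gradient axis
divided by total path length — bounded in [−1, 1], the standard definition
for microchannel chemotaxis.

## Hertz AFM analysis

The spherical-tip Hertz law F = (4/3)·E/(1−ν²)·√r·δ^{3/2} is used exactly
as written — no Sneddon conical variant — with ν = 0.45 and r = 30 nm as
defaults. The fit estimates (log E, contact point z₀, force baseline)
jointly: contact-point pre-detection by thresholding biases E downward on
soft samples, so z₀ is a free parameter. Indentation is δ = max(z − z₀, 0)
for force-vs-distance input; raw deflection-vs-piezo data are converted via
z_tip = z_piezo − d, F = k·d (`force_curve_from_deflection`).

Numerics: E is fit in log space (the plausible range spans kPa–GPa);
tolerances are tightened to 1e-14 because with the default settings the
trust-region step stalls within ~10% of the initialization on noiseless
curves. A curve whose rise above baseline stays below 10× the baseline
noise (MAD-estimated) raises a no-contact error. An optional force ceiling
restricts the fit to the triggered range (≈1.35 nN); on synthetic
1–100 kPa curves this changes E by < 5%.

Force maps (100 curves over a 5 µm² region in the emulated acquisition)
aggregate converged per-curve moduli with the median by default — robust
to occasional glass-proximity stiffening or debris — with the mean
available by flag; the non-converged fraction is reported.

Recovery: noiseless curves invert to < 1%; with 10 pN Gaussian force noise
the median of 100 curves is within 5% of truth for 1–100 kPa.

## Focal-adhesion scoring

Marker channels are background-subtracted with a rolling ball (radius
50 px; a plain grayscale-opening variant is available and serves as a
cross-check), auto-thresholded (Otsu default), labelled 8-connected, and
filtered at a minimum adhesion size of 4.14 µm² — interpreted as an area,
since minimum "size" in particle analysis is an area; the cutoff is
configurable. Cell area is segmented from the actin channel (threshold,
largest component, fill holes). An adhesion counts toward a cell if its
centroid lies inside the actin mask; density = count / cell area.
Processing runs in native bit depth; 8-bit conversion first yields the
same masks on clean synthetic data (verified in the tests).

## Statistics battery

- Normality: D'Agostino–Pearson K² (skewness + kurtosis z-scores, χ²₂);
  requires n ≥ 8, errors on constant input. Groups too small or degenerate
  to test are treated as non-normal for branching.
- Branch rule: if the groups follow *or partially follow* a normal
  distribution (≥ 1 group passes at α = 0.05 — the permissive rule),
  one-way or two-way ANOVA with a Tukey follow-up; if no group is normal,
  tie-corrected Kruskal–Wallis with Dunn's pairwise z-tests. The orthodox
  all-groups-normal predicate is available (`normality_rule="all"`).
- Dunn's z uses the pooled-rank variance N(N+1)/12 minus the tie term
  Σ(t³−t)/(12(N−1)); adjustment is Bonferroni over all pairs by default
  (Holm and none available). All-identical pooled data short-circuits to
  H = 0, p = 1.
- ROUT outliers, univariate special case: the original procedure couples a
  robust nonlinear fit with FDR-controlled residual flagging; for a single
  sample the robust fit degenerates to the median with MAD-based scale
  (×1.4826), residual p-values from t(n−1), and a Benjamini–Hochberg step
  at Q (default 1%) choosing the flag set. Zero MAD falls back to the IQR
  scale with a warning; flags are returned, data are never deleted by the
  library. The pipeline's documented order is flag → exclude → re-test.

## Synthetic data: what it does and does not emulate

Generators provide bright-on-dark shapes rendered without anti-aliasing
(a pixel is foreground iff its center is inside the analytic shape, making
truth areas reproducible), exact-transition random walks, Hertzian curves
with Gaussian force noise, and disk-shaped adhesion puncta placed without
overlap inside a cell footprint. Ground-truth tables carry analytic
descriptors computed from the geometry; for adhesions they also record the
realized rasterized area (pixel count × pixel area), which is the right
reference for cutoff-exactness checks.

Not modelled: phase-contrast halos (which inflate measured bead diameters
in the real workflow), uneven illumination, shot noise, out-of-focus
light, cell–cell contact, track gaps or localization error, cantilever
hydrodynamics, and adhesion shape irregularity. Passing the recovery
suites therefore demonstrates the correctness of the measurement chain on
well-posed inputs — not robustness to these instrument effects.

## Problem sizes

The validation suites use 300 beads, 200-track ensembles of 100 steps,
100-curve force maps, ≤ 12 adhesions per cell, and 1,000-replicate null
calibrations — sizes at which the Monte-Carlo error of each check sits
comfortably below its acceptance tolerance while the full test suite runs
in well under a minute per module.
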