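# cellmech

Quantitative mechanophenotyping of cultured cells: a tested, reusable
implementation of the measurement chain used to compare tumor-cell clones
by shape, motility, stiffness, and adhesion — together with synthetic-data
generators that produce every input class with exact ground truth, so the
whole pipeline can be validated end to end without microscope data.

It is aimed at cell biologists and biophysicists who quantify phase-contrast,
time-lapse, AFM, and immunofluorescence experiments and want the analysis
steps — usually spread across ImageJ macros, vendor AFM software, and a
stats package — as one scriptable, testable library.

## What it computes

**Particle morphometry** (`cellmech.morphometry`). Images of suspended
beads/cells or adherent silhouettes are auto-thresholded (Otsu by default),
hole-filled, and labelled 8-connected; per particle the pipeline reports
area *A*, Crofton perimeter *P*, circularity 4π*A*/*P*² (1 for a circle),
inverse aspect ratio (minor/major axis of the moment-equivalent ellipse),
solidity (*A* / convex area), and equivalent diameter √(4*A*/π). A particle
filter (defaults 300–1,250 px² and circularity 0.65–1) rejects debris and
aggregates.

**Migration analysis** (`cellmech.migration`). From (t, x, y) tracks:
path-based speed; time-averaged mean-squared displacement over all
overlapping pairs; a weighted nonlinear fit of the Fürth
persistent-random-walk form

&nbsp;&nbsp;&nbsp;&nbsp;MSD(t) = 4D·[t − τ(1 − e^(−t/τ))]

for the diffusion coefficient D (µm²/min) and persistence time τ (min);
and the chemotactic index (net on-axis displacement / path length).

**AFM stiffness** (`cellmech.afm`). Force curves are fit to the
spherical-tip Hertz model

&nbsp;&nbsp;&nbsp;&nbsp;F = (4/3)·E/(1 − ν²)·√r·δ^{3/2}

with the contact point and baseline estimated jointly with the Young's
modulus E (defaults ν = 0.45, tip radius r = 30 nm); 100-curve force maps
aggregate to a per-cell modulus (median by default).

**Focal adhesions** (`cellmech.focal_adhesions`). Marker channels
(phospho-paxillin / phospho-FAK) get rolling-ball background subtraction
(50 px), auto-thresholding, and a minimum adhesion size of 4.14 µm²; cell
area comes from the actin channel, and adhesion density is count / cell
area.

**Statistics battery** (`cellmech.stats`). D'Agostino–Pearson normality per
group; Kruskal–Wallis + Dunn's (Bonferroni-adjusted) when the data are not
normal, one-/two-way ANOVA + Tukey when they are (or partially are);
ROUT-style FDR-controlled outlier flagging (Q = 1%), with the documented
order flag → exclude → test.

**Synthetic ground truth** (`cellmech.synthetic`). Renders bead/cell
silhouettes with analytic descriptors, samples persistent random walks by
the exact Ornstein–Uhlenbeck transition (so the Fürth form holds at any
sampling interval), generates Hertzian force curves, and places adhesion
puncta with known per-blob areas.

## Worked example

```python
import numpy as np
from cellmech import measure_particles, ensemble_msd, fit_prw, fit_hertz
from cellmech.synthetic import bead_field, generate_prw_ensemble, generate_hertz_curve

# 300 calibration beads (9.94 ± 1.01 µm batch) sized by the particle pipeline
image, truth = bead_field(300, pixel_size=0.3, seed=1)
records = measure_particles(image)
d = [r.equiv_diameter_um for r in records]
print(f"{len(records)} beads: measured {np.mean(d):.2f} ± {np.std(d):.2f} µm "
      f"(generated {truth.equiv_diameter_um.mean():.2f} µm)")

# persistent-random-walk fit on 200 synthetic tracks
tracks = generate_prw_ensemble(200, D=10.0, tau=5.0, dt=1.0, n_steps=100, seed=1)
print(fit_prw(ensemble_msd(tracks)).summary())

# Hertz fit of a noisy synthetic indentation curve (1 kPa ground truth)
z = np.linspace(0, 2e-6, 400)
curve = generate_hertz_curve(E=1000.0, nu=0.45, r=30e-9, contact_point=0.8e-6,
                             z_grid=z, noise_sd=1e-11, seed=1)
print(fit_hertz(curve).summary())
```

prints

```
294 beads: measured 9.78 ± 0.86 µm (generated 9.84 µm)
Persistent-random-walk fit (Furth MSD)
  D    = 10.01 um^2/min  (se 0.014)
  tau  = 5.052 min     (se 0.016)
  RSS  = 0.001013  over 50 lags
  converged: True
Hertz fit
  E            = 1014 Pa  (se 9.9)
  contact z0   = 8.073e-07 m
  ...
```

The bead mean lands within 2% of the generating 9.94 µm batch mean (six
beads above ~12 µm fall outside the 1,250 px² filter window, a ≈0.5%
downward nudge discussed in `docs/methods.md`); D and τ are recovered
within ~1%, and the fitted modulus within ~1.5% of the 1 kPa ground truth.

A full run — generate all synthetic inputs, quantify each modality, and
compare groups — is one command:

```
cellmech run-all --outdir demo_out --seed 1
```

with per-stage CSV outputs and a provenance log (`run_report.json`) in
`demo_out/`. Individual stages are available as `cellmech generate`,
`morphometry`, `migrate`, `afm`, `fa`, and `stats`.

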