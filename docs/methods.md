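# Methods

This note records the models, parameter choices, numerical decisions and known
limitations of the package, in the spirit of a model-description appendix.

## Surface estimation from serial-section traces

A traced ASI is an ordered stack of planar contours on consecutive sections of
thickness *T* (default 0.045 µm, the midpoint of the nominal 40–50 nm range;
pixel size default 0.004 µm). *m* contours define *m − 1* slabs between
consecutive sections. Each slab contributes half the perimeter of its top and
bottom trace times *T* (the two lateral walls of the sheet), plus the
**absolute** difference of the trace areas (the exposed horizontal ring where
consecutive traces differ in size). The first and last trace areas are then
subtracted as end caps and the result is halved, because the traced element is
a two-faced sheet and the quantity of interest is one apposed face.

Decisions worth stating:

- **Slab convention.** *m* contours → *m − 1* slabs. This reproduces the
  lateral surface of right prisms exactly: for a contour of perimeter *P* and
  area *A* repeated *m* times, apposed = (*P·T·(m−1) − 2A*)/2.
- **Absolute ring areas.** With a *signed* area term the slab contributions
  telescope to *A(first) − A(last)* and the final estimate changes when the
  stack is traversed in the opposite direction — an orientation dependence
  with no physical meaning. The absolute value restores exact invariance
  under section-order reversal (and equals the signed sum for monotonically
  shrinking or growing objects).
- **Perimeter smoothing.** "Smoothed perimeter" is implemented as a circular
  moving average of the vertex coordinates with an odd window; the default
  window of 1 means no smoothing, because no particular smoother is canonical
  and an unsmoothed perimeter is reproducible. The window is exposed
  everywhere. Whether the original tracing software smooths before or after
  pixelation is not determinable from the tracing conventions alone; this is
  recorded, not guessed.
- **Clamping.** For very thin stacks the end caps can exceed the lateral sum;
  negative results are clamped to zero and flagged, since areas are physical.
- **Single-section objects** are supported with raw bound *Ps·T* and flagged.
- **Ribbons vs outlines.** Both closed outlines and 1-pixel ribbon rectangles
  are just polygons to the estimator; the ribbon interpretation (width =
  pixel size) is the documented default for ASI traces. For a straight ribbon
  of length *L* and width *w* the apposed estimate is
  *L(T(m−1) − w) + wT(m−1)*, i.e. the mid-line sheet area with an
  O(*w/(T(m−1))*) relative bias from the end caps — about 2% at 5 sections
  and 0.4% at 11 sections for 4-nm ribbons. Below 5 sections the bias can
  exceed 3%, which bounds the accuracy achievable for the very smallest
  synapses.

Degenerate (collinear, zero-area) traces are legal and contribute zero area;
self-intersecting polygons and gaps in the section indexing are errors (no
interpolation is attempted).

## Cohort structure, filters and summaries

The canonical container is a spine-level pandas DataFrame (one row per
protrusion) carrying the dendrite- and mouse-level covariates. A protrusion
counts as a synapse iff it has ≥ 1 presynaptic vesicle within 50 nm of the
apposed membrane, a visible cleft and a postsynaptic density. Dendrite
inclusion mirrors the sampling rules: diameter within the age-group range
(0.44–2.24 µm at P13, 0.54–1.74 µm at P30), at least `min_spines` (default 3)
protrusions, and not a sparsely spiny segment dominated by shaft synapses.
The "few spines" threshold of that last rule is not fixed by the sampling
description; we use `few_spines = 2·min_spines` (default 6), configurable.

Spine densities are counts per µm² of the **lateral cylinder surface**
π·diameter·length. The reconstructed mesh surface is not available in this
representation; the cylinder is consistent with reporting mean diameter and
length per dendrite, and the choice only rescales densities by a
condition-independent factor. The without-synapse density is computed as
total minus with-synapse density so the partition is exact in floating point.
Oblique spines (synapse present but unmeasurable interface) contribute to
densities and percentages but never to ASI statistics. The SD of a single
observation is reported as 0.

## Mixed-effects inference

All group comparisons use Gaussian linear mixed models on transformed
responses — log for ASI and organelle volumes (volumes are strictly positive
by construction; the log keeps them on a multiplicative scale like ASI),
square root for densities — with a mouse random intercept and, for
spine-level responses, a dendrite intercept nested in mouse. Estimation is
maximum likelihood (not REML) so that likelihood-ratio tests between nested
fixed-effect structures are valid.

The default estimator profiles the likelihood down to the variance ratios
γ_m = σ²_mouse/σ²_resid and γ_d = σ²_dendrite/σ²_resid: for fixed ratios the
GLS β and the residual variance are closed-form, V⁻¹ and log|V| are computed
exactly per mouse block with two nested Sherman–Morrison steps (only
per-dendrite and per-mouse sums are needed), and the two ratios are optimised
by Nelder–Mead on the log scale from three starts (tolerance 1e-9 on the
objective, 500 iterations, ratio floor e⁻³⁰ ≈ 0). Variance components are
thereby bounded at zero; a boundary estimate simply reports SD ≈ 0. The fit
agrees with lme4's `lmer(..., REML=FALSE)` to ~7 significant digits on
reference data (pinned in the tests) and with the statsmodels MixedLM
backend, which remains selectable (`backend="statsmodels"`) as an independent
route.

Inference conventions:

- LRT statistic 2Δℓ clamped at zero, chi-square reference with df = the
  difference in fixed-effect parameter counts (the df convention for
  interaction tests is exactly this parameter-count difference).
- Pairwise contrasts use the fixed-effect covariance; the default
  multiplicity adjustment is single-step max-|z| estimated from 50 000 seeded
  Monte-Carlo draws of the joint contrast correlation (Holm and Bonferroni
  are deterministic alternatives). Contrasts inside an endosome stratum add
  the interaction coefficients to the condition effects before differencing.
- Reference levels follow the published parameterisation: CSR for the P30 ASI
  model, EW15 for the P13 models.
- Diagnostics return conditional residuals (observed − fixed − BLUP random
  effects) and normal-quantile pairs; no plotting in the core.
- The truncation sweep refits a two-condition model after removing the q
  fraction smallest responses pooled across the pair (q = 0, 0.1, …, 0.9) and
  reports the Wald p-value profile and the first non-significant q.

**Small-sample caveat.** The chi-square calibration of the condition LRT is a
cluster-level asymptotic. Simulations with the packaged variance components
show the nominal 5% level is honest at ≥ 8 mice per condition (measured
0.056 over 500 null replicates at 32 mice) but visibly liberal at the
study's own 15 mice (~0.15 under mouse-level label permutation). Calibration
tests in the suite therefore run at 8–10 mice per condition; the few-cluster
liberality is an inherent property of the design, not of the estimator.

## Scaling analysis

The multiplicative-scaling hypothesis H₀: f₁(x) = f₂(x − c) on log areas is
tested by estimating c as the difference of sample medians (midpoint
interpolation at even n), aligning, and applying the two-sample KS test
(exact p below n = 30 per sample, asymptotic otherwise). Because c is
estimated from the same data, the test is **conservative**: under a true pure
shift (n = 500/500) the measured type-I rate at α = 0.05 is ≈ 0.006, a
Lilliefors-type effect of parameter estimation before a distribution test.
We document and quantify this rather than correct it, since the same
procedure underlies the original analyses; acceptance of H₀ is therefore
generous, while rejections (the informative outcome for shape changes —
power ≈ 1.0 against a twofold log-SD change at n = 1000) remain trustworthy.
The log-normality report uses a parametric bootstrap (default 2000
replicates, seeded) for the same reason. Samples are pooled across mice for
these tests, since no clustering correction is part of the procedure being
reproduced.

## Synthetic cohorts

The generator draws, per mouse, Gaussian intercepts for the ASI and density
models; per dendrite, a truncated-normal diameter and length (per-condition
moments from the descriptive summaries; diameters truncated at the filter
ranges so generated cohorts pass the inclusion filters unchanged), a nested
dendrite intercept, and a sqrt-normal synapse-bearing density whose rounded
product with the lateral cylinder surface gives the synapse-bearing spine
count (the density, not the count, is the modelled quantity); spines without
a synapse are appended at the per-condition published proportion. Per
synapse-bearing spine, log ASI = intercept + condition effect +
slope·diameter (+ endosome main effect and condition×endosome interaction at
P30 only; at P13 the endosome terms are omitted because no interaction was
found there) + mouse + dendrite intercepts + residual. Endosome and
spine-apparatus presence are Bernoulli with the published percentages; their
volumes are log-normal with plausible synthetic location/scale (no published
parameters exist — only the hierarchical structure of the volume models is
exercised, not their absolute levels). The oblique-spine fraction defaults to
0 (no published percentage); it is configurable.

The packaged P13 configuration transcribes the published model parameters;
its internal consistency was checked in closed form: the implied lognormal
group means (0.259/0.298/0.205/0.185 µm² for S/EW4/EW15/Rec) agree with the
published descriptive means (0.25/0.30/0.20/0.19) to well within 0.01 µm².
No published P30 density model exists; that block is moment-matched to the
P30 descriptive density means (mean = µ² + σ²_mouse + σ²_resid) with
pup-like variance components, and is marked as derived in the config notes.
Per-condition sqrt-density mouse/residual SDs and the length truncation range
(5–60 µm) are the only other invented quantities; both are stated in the
configs.

**Study-matched fixtures** use the published mouse counts (P13: 4/3/4/3 for
S/EW4/EW15/Rec; P30: 4/4/4/3 with CSR = 3) and add dendrites round-robin
across each group's mice until the cumulative synapse-bearing count reaches
the published group total (1066/912/1398/842 at P13; 1367/1347/1167/905 at
P30). A fixed dendrites-per-mouse count would leave the group totals with a
~9% CV under the generating variance structure; the stopping rule pins them
to within about half a dendrite and mirrors how a tracing study accumulates a
target number of synapses per animal. One ribbon contour stack is emitted per
measured spine, with section count ≈ 1 + √area/T and trace length solved in
closed form so the stack's estimated surface reproduces the spine's ASI
exactly (per-section jitter is rigid, which the estimator is invariant to).

What the generator deliberately does **not** emulate: imaging noise,
segmentation error, section-thickness variability, oblique synapses (by
default), spatial correlation along dendrites, and any non-Gaussian tails in
the random effects. Passing tests therefore demonstrate statistical
correctness of the pipeline under the generating model, not robustness to
real-data artefacts.

## Problem sizes used by the test and acceptance suites

Parameter-recovery runs use 40 mice/condition × 15 dendrites/mouse
(~60 000–105 000 spines; each model fits in a few seconds). Calibration
suites use 500 null replicates for the LRT (32 mice, 3 dendrites, 8
spines/dendrite), 200 mouse-level permutations (10 mice/condition), 1000
replicates for the scaling type-I rate (n = 500/500) and 200 study-matched
seeds for the qualitative orderings. These sizes were chosen so cluster-level
asymptotics hold and Monte-Carlo error is small relative to each assertion's
band.

## Known limitations

- The surface estimator is an upper-bound heuristic, not a mesh
  reconstruction; its accuracy claim (≈ 3%) is established on prism/ribbon
  geometries.
- The profiled-ML fitter covers exactly the model family used here (one or
  two nested random intercepts); crossed designs, random slopes and REML are
  out of scope.
- The scaling test's conservativeness means "no evidence against scaling" is
  a weak statement at these sample sizes.
- Density normalisation assumes a cylindrical dendrite.
- With 3–4 mice per condition, mouse-level LRT p-values are mildly liberal;
  between-litter effects beyond the mouse intercept are not modelled.
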