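# Methods

## Coordinate normalization

A soma's polar measurement (D, α) is taken from the ventral-most midline
point of its transverse section; α is measured in degrees from the
horizontal (medio-lateral) axis through that point, counter-clockwise
for the right hemicord. This convention is forced by the normalization
formulas themselves — sin α must give the vertical component — and the
interface accepts `angle_from="vertical"` for datasets digitized against
the other axis. The normalized position is DV = D·sin α/H,
ML = |D·cos α|/W. Taking |cos α| folds the two hemisections onto one
positive hemicord, which matches the practice of quantifying one side
per section; angles in (90°, 180°] therefore belong to somata on the
side whose lateral direction is opposite the reference direction.

H, W and D must share one length unit per dataset (px or µm); the unit
is validated for consistency but never converted, since only ratios
enter the coordinates. Measurement noise can push DV or ML slightly
above 1; values above 1.05 are flagged as out-of-range but kept, never
clamped, so downstream statistics see the data as measured. Coordinates
are continuous with origin at the ventral-most midline point; 0-based
half-open pixel semantics apply only to the intensity module's ROI
rectangles.

H and W are required per section (not per embryo): section-to-section
size variation is real and the per-section frame absorbs it.

## Hotelling T² comparison

The classical equal-covariance two-sample T² with the F(p, n₁+n₂−p−1)
conversion is used, requiring n₁, n₂ ≥ 3 and a well-conditioned pooled
covariance — a singular or near-singular S (condition number > 1e12)
raises an error rather than silently pseudo-inverting, because a test
the data cannot support should not be reported. Cells pooled across
sections and embryos are treated as independent observations, mirroring
how pooled 2D distribution plots integrate "multiple sections of
multiple embryos"; this is pseudoreplication with few embryos, so every
report records n_sections and n_embryos and carries an explicit caveat
string. The permutation companion permutes group labels over pooled
cells and uses the add-one estimator p = (1+k)/(1+B), which never
returns 0 and is deterministic given its seed.

Per-population, per-level tests are reported without multiplicity
correction by default (matching common practice for this design);
Bonferroni across strata is available via `bonferroni_levels`.

## Density estimation

1D profiles use a Gaussian kernel with Silverman's rule
h = 1.06·σ̂·n^(−1/5); 2D maps use a diagonal-bandwidth product kernel
with per-axis Silverman bandwidths. The evaluation grid spans
[min−3h, max+3h] united with [0, 1] and is deliberately not clipped at
the anatomical boundary, so the trapezoidal integral stays within 1% of
1 (2% in 2D) and profiles remain comparable across groups. No boundary
correction is applied; near dv = 0 a KDE spreads mass below zero, which
is visible in the curves but cancels in two-group overlays computed the
same way. The exact bandwidth/binning behind any published density
curve is generally unknowable, so no result here depends on matching a
specific curve shape.

## Counts, co-labeling, intensity

The unit of inference is the embryo: each embryo's five sections are
averaged first, then mean ± SEM is computed over n = 3 embryos
(`unit="section"` exists for power studies and is labeled as such). A
single embryo yields SEM = 0 by convention, flagged. The automatic test
rule — Shapiro–Wilk normality in both groups and a two-sided
variance-ratio F pretest, both at 0.05, selecting pooled-variance
Student's t when all pass and Mann–Whitney U otherwise — is one stated,
overridable operationalization of "choose t or Mann–Whitney based on
the variance in each group"; the report always names the test used.
Mann–Whitney is exact for group sizes ≤ 8 and tie-corrected-asymptotic
above; when every pooled observation is tied the result is p = 1.
Pooled Student's t is the default; Welch is a flag. The pretest cascade
slightly inflates the null rejection rate, which is why its calibration
bound is 0.07 rather than 0.05.

Co-labeling is set logic on per-cell marker annotations: per section,
the proportion of reference-population cells (markers ⊇ reference set)
whose markers also include the required set, with zero-denominator
sections reported as undefined and excluded from means. Proportions are
computed per section then averaged per embryo, consistent with the
count pipeline.

ISH intensity is the arithmetic mean of pixel values inside a
rectangular ROI of fixed area (13,500 px² default, enforced to within
one row/column of rounding) minus the mean of a user-placed,
non-overlapping adjacent background ROI; the net value is in arbitrary
units and is invariant to adding a constant to the whole image. ROI
placement is deliberately manual — automatic placement would be a
segmentation problem out of scope. The two-group comparison runs
Student's t on per-embryo mean nets and reports fold change
mean_b/mean_a, undefined (flagged) when mean_a ≤ 0.

## Synthetic data

The generator emulates the study design the analysis assumes: per
condition, 3 embryos × 5 sections at each of three axial levels;
per-section cell counts Poisson with mean 40; positions drawn from
per-population Gaussian mixtures in (dv, ml), truncated to [0, 1.05]²
by rejection sampling (cap 1,000 attempts per cell — wide covariances
near the boundary distort weights slightly, which is accepted and
bounded by the cap); geometries log-normal (H median 200, W median 100,
σ_log = 0.08, one arbitrary unit) to guarantee positivity; marker
co-labeling Bernoulli per marker (default 0.3); ISH images a constant
background (40 a.u.) plus Gaussian pixel noise with a rectangular
signal region (amplitude 60 a.u. × condition fold). Raw (D, α) are
emitted through the exact inverse transform D = √((dv·H)²+(ml·W)²),
α = atan2(dv·H, ml·W), so normalization recovers the sampled positions
to 1e-9 — this closes the loop that makes end-to-end recovery tests
meaningful.

The named cluster presets (dI2: dorso-medial stream + ventral cluster;
dI3: single intermediate cluster; dI5: medial major + lateral minor;
dI6: ventro-medial cluster) encode qualitative anatomy as stylized,
editable scenarios; they are not reconstructions of any measured
dataset. What passing tests show is therefore that the pipeline
recovers known truth under Gaussian-mixture structure with realistic
sample sizes — not that real somata are Gaussian-distributed, that
cells are independent within a section, or that digitization noise is
absent.

Randomness is a hierarchical stream (global seed → embryo → section),
so adding embryos or sections never perturbs earlier draws, and
identical (truth, seed) regenerate bit-identical tables.

## Numerical and design choices

- Permutation tie-break: permuted T² counts as ≥ observed at 1e-12
  slack, so exact ties favor the conservative side.
- Degenerate inputs error early and specifically: zero variance on a
  profiled axis, undersized samples, singular covariance, invalid truth
  parameters before any sampling.
- Significance is inclusive at the threshold (p ≤ 0.05 is significant).
- All stochastic operations take explicit seeds; pipeline reports embed
  config hash, input checksums and the seed, and reruns are
  byte-identical.
- File dialect: UTF-8 CSV with header, "." decimal, "NA" missing; TSV
  accepted on read by sniffing. Readers name the file, column and line
  of the first offending field.
- Calibration/recovery problem sizes (2,000 null replicates at
  n = 30/group; 1,000 for power; ~200 cells/group for shift recovery;
  3 embryos × 5 sections for intensity) were chosen to make Monte-Carlo
  error small relative to the checked tolerances.

## Limitations

- The pooled-cell T² inherits pseudoreplication from its design; a
  per-embryo alternative (test on embryo centroids) would be better
  powered against between-embryo variance but is not what pooled plots
  of this kind test, so it is exposed only as a disclosed caveat.
- No image segmentation or soma detection: coordinates and counts are
  inputs, digitized upstream.
- No 3D/rostro-caudal coordinate; axial level is a categorical stratum.
- No spatial point-process statistics (Ripley's K etc.) and no mixture
  inference on real data; mixtures exist only in the generator.
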