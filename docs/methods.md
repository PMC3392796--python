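# Methods

## The measurement model

Slide-based cytometry of a stained tissue section yields, after non-cell
"phantom" contouring, one event per grid tile with an integral fluorescence
and a MaxPixel value. `lscpanel` models this chain in two interchangeable
ways: a pixel-level path (`generate_scan` → `tile_phantoms` →
`mask_tissue`) and a direct event-table path (`generate_phantom_table`),
which produces the same tabular unit the rest of the pipeline consumes.

Phantoms are non-overlapping square tiles in row-major order, 0-based
indices, default edge 20 px; partial edge tiles are dropped rather than
padded so every phantom integrates the same area. Tissue gating keeps
phantoms whose scatter maximum exceeds a cutoff — a fixed value, or an Otsu
two-class split of the scatter-maximum histogram. The resolved cutoff is
stored on the output table and reused on re-application, making the gate
idempotent under the automatic rule too. Whether real instruments use
overlapping or circular contours varies; fixed grid tiles are an explicit
modelling choice, not a claim about any instrument.

## Section statistics

For each (patient, dye) pair a matched negative-control section calibrates:

- the **autofluorescence cutoff**: the smallest *observed* MaxPixel value
  leaving strictly fewer than `max_fpr` (default 0.05) of calibration
  events above it. Choosing an observed value with a strict comparison
  makes the "< 5 % positive events" contract hold deterministically on the
  calibration set; the achieved exceedance is recorded.
- the **MFI correction**: corrected MFI = median(integral) on the stained
  section minus the same median on the control. Negative values are
  reported as-is — clamping would hide control mismatch.

Affected area is 100 × the fraction of stained-section phantoms with
MaxPixel strictly above the cutoff, on a 0–100 scale. MFI is paired with
integral fluorescence and affected area with MaxPixel; both functions are
exposed separately for sensitivity analyses.

## Cohort statistics

Two-sided tests throughout. Mann-Whitney uses the exact permutation null
when the pooled sample has ≤ 12 observations and no ties (where exact and
asymptotic conventions visibly differ), otherwise the tie- and
continuity-corrected normal approximation. Kruskal-Wallis uses the
chi-square reference with k−1 df and tie correction; a fully tied sample
returns H = 0, p = 1. After a significant omnibus test, the three pairwise
post hocs run at the Bonferroni level 0.05/3 ≈ 0.017. Profile bands use the
control cohort's mean + 1 SD and + 2 SD per marker with the sample SD
(n−1), appropriate for small control groups; zero-variance markers are
flagged degenerate rather than silently banded. The test machinery is
scipy.stats; this module pins the conventions.

## Discrimination and panel search

The discriminant is Fisher's rule from class means and pooled within-class
covariance (divisor n−2), with ridge λI added before the solve. λ defaults
to 1e-6 × the mean covariance diagonal — enough to make a duplicated
feature harmless while moving well-conditioned solutions by less than the
estimation noise. Because λ is a scalar, extreme relative feature scalings
(factors ≳ 100) perturb the solution at the λ/variance level; panels of
like-scaled section statistics are far from that regime. Priors are equal
by default so sensitivity/specificity are not skewed by cohort prevalence
(14 vs 17, or 14 vs 5); priors are configurable.

Cross-validation is stratified k-fold (default k = 10) with 10 repetitions
reshuffled from one seed. Stratification matters at n(RA++) = 5: plain
folds could lack a class entirely; when the smaller class has fewer than k
members the fold count is reduced to that size with a warning. Confusion
counts are pooled over all folds and repetitions rather than averaged
per fold — per-fold rates are unstable with ~3 samples per fold. Each
sample's out-of-fold decision score (averaged over repetitions) feeds the
ROC, so AUC, sensitivity-at-specificity and the confusion counts describe
the same generalization surface; resubstitution scores never enter a
ranking. A test on null data demonstrates the residual selection-bias
offset of picking the best of many cross-validated panels.

ROC curves sweep every distinct score threshold (ties form diagonal
segments); AUC is the trapezoid area and equals the pairwise
P(case > control) + ½P(tie). The 95 % CI is DeLong's placement-variance
interval by default, with a class-stratified percentile bootstrap (2,000
resamples) as the alternative and as the automatic fallback when perfect
separation degenerates the DeLong variance. Sensitivity at 90 % specificity
is read off the curve's upper envelope by linear interpolation; the
conservative step-function value is reported alongside, since printed
values in the literature may follow either convention. AUC bands:
> 0.85 highly discriminative, < 0.55 nondiscriminative, the boundaries
themselves intermediate.

Panel search enumerates all marker subsets of sizes 1–3 (9 markers give
36 two-marker panels) in lexicographic order, scores
each with the same seed so fold assignments are comparable, and sorts by
AUC, sensitivity-at-90 %-specificity, or LR⁺ with ties broken by smaller
panel then lexicographically. MFI and affected area are evaluated as
separate tracks and never mixed in one feature matrix; combining them has
not been found to improve discrimination, and mixing would blur which
parameter carries the signal.

## The synthetic cohort generator

The generator reproduces the *statistical* structure the analysis assumes,
not histology. Defaults mirror the motivating study design: 14 controls,
12 RA(+), 5 RA(++); nine markers; 5,000 phantoms per section (large enough
for stable 95th-percentile cutoffs, small enough for desk-scale runs); one
stained plus one negative-control section per patient and marker.

Per event, MaxPixel is log-normal — strictly positive and right-skewed like
fluorescence intensities: background ~ exp(N(μ_p, 0.4)) with a per-patient
level μ_p = 5.0 + N(0, 0.1); positive events (probability = the cohort ×
marker positive fraction) are shifted by +1.2 in log space with a 1.5×
wider log-SD (heavier-tailed signal). Integral = MaxPixel × (1 + log-normal
area factor), so integral ≥ MaxPixel always. Negative controls share the
patient's background parameters exactly (idealized isotype control); a
jitter option models control mismatch. Each patient's effective positive
fraction is multiplied by a log-normal jitter (log-SD 0.8) — without
between-patient spread, 5,000-event sections estimate the fraction so
precisely that any effect separates cohorts perfectly, which real patient
cohorts do not. Under these defaults responsive single markers score AUC
≈ 0.8–0.95 against controls and null markers sit near chance, the regime
the method is meant to operate in. The default effect pattern: CD4 and
CD271 null; CD29/CD90/HLA-DR respond preferentially in RA(+);
CD11b/CD38/CD304 in RA(++); CD64 and HLA-DR in both.

Cohort labels are metadata supplied to the generator, never inferred —
histopathologic grading of activity is an input to this analysis, not part
of it.

What passing tests on synthetic data do **not** show: robustness to
staining chemistry, spectral bleed-through, spatial autocorrelation of
signal within tissue (events here are exchangeable), section-to-section
registration error, or non-log-normal autofluorescence. Conclusions about
real tissue require real scans through the same file formats.

## Numerical and design choices

- Determinism: every stochastic component is driven by explicit integer
  seeds through `numpy.random.SeedSequence`; per-section streams are keyed
  by (seed, patient, marker, control flag) so sections are independent yet
  reproducible individually and in bulk.
- Tabular floats are written with round-trip repr and read with
  `float_precision="round_trip"`, so the file path and the in-memory path
  give bit-identical downstream results (checked by manifest checksums).
- Ties: midranks everywhere (tests, Spearman, ROC placements); ROC ties
  get the ½ convention.
- Degenerate inputs are flagged, not silenced: empty tissue gates warn,
  zero-variance profile bands warn, perfect specificity reports LR⁺ = ∞
  with a warning, degenerate DeLong variance falls back to bootstrap with a
  warning.
- Problem sizes in the test suite (phantoms per section, seed-grid widths,
  permutation and simulation counts) are desk-scale choices that keep the
  full suite in well under a minute while leaving Monte-Carlo tolerances
  honest; the acceptance script uses 10,000 calibration events and the
  14 + 5 patient geometry of the smallest cohort contrast.

## Known limitations

- The scan simulator's tissue blob is a disk with i.i.d. pixel noise and
  isolated bright foci; it exercises the tiling/gating geometry, not
  morphology.
- The discriminant is strictly linear with a scalar ridge; no quadratic
  boundaries, no logistic alternative.
- Bonferroni is the only multiplicity correction offered, matching the
  three-post-hoc screening design; it is conservative for larger marker
  sets.
- DeLong CIs are asymptotic; at 5 cases per class the bootstrap option is
  the more defensible interval.
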