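# Methods

This note documents the models and procedures implemented in `phhkit`, the
assumptions behind them, the parameters that matter, and what the synthetic
benchmarks do and do not demonstrate.

## Stain quantification (`phhkit.stain`)

**Model.** A Perls Prussian-blue / eosin section is treated as a mixture of
three color populations.  Pixel classification uses one axis-aligned box per
stain class in RGB space: an inclusive `(low, high)` interval per channel,
eight-bit units.  A pixel inside the blue box is BLUE; otherwise inside the
pink box, PINK; otherwise OTHER.  Where the boxes overlap, BLUE wins — the
assay's analyte is ferric iron, so ambiguous pixels are credited to the iron
class rather than the counterstain.  Iron deposition is summarized per image
as `blue / (blue + pink)`; OTHER pixels never enter numerator or
denominator, so slide background and mounting artifacts cannot dilute the
ratio.  (The denominator is sometimes described loosely as "whole tissue
area"; the implemented quantity is exactly the blue+pink pixel total, which
equals tissue area only insofar as eosin stains all non-iron tissue.)  An
image in which no pixel lands in either box raises an error instead of
returning 0 — a silent zero is indistinguishable from a genuinely
iron-negative section.

**Thresholds.** Real-batch thresholds are an empirical choice and are not
published; `DEFAULT_THRESHOLDS` (blue: R 0–140, G 0–160, B 110–255; pink:
R 170–255, G 90–200, B 120–220) is a documented stand-in constructed around
the synthetic color model, not fitted to any real staining batch.  Every
`StainRatioResult` records the threshold set used, and one set is intended
to be applied to an entire batch so between-group comparisons are made under
identical classification rules.  `calibrate_thresholds` fits boxes to
annotated pure-class patches by exhaustive search over per-channel candidate
intervals, maximizing balanced per-class accuracy (mean of sensitivity and
specificity); ties break toward the earliest grid point, so calibration is
deterministic for a fixed grid.  Each class box is searched independently;
the BLUE-precedence rule resolves any residual overlap.

**Scope.** The input is one captured whole-brain view per sample, optionally
restricted by a binary tissue mask.  No stain deconvolution, tiling or
cross-section registration is attempted.

## Volumetry (`phhkit.volumetry`)

**Model.** Ventricular CSF volume is the Cavalieri estimator
`V = Σ_k A_k · t` over serial MR slices (areas in mm², thickness `t` in mm,
output in mL with 1 mL = 1000 mm³).  For a single slice this reduces to
area × thickness.  Slice thickness is scanner-specific and therefore a
required input with no default.  Mixed thickness within one scan is rejected
unless explicitly overridden, in which case each record's own thickness is
used.

**Compartments.** Left and right lateral ventricles are carried as separate
labels (laterality is worth preserving under bilateral injections) and the
default inclusion set is {LATERAL_L, LATERAL_R, THIRD}.  Aqueduct, fourth
ventricle and extra-axial subarachnoid spaces are tracked but excluded by
default — they are hard to delineate reproducibly, and the exclusion is
validated by an invariance test (adding excluded-compartment records never
changes the returned volume).

**Missingness.** Longitudinal tables preserve absent visits as absent rows;
animals that die of severe hydrocephalus before the final scan simply stop
contributing.  No imputation of any kind.

## Statistics (`phhkit.stats`)

**Trend.** `VolumeTrend` fits ordinary least squares to a group's
*mean* trajectory — the per-day group means, typically four points — and
reports the slope (mL/day), intercept and Pearson *r*.  Fitting the means
rather than the pooled per-animal scatter makes the slope a property of the
group trajectory and reproduces the study's printed slopes exactly from the
printed means; a pooled fit is available through
`VolumeTrend.from_dataframe(..., aggregate=False)`.  A constant response
yields slope 0 with *r* flagged undefined (NaN, `r_defined=False`), never a
silent 0; identical days raise an error.

**Gated comparison.** `GroupComparison.fit()` applies the decision tree:

1. Shapiro–Wilk per group at level alpha (default 0.05, configurable).
   Parametric iff every group passes.  Groups with n < 3 (below the
   Shapiro–Wilk minimum) force the nonparametric route with a logged
   warning — conservative and reproducible.  A constant sample is assigned
   Shapiro p = 0 (certainly non-Gaussian).
2. Parametric, 2 groups: unpaired two-tailed Student's t.  The SD gate is
   not applied here — it belongs to the multi-group ANOVA branch.
3. Parametric, >2 groups: Brown-Forsythe test of equal spread (Levene with
   median centering, the k-group generalization of the two-group F-test) at
   the same alpha.  Equal spread: one-way ANOVA with Tukey HSD over all
   pairs.  Unequal: Welch ANOVA (omnibus p reported) together with the
   Brown-Forsythe robust ANOVA F\* (closed form
   `F* = Σ n_i (m_i − m)² / Σ (1 − n_i/N) s_i²`, Satterthwaite denominator
   df; recorded in `extras`), and Dunnett's post hoc against the first group
   in input order as control.  Which exact Dunnett variant the original
   analysis software uses under unequal SDs is not documented; the standard
   multivariate-t Dunnett is used here.
4. Nonparametric, 2 groups: two-sided Mann–Whitney U.  >2 groups:
   Kruskal–Wallis, with Dunn's all-pairs post hoc: pooled-rank z statistics
   with tie correction, two-sided normal p, Bonferroni adjustment over all
   k(k−1)/2 pairs (the adjustment family is a design choice; Bonferroni is
   the common default and is never anti-conservative).

Every decision is captured in a `GateTrace` (per-group Shapiro p, SD-gate p
where applicable, alpha, route) sufficient to replay the selection.  Test
statistics themselves come from scipy; the gating, orchestration, the
Brown-Forsythe omnibus and Dunn's test are implemented in this package.

When several scan days are analyzed, the intended usage is one four-group
omnibus per day followed by the post-hoc pairs, each day treated as an
independent cross-section.

## Synthetic data (`phhkit.synthetic`)

**Stained sections.** `make_stain_image` allocates exact per-class pixel
counts by largest-remainder rounding of the requested fractions (ties break
blue → pink → background), assigns classes to pixel positions (uniformly at
random, or in blob-like clusters that preserve the exact counts), and
samples colors around per-class centers with Gaussian per-channel jitter,
rounded and clipped to [0, 255].  The default centers — blue (60, 80, 190),
pink (230, 150, 170), background (245, 245, 245) — sit inside the default
threshold boxes with margin, so at zero jitter classification recovers the
generated counts exactly, and at the default jitter SD of 6 the populations
stay inside their boxes out to ±4 SD.  What this shows: the classifier and
ratio arithmetic are correct on images that obey the three-population color
model.  What it does not show: robustness to stain variation, illumination
gradients, chromatic mixtures at stain boundaries, or compression artifacts
of real slides — for those, per-batch calibration is the answer.

**Ventricle phantom.** `make_ventricle_stack` rasterizes an axis-aligned
ellipsoid (semi-axes a, b, c in mm) into per-slice label masks: slices at the
centers of consecutive thickness-t slabs covering [−c, c], in-plane pixel
spacing 0.02 mm by default, pixel counted if its center lies inside the
slice's ellipse.  The analytic volume 4/3·π·abc is returned alongside.  With
the default (2, 1.5, 1) mm phantom the Cavalieri estimate lands within 0.1%
of the closed form at 0.1 mm slices and the error shrinks monotonically
under slice refinement (0.5 → 0.25 → 0.1 mm: ≈3.1% → 0.78% → 0.07%); the
dominant error term is the midpoint-rule O(t²) area-integration error, not
rasterization.

**Cohorts.** `make_cohort` draws each subject's volume per day from a
lognormal with the group-day mean as its expectation — positivity is
guaranteed, matching a volume measurement — with a single coefficient of
variation for all group-days.  The generating means default to the study's
printed four-group trajectories (saline control, Hb, iron, L-RBC at days
5/12/19/26) and the default CV of 1.0 is scaled from the one printed
standard error (iron, day 26: 0.9695 ± 0.1386 SEM at n = 49 implies
SD ≈ mean); per-day spreads beyond that single point are unknown and this
constant-CV choice is an assumption.  Default group sizes are the study's
(20/25/49/41).  Optional dropout emulates death from severe hydrocephalus:
after any scan whose volume exceeds a threshold the subject dies with
probability `dropout_prob` (default 0.5) and contributes no later rows.
All generators are pure functions of spec + seed (bit-reproducible).

## Numerical and interface choices

- Interval bounds inclusive at both ends (common 8-bit threshold
  semantics); class maps use 0 = other, 1 = pink, 2 = blue, 255 = masked.
- Units fixed at mm², mm, mL; CSV headers carry them (`area_mm2`,
  `thickness_mm`, `volume_mL`).
- CSVs are comma-separated UTF-8 with required headers and `.` decimals;
  threshold sets and reports are JSON; images PNG/TIFF, 8-bit RGB.
- CLI exit codes: 0 success, 2 schema/configuration error, 3 computation
  error; every command writes a reproducibility manifest.
- Benchmark problem sizes (chosen to keep the full suite in the minutes
  range while leaving the statistical checks well-powered): 50 synthetic
  sections of 120×120 px for ratio recovery; the (2, 1.5, 1) mm phantom at
  0.02 mm pixels; 2000 replicates for the null-calibration estimate
  (binomial SE ≈ 0.005 at a true rate of 0.05); 60–100 seeds for the
  day-26 power readout at n = 10 per group.

## Known limitations

- RGB boxes cannot separate classes whose populations overlap in RGB; no
  optical-density unmixing is provided.
- The volumetry path starts from segmented areas; segmentation itself (and
  DICOM handling) is out of scope.
- The gated procedure inherits the well-known caveats of pre-testing for
  normality; it is implemented because it is the procedure under study, not
  as a recommendation.  Its composite type-I error is verified empirically
  (≈0.045 at nominal 0.05) rather than derived.
- Real-data effect sizes (stain ratios and volumes of actual animals)
  cannot be reproduced from synthetic data; the cohort benchmarks check the
  qualitative group pattern and the machinery, not the biology.
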