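# Methods

This package reconstructs a complete fibroblast-bioenergetics analysis —
from raw plate-assay signals to per-line feature profiles, group-level
nonparametric statistics, and SVM-based patient stratification — together
with a synthetic-cohort generator calibrated so that every stage can be
exercised and validated without access to patient material.

## The measurement model

The unit of analysis is a primary skin fibroblast line carrying a
diagnostic label (control, sporadic ALS, primary lateral sclerosis, or a
C9orf72 repeat expansion) and clinical covariates. Three plate-assay
families produce the raw data:

* **Extracellular flux (mito stress test).** Oxygen consumption rate
  (OCR) and extracellular acidification rate (ECAR) are recorded per well
  over four injection phases: baseline → oligomycin (ATP-synthase
  inhibitor) → FCCP (uncoupler) → antimycin A + rotenone (respiratory
  chain block). Twelve wells per line, several measurement cycles per
  phase.
* **TMRM / MitoTracker Green fluorescence.** TMRM accumulation reports
  mitochondrial membrane potential; MTG reports mitochondrial content.
  Eight wells per dye per condition; FCCP-treated wells give the fully
  depolarized background.
* **ATP luminescence.** Luciferase luminescence at baseline, after
  2-deoxyglucose (glycolysis block), and after oligomycin (oxidative ATP
  block); triplicates per condition, converted to ATP amounts through a
  standard curve.

### Feature extraction

Processing follows the standard conventions for these assays, composed in
`features.py`:

1. **Cycle averaging.** Multiple cycles within a phase are averaged per
   well before any replicate comparison, giving one rate per well per
   phase (the analysis operates on per-phase rates).
2. **Replicate QC.** Within each (line, phase, signal family), replicates
   farther than two *sample* standard deviations from the replicate mean
   are discarded. The rule is single-pass: mean and SD are computed once,
   then the mask is applied — no iteration. A useful consequence of the
   identity Σ(x−x̄)² = (n−1)s² is that at most ⌊(n−1)/4⌋ replicates can
   ever be discarded, so the mask is never empty and ATP triplicates are
   never reduced. At least two surviving wells per phase are required,
   else the line is flagged and skipped for that assay.
3. **Non-mitochondrial correction.** The line's own mean AA+Rot OCR is
   subtracted from all of that line's OCR phases (per-line, not
   plate-wide, consistent with per-line normalization elsewhere). ECAR is
   never corrected; ECAR at the AA+Rot phase is taken as-is, since CO₂
   contributes negligibly to acidification at OCR/ECAR ratios well below
   4 (cohort average ≈ 1.5).
4. **Metrics.** With corrected phase rates and protein mass p:
   `ocr_base = baseline/p`; `ocr_oligo_sens = (baseline − oligomycin)/p`
   (the non-mito floor cancels in the difference, so corrected and raw
   rates give identical results); `ocr_max = FCCP/p`;
   `ocr_spare = ocr_max − ocr_base`; `ecar_base`, `ecar_aarot`
   analogously without correction; `ocr_ecar_ratio = ocr_base/ecar_base`.
5. **Fluorescence.** Per dye, (mean untreated − mean FCCP background)/p,
   each side QC'd first. A negative difference can only arise from noise
   and is clamped to zero; clamps are counted in the QC report because a
   high count signals miscalibrated noise.
6. **ATP.** Luminescence → ATP amount by piecewise-linear interpolation
   on the standard curve (end segments extrapolate); per-condition means
   are protein-normalized. Deltas are baseline − treated, so an ATP
   *rise* after oligomycin yields a negative `atp_oligo_delta` — the
   convention under which the control-group mean of that feature is
   negative.
7. **Protein.** Recorded per line (per-well values are averaged per assay
   family); all features are per mg total protein.

The 12 features, in canonical column order: tmrm, mtg, ecar_base,
ecar_aarot, ocr_base, ocr_oligo_sens, ocr_spare, ocr_max, ocr_ecar_ratio,
atp_base, atp_2dg_delta, atp_oligo_delta.

## The synthetic cohort

`synthesize.py` generates a cohort of 91 control, 171 sALS, 34 PLS and 13
C9orf72 lines (309 total) whose *feature-level* distributions match the
observed cohort summaries baked into `default_config()`: per-group
mean/SD for every feature, and the seven canonical Spearman rank
correlations per group (entries reported as not significant are targeted
at 0).

**Copula construction.** Ten features are sampled through a Gaussian
copula: latent standard normals with correlation `2·sin(π·ρ_s/6)` for a
target Spearman ρ_s, pushed through marginal inverse CDFs. Marginals are
lognormal — these assay readouts are strictly positive and right-skewed,
and none pass a normality test — except the oligomycin ATP delta, which
straddles zero and is normal. Rank correlations survive the monotone
marginal maps, so the Spearman structure is imposed exactly.

**Derived features.** Spare respiratory capacity and the OCR/ECAR ratio
are deterministic functions of other features and are recomputed after
sampling so the profile identities hold exactly. Their distributions are
then emergent, with two calibrations:

* The spare *mean* is automatic (the configured group means satisfy
  mean(max) − mean(base) = mean(spare) exactly). The spare *SD* is hit by
  solving the exact lognormal covariance identity
  cov(X,Y) = m_x·m_y·(e^{σ_x σ_y r} − 1) for the latent baseline~maximal
  OCR correlation — a pair unconstrained by the correlation targets.
* Rank targets that involve the ratio are expressed through the ratio's
  latent representation (σ_b·Z_base − σ_e·Z_ecar)/σ_r and solved for a
  free direct correlation. For the PLS ratio~ATP-baseline target both
  parent correlations are already pinned; the implied value (−0.510)
  agrees with the target (−0.508) without adjustment — an internal
  consistency of the calibration data.
* The ratio's own mean/SD cannot be matched simultaneously, because its
  parents' correlation is itself a target; its emergent moments are close
  (control ≈ 1.58 vs 1.5) and are reported, not asserted.

**Completion of unspecified correlations.** Pairs with no target are
filled by the maximum-determinant completion — each free entry set so its
partial correlation given all other variables vanishes — computed by
coordinate ascent on log det with a homotopy start. Unlike a plain zero
fill (which is indefinite here, and whose nearest-PSD repair would drag
the *targeted* entries off by far more than the Monte-Carlo tolerance),
the max-det completion preserves every specified entry exactly and is
positive definite by construction for the chordal target pattern. A
final PSD projection remains as a safety net; its repair magnitude is
logged and is ~1e-16 for all four default groups.

**Plate rendering.** `render_plate_data` inverts the extraction pipeline:
flux wells carry phase-level true OCR plus a non-mitochondrial floor
(default 15% of true baseline — any positive value cancels in background
subtraction); fluorescence background wells carry an FCCP-background
component (default 20% of signal); ATP wells invert the linear standard
curve (intercept 5000, slope 100 per unit — the intercept keeps
luminescence positive even for the rare sampled line whose post-2DG ATP
content goes negative under the configured marginals). Technical noise is
a mean-one multiplicative lognormal per replicate (default CV 8%, typical
of plate assays), with outliers as additional multiplicative shocks
(default rate 1%, scale 3). Per-line protein is lognormal (mean 0.1 mg,
CV 15%). With noise switched off, the pipeline recovers the ground-truth
profile to float precision — the package's core oracle, asserted at
1e-9 relative tolerance.

**What the generator does not emulate:** plate/batch effects, positional
(edge) effects, instrument drift, day-to-day passage variation, and any
real clinical structure — clinical covariates are uniform draws over the
observed ranges, present only to exercise the median-split machinery.
Passing tests therefore validate the *pipeline arithmetic and the
statistical machinery*, not robustness to real-world plate artifacts.

## Statistical battery

All features fail the D'Agostino–Pearson omnibus normality test on
cohort-scale data (the scan requires n ≥ 20, the statistic's validity
floor), so the battery is nonparametric throughout, two-sided, α = 0.05:

* **Kruskal–Wallis** omnibus across the four groups (tie-corrected),
  followed by **Dunn's test** on mean ranks with tie-corrected variance;
  post hoc p-values are reported only under a significant omnibus. No
  correction is applied across the post hoc family by default (a
  Bonferroni flag exists). Dunn's statistic is implemented directly (no
  installed package provides it) and is verified against a hand-computed
  rank oracle.
* **Effect sizes** as percent-of-reference, mean(a)/mean(b)×100, with a
  bootstrap percentile 95% CI (default 10,000 resamples, seeded). Groups
  are resampled independently — they are independent patient samples; a
  paired mode (shared resample indices) exists for paired designs, where
  the CI of a constant elementwise ratio correctly collapses to a point.
* **Spearman correlations** (average ranks for ties) with
  Benjamini–Hochberg FDR at 0.05 over the *joint* family of all tested
  pair × group hypotheses — the conservative reading; a per-group family
  is available.
* **Median splits**: lines are split at the feature median (ties, and
  for odd n the median line, go to the lower half), and the clinical
  variable is compared across halves by two-sided Mann–Whitney U with a
  percent-difference effect.

## Classification harness

Two tasks: control vs. disease (all three disease groups pooled; disease
positive) and sALS vs. PLS (C9orf72 excluded; sALS positive).

* **Grid.** 4 kernels × 7 penalties (C = 10⁻²…10⁴, log-spaced) × 8 gamma
  values (10⁻⁴…30, log-spaced) × 5 class-weight settings (none, balanced,
  and positive-class weights 2/5/10) = 1120 parameter sets, enumerated
  kernel-major. The axis values are the package's choice; the cardinality
  is the constraint they satisfy.
* **Selection.** Stratified 10-fold cross-validation, folds fixed by seed
  and shared across all grid points; plain validation accuracy (balanced
  accuracy behind a flag); ties break by enumeration order. Features are
  z-scored with training-fold statistics only — the raw feature scales
  span four orders of magnitude, which distance-based kernels cannot
  tolerate. The selection is single-level; its optimistic bias is a known
  property, noted and not corrected.
* **Numerical guard.** SVC fits carry an iteration cap (5·10³) so that
  pathological large-C grid points cannot stall the search; a truncated
  fit simply scores what it earned. The linear kernel ignores gamma, so
  the solver result is shared across that axis (the grid still enumerates
  all 1120 points).
* **Evaluation.** The selected model is refit per fold; ROC curves come
  from the continuous decision score; the mean ROC is the vertical
  (pointwise) average on a fixed 101-point FPR grid, with vertical
  segments collapsed to their top TPR so a perfect fold averages to AUC
  exactly 1; AUC by trapezoid on the mean curve. The confusion panel
  (sensitivity, specificity, PPV, NPV, FPR, FNR, FDR) uses confusion
  counts pooled across validation folds (fold-averaged metrics behind a
  flag); 95% CIs are across-fold normal approximations, truncated to
  [0, 100]. Folds whose validation set lacks a class are excluded from
  the affected CI with a warning.

## Problem sizes and tolerances

* Inverse-pipeline identity: asserted at 1e-9 relative error (measured
  ~1e-15).
* Marginal/correlation recovery: n = 5000 lines per group; means within
  2%, SDs within 5%, Spearman within ±0.05. Where a stated percentage
  falls below the Monte-Carlo noise floor at n = 5000 (the near-zero-mean
  oligomycin ATP delta; the heaviest-tailed SDs), the test guards with
  3.5 standard errors instead — a familywise false-alarm rate of ~2%
  over the ~80 simultaneous checks for a correctly calibrated sampler.
* Battery oracles: BH against the literal step-up definition on an
  exhaustive grid of p-vectors up to length 6; Kruskal–Wallis/Dunn
  against hand-computed ranks on a nine-value instance; omnibus type-I
  error ≤ 7.5% at nominal 5% over 1000 seeded null simulations.
* Classifier limits: ≥ 98% mean CV accuracy and ≥ 0.99 mean AUC on
  10-σ-separated Gaussian clouds (n = 100 + 100); label-permuted data
  within 5 points of the majority rate (n = 200, 60/40) even after
  selecting the best of 1120 grid points.
* Task ordering: on five full default cohorts (seeds 1–5, rendered
  plates, full grid) the mean sALS-vs-PLS AUC exceeds the mean
  control-vs-disease AUC. This is asserted as an ordering only — the
  absolute AUCs depend on the real cohort and are not reproducible from
  summary statistics.

## Known limitations

* The generator matches marginals and pairwise rank correlations; higher
  -order dependence, batch structure, and real clinical-bioenergetic
  coupling are absent. Median-split results on synthetic data are
  therefore null by construction.
* The OCR/ECAR ratio's marginal is emergent (see above); analyses that
  depend on its exact SD should treat the synthetic cohort qualitatively.
* Cross-validated accuracies/AUCs on synthetic cohorts track the
  configured effect sizes, not any particular published operating point;
  only orderings and qualitative patterns transfer.
* The median-split tie rule (ties to the lower half) makes the two
  halves unequal in the presence of heavy ties; this matches the stated
  convention rather than attempting an optimal balanced split.
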