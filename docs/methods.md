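# Methods

## The model

Each surgical record carries 14 ordinal difficulty indicators of an impacted
mandibular third molar (coded 0-based in the fixed level order of the packaged
schema) and an operative duration in seconds. Three layers sit on top of the
records:

**Response.** Operative time is z-scored per surgeon with the population SD,
computed once over the surgeon's full record history. This removes each surgeon's
personal speed baseline so that Lasso coefficients describe how *case features*
move a surgeon away from their own average, not how fast the surgeon is. Class
labels, in contrast, use raw seconds (class 1 < 600 s, class 2 600–1200 s
inclusive of both endpoints, class 3 > 1200 s): difficulty is a property of the
case in absolute time.

**Lasso paths and preference sequences.** For a record subset, predictors are the
ordinal codes standardized to mean 0 / population SD 1 over that subset (constant
columns are pinned to coefficient zero), and the path solves

    (1/2n)·||y − β₀ − Xβ||² + λ·||β||₁

on a geometric grid of 200 penalties from λ_max = max_j |⟨x_j, y⟩|/n (where every
coefficient is zero by the Karush–Kuhn–Tucker conditions) down to 10⁻⁴·λ_max. The
*preference sequence* is the order in which coefficients first exceed 10⁻⁸ in
magnitude as λ decreases; grid-point ties break by larger magnitude at the tied
point, then schema order. Features that never activate are omitted rather than
appended — appending them in a fixed order would manufacture artificial agreement
between surgeons. Coefficients at the truncation penalty λ₀ = 0.01 are linearly
interpolated in log λ, and the retention rule keeps indicators with |β(λ₀)| ≥
τ = 0.05. Re-activations (a coefficient leaving and re-entering the active set)
are ignored for the sequence; a per-feature activation count is exposed as a
diagnostic only.

**Decoupling and per-group experts.** Surgeon similarity is the unit-cost
Levenshtein distance over sequences whose tokens are indicator identities (not
characters of their names). Agglomerative clustering with average linkage — robust
for short integer-valued distances; complete and single linkage are available —
is cut at k = 2; exact merge ties go to the pair of clusters with the lowest
id-ordered member indices, which makes the tree deterministic and order-invariant
up to relabeling. One classifier per cluster is then grid-searched with seeded
stratified 5-fold CV maximizing the macro one-vs-rest ROC AUC (SVM:
C ∈ {0.1, 1, 10, 100, 1000} × γ ∈ {scale, 10⁻³, 10⁻², 10⁻¹, 1}; random forest:
100/300 trees × depth {∞, 5, 10}; XGBoost: depth {3, 6} × learning rate
{0.1, 0.3} at 200 rounds). When a class is rarer than the fold count, the fold
count shrinks to the rarest class size (≥ 2); a singleton class falls back to
unstratified folds. SVM candidates are ranked on decision-value AUC — the margin
ranking is invariant to probability-calibration noise and much cheaper — and only
the winner is refit with pairwise-coupling probability calibration, which is the
score contract at prediction time. Test records are routed to their surgeon's
cluster; records from unseen surgeons go to the nearest cluster centroid in
globally standardized feature space (a flag switches to per-sample centroid
routing for all records).

**Evaluation.** Accuracy, per-class one-vs-rest sensitivity/specificity/F1 from
the 3×3 confusion matrix, and macro AUC as the unweighted mean of the three
one-vs-rest trapezoidal ROC areas. A class absent from the truth is excluded from
the macro averages with a warning. Group operative-time differences use the
pooled-variance (Student) two-sample t-test on raw seconds. The comparison
baseline partitioner is a full-covariance Gaussian mixture over per-surgeon
summary vectors: mean standardized indicator codes concatenated with the mean and
SD of the surgeon's *globally* standardized durations (per-surgeon z-scores would
be identically (0, 1) and carry no information, so the global z-score is used for
these two summary statistics).

## The synthetic clinic

The generator emulates the structure the method assumes, at the scale of a
single-department resident cohort:

* **Cohort.** Nine surgeons with tenures {10, 10, 10, 6, 6, 1, 4, 5, 1} months and
  log-duration baselines equal to the log of the published per-surgeon mean
  operative times (759–1585 s). Surgeons 1, 2, 3, 4, 7 form the experienced group;
  5, 6, 8, 9 the novice group. Monthly caseloads give short-tenure surgeons a full
  month's workload (≈ 47 extractions — the published cohort total split evenly
  across nine residents) and the ten-month surgeons 14 cases/month, so the late
  months only they populate still contain 3 × 14 = 42 records, enough headroom for
  a 14-predictor fit. The default cohort is 703 records.
* **Indicators.** Levels drawn independently per indicator from the baseline
  proportions shipped with the schema (renormalized within indicator). Correlated
  draws are out of scope; a copula hook would slot into `generate_dataset` but is
  deliberately not implemented.
* **Durations.** log d = b_s + Σ_j β_j(m)·z_j + ε with z_j the ordinal code
  standardized under the configured marginals, ε ~ N(0, noise_sd²), and for
  novices β_j(m) = β_j·decay^(m−1) on all indicators outside the experienced core
  (core effects constant). The log scale reflects that operative times are
  positive and right-skewed with dispersion growing with the mean.
* **Effects.** The experienced support is the published four-factor core
  {Resistance, Angle, Opening, Gender}; magnitudes (0.20, 0.30, 0.09, −0.14
  respectively, log-units per indicator SD) are gapped so the group's activation
  order is identifiable at cohort scale and give a per-surgeon coefficient of
  variation near the published ≈ 0.4. Novices have full support: the dominant
  effects sit on Depth (0.45), the IAN relationship (0.33) and Root number (0.24)
  — the factors the learning-curve narrative identifies as early-career drivers —
  tapering to 0.04 on the least involved indicators, with the shared core factors
  present but small (|β| ≤ 0.08). decay = 0.92 per month halves novice-specific
  effects by about month 9, matching the "proficient after ~8 months" picture;
  noise_sd defaults to 0.02.

Chosen once by a power analysis of the retention rule and the sequence pipeline at
cohort scale, then frozen: τ = 0.05 is an absolute threshold on the normalized
response scale, and both the per-month sample sizes (≥ 42) and the residual level
had to keep null coefficients clearly below it while the planted activation
orders stay stable.

**What the generator does not emulate.** Real operative times have larger
unexplained dispersion (the published per-surgeon SDs are ≈ 40% of the means;
here most dispersion is carried by the planted effects, and novice dispersion
exceeds experienced dispersion by design). Indicator correlations, case-mix drift
over a residency, and recording error are absent. Passing tests on this generator
therefore demonstrate that the pipeline recovers the structure it assumes when
that structure is present and identifiable — not that real clinics satisfy those
assumptions.

## Numerical choices and degenerate inputs

* Solver: scikit-learn's coordinate-descent `lasso_path` at tolerance 10⁻¹²,
  which keeps grid coefficients within ~10⁻⁹ of an independent coordinate-descent
  oracle (the test-suite carries that oracle and checks 100 random instances).
* λ₀ interpolation is linear in log λ; λ₀ above λ_max is a zero vector
  (mathematically exact), λ₀ below the grid is an error.
* A response orthogonal to every predictor (e.g. identically zero) yields an
  all-zero path on a nominal grid and an empty sequence.
* Imputation: within-surgeon mean of ordinal codes, rounded half-up, with an
  optional global-mean fallback for a surgeon who never observed an indicator.
* Per-surgeon splits take round(0.2·n) test records (min 1, max n−1), allocated
  across classes by largest remainder when stratifying.
* Zero-variance surgeons (constant durations) are an error for normalization;
  months with fewer than two records are reported as empty learning-curve entries
  rather than errors.

## Known limitations

* The z-scored raw duration is a convex function of log-duration, so with large
  log-scale effects the linear Lasso sees curvature that can leak ~0.05-level
  spurious coefficients into skewed indicator columns at monthly sample sizes.
  This is a property of the published protocol (raw-time z-scores over a
  multiplicative process), visible here because the generator makes the truth
  known.
* Mouth opening illustrates a structural limit of month-level retention: with
  98.8% of cases at "Normal", a 40-record month has a limited-opening case less
  than half the time, and a constant column is necessarily pinned to coefficient
  zero. Group-level fits (hundreds of records) retain Opening reliably;
  month-level retained sets usually show only the three well-populated core
  factors. No sample size consistent with a single-department cohort fixes this.
* Sequences at cohort scale are stable only in their leading tokens; the tail
  order of weakly involved indicators is sampling noise. The Levenshtein
  decoupling works off the stable prefixes, which is why planted recovery needs
  groups that differ in their leading factors.
* k = 2 is fixed by design (experienced vs novice); the partitioners expose k but
  no selection rule for it.
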