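# Methods

## The estimation problem

An EHR diagnosis code is a cheap classifier of true case status; chart
review is the expensive gold standard. Reviewing a simple random sample of
children is hopeless when code prevalence is a few percent — almost no
coded children would enter the sample — so the design stratifies phase-two
(chart review) sampling on the phase-one classifier itself: a fixed number
of records per condition × period × stratum (Dx / No-Dx) cell. That makes
PPV and NPV directly estimable within strata, but sensitivity and
specificity must be reweighted back to the population.

## Weights and estimators

With stratum population sizes `N_ij` (condition i, stratum j), per-stratum
sampled counts `n_ij`, and `N_i = Σ_j N_ij`, each sampled record carries

    W_ij = N_ij / (n_ij · N_i)

so that `Σ_j n_ij · W_ij = 1` within a condition (an exact algebraic
identity, property-tested), and the sum of Dx-sampled weights equals the
population code prevalence `N_i,dx / N_i` exactly. The classical
verification-sampling estimators follow: TP and FP are tallied among
Dx-sampled records against the gold standard, FN and TN among No-Dx
records, and

    sens = TP·W_dx / (TP·W_dx + FN·W_nodx),
    spec = TN·W_nodx / (TN·W_nodx + FP·W_dx),

while PPV = TP/(TP+FP) and NPV = TN/(TN+FN) are weight-free because the
weight is constant within a stratum. F is the harmonic mean of sensitivity
and PPV; Youden J = sens + spec − 1. The published form of the weight
denominator hard-codes the per-stratum sample size 120; we implement the
general `n_ij` so that replacement records and non-default designs stay
correctly weighted. Results are reported as percents rounded half-up to
one decimal; metrics with an empty weighted denominator propagate as NaN,
never as 0 or 100.

A deliberately discriminating regression: with identical confusion cells
(TP=119, FP=1, TN=120, FN=0), specificity rounds to 100.0 under one
condition's weight ratio and 99.9 under another's — only correct weight
arithmetic reproduces both.

## Confidence intervals

The CI construction behind validation tables of this kind is rarely
stated, and no standard closed form reproduces intervals such as
"87.7 (63.4–100)" exactly; we therefore treat point estimates as the
reproducible surface and provide two documented interval methods:

* **stratified percentile bootstrap** (default, seeded): records are
  resampled with replacement within each stratum — equivalently the
  confirmed counts are redrawn from binomials at the observed rates — the
  weighted metric is recomputed per replicate (default 1000), and
  percentile bounds are clamped to [0, 100]. Degenerate cells (zero
  observed errors) yield an interval touching the boundary, e.g.
  (100, 100).
* **logit-normal**: delta-method normal interval on the logit scale,
  back-transformed. For within-stratum proportions k/n the logit variance
  is 1/k + 1/(n−k); for the weighted sensitivity/specificity the two
  binomial "success" counts enter the odds and the variance is the sum of
  the two log-count variances. Defined for the four proportion metrics
  only; degenerate points return a zero-width boundary interval.

Bootstrap intervals are exactly reproducible for a fixed seed; because the
resampled counts are small integers, nearby seeds can legitimately produce
identical percentile bounds.

## Interrater reliability

Cohen's κ = (p_o − p_e)/(1 − p_e) from the 2×2 table of the two
abstractors' yes/no readings; pairs involving blocked or insufficient
charts are dropped with a logged count. Under the simulator's independent
flip model with error rate e per abstractor and balanced truth,
E[κ] ≈ 1 − 4e(1 − e): e = 0.0125 centers κ near 0.95 (the almost-perfect
agreement regime) and e = 0.025 near 0.90. Both calibrations are verified
by Monte-Carlo against the closed form.

## The synthetic cohort generator

The generator emulates the *design-relevant* structure of a pediatric EHR
cohort, not clinical realism:

* **Strata first.** Each condition's Dx stratum is hit at exactly the
  requested size (codes are assigned to make it so), and latent truth is
  drawn conditional on stratum: Bernoulli(ppv_true) for Dx children,
  Bernoulli(one_minus_npv_true) for No-Dx. This makes published-table
  -shaped fixtures exact and the weighting math directly exercisable, and
  it is the quantity a validation study actually conditions on.
* **Nested age eligibility.** Conditions differ only in minimum age
  (defaults: ASD 2, DBD/anxiety/MDD 3, ADHD 5, all capped at 17), so
  eligible pools are nested. The generator assigns each child an age band
  (via its birth date relative to its period's end) that makes it eligible
  for exactly the conditions whose minimum it clears; configs must request
  per-condition totals that are equal within a minimum-age level and
  non-increasing with minimum age — the structure real cohorts of this
  design exhibit.
* **One period per child.** Enrollment covers, and all visits fall inside,
  one assigned study period (default shares equal; configurable), so
  period strata partition the overall strata, matching designs whose
  per-period percentages sum to 100% within a stratum. Dx counts are
  allocated across periods by largest remainder, hence exact.
* **Coding system by date.** Encounters before 2015-10-01 carry ICD-9-CM
  codes, later ones ICD-10-CM, using a representative billable code per
  condition; the stratifier re-derives the system per encounter date, so
  generator and stratifier agree by construction of the codes, not by
  shared bookkeeping (verified against a brute-force per-child rescan).
* **Chart review.** Blocked and insufficient notes are per-child chart
  properties (stable across re-reads and conditions) drawn at the
  configured rates (defaults 0.03 and 0, the latter because the frequency
  of insufficient-notes outcomes after frame cleaning is not publicly
  reported); abstractor errors are independent per reader. Disagreements
  in dual-read records are adjudicated to the truth, emulating expert
  adjudication; single readings stand, so abstraction error propagates
  into the gold standard at rate ≈ abstractor_error_rate, as in reality.
* **Demographics** (sex, race/ethnicity, household income band, insurance)
  are drawn independently from categorical distributions matching a large
  Southern-California integrated-system pediatric population; no
  correlation structure, which is sufficient for frequency-table
  reporting and nothing else.

What passing tests therefore show: the sampling, replacement, weighting,
and estimation machinery is correct for any cohort with this stratum
structure. What they do not show: robustness to messy real-world features
— comorbidity correlation, visit-level coding idiosyncrasies, children
active in several periods, informative blocking of notes.

## Sampling machinery

* `draw_sample`: simple random sampling without replacement per cell,
  never reusing a child within a condition; undersized cells raise with
  the cell named.
* `replace_blocked`: one replacement generation per call — blocked active
  records are retired and fresh same-cell children appended with the
  generation counter incremented; the pipeline loops review → replace
  until no active record is blocked (whether a replacement is itself
  blocked is only knowable after it is reviewed, so the loop cannot live
  inside the single-generation operation for real review data). Cell
  exhaustion raises, reporting the shortfall.
* `select_reliability_subsample`: balanced across conditions, balanced
  Dx/No-Dx within condition, split evenly between the two reabstractors;
  drawn from the main sample.
* `one_sided_margin`: the design calculator z_c·√(p(1−p)/n). At the
  planning values p = 0.85, n = 120 it returns 0.0418 for a 90% one-sided
  level (z ≈ 1.282) and 0.0536 at z = 1.645; which convention a given
  protocol's "margin" refers to should be stated explicitly — the
  calculator asserts neither.

## Numerical and design choices

* Half-up decimal rounding (not banker's) on the percent scale, matching
  how such tables are printed.
* Ages are completed years; a birthday on the evaluation date counts.
  Eligibility requires the age window to be met at some point during the
  period (the window [age at start, age at end] must intersect
  [min, max]); cumulative enrollment days (≥ 365) may span gaps.
* A single qualifying encounter code defines Dx; code matching is
  case-insensitive, decimal-point-insensitive, and prefix-based, so a
  3-character category matches all its subcodes.
* The shipped code sets are editable package defaults at category
  granularity (e.g. ICD-10 F84.x for ASD, F90.x for ADHD, F91.x for DBD,
  F40.x/F41.x/F93.0 for anxiety, F32.x/F33.x/F34.1 for MDD; ICD-9 299.x,
  314.x, 312.x + 313.81, 300.0x/300.2x/300.3x/309.21,
  296.2x/296.3x/300.4/311), not a curated clinical list; production use
  should load study-specific sets from JSON/CSV.
* Determinism: every stochastic stage draws from
  `numpy.random.default_rng` seeded from the config seed plus a fixed
  stream tag; rerunning a manifest reproduces all outputs byte-identically.

## Problem sizes used in the checks

Monte-Carlo checks run at sizes where the relevant asymptotics already
hold: parameter recovery uses 200 cohorts of 5,500 children (500 Dx /
5,000 No-Dx, generative PPV 0.95 and coding sensitivity 0.90, 40 records
sampled per stratum); κ calibration uses 300–500 replicates of the
180-record balanced dual-read design; the blocked-replacement audit uses
one 4,000-child cohort yielding the full 1,200-record design plus 30
exhaustively checked 30-child toy cohorts. Tolerances are 3 Monte-Carlo
standard errors of the estimated mean throughout.

## Known limitations

* The generator cannot represent a child eligible in multiple periods or
  with conflicting age bands across conditions outside the nested-minimum
  structure.
* Weighted-metric CIs ignore the finite-population correction (sampling
  fractions here are ≤ 10⁻³, where it is negligible).
* κ is two-rater, unweighted, binary only; no multi-rater or weighted
  variants.
* Period-specific metrics recompute weights from period-specific stratum
  sizes; whether a given published table used overall or period weights
  per period is often unstated, so both are possible via the `period`
  argument of `compute_weights`.
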