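# Methods

## The marker model

The pipeline evaluates a combined two-analyte marker for local control (LC)
after breast-conserving therapy.  Per patient we observe a normalized
hsa-miR-375 level and a normalized RASD1 level (both dimensionless ratios to
the EEF2 housekeeper).  Within a cohort, each marker is mapped separately to
a quartile index q ∈ {1,2,3,4} and the difference d = q(miR) − q(RASD1)
defines three strata (d > 0, d = 0, d < 0).  The construction is rank-based,
hence invariant to any strictly monotone rescaling of either assay, which is
what makes a microRNA assay and an mRNA assay comparable on one scale.

Quartile boundaries are the empirical 25/50/75 % quantiles under the
linear-interpolation definition (numpy's default), with lower-open /
upper-closed membership: x ≤ Q1 → 1, Q1 < x ≤ Q2 → 2, Q2 < x ≤ Q3 → 3,
x > Q3 → 4.  Consequences we rely on and test: the cohort minimum and maximum
always receive indices 1 and 4; boundary ties share the lower index
(deterministic and order-independent); with n divisible by 4 and distinct
values each index holds exactly n/4 patients.  Quartiles are always computed
within the cohort being analysed — applying the marker to a new cohort means
re-indexing, and the API only offers the cohort-level operation.

The continuous score for ROC analysis is the miR-375/RASD1 ratio.  Its
default form divides within-cohort fractional ranks (midranks for ties,
scaled to (0,1]) rather than raw levels, because the two assays have
incomparable units; the raw ratio is kept as an option and both are reported.

## Statistics

All statistics consumed by the analysis are implemented in
`mirascore.survstats` and verified against independent oracles in the test
suite (lifelines for KM/log-rank, scipy for the rank tests, scikit-learn for
AUC, brute-force enumeration for the exact branches).

* **Kaplan–Meier**: product-limit estimator; a censoring tied with an event
  at the same time stays at risk for that event (censored-after-events).
* **Log-rank**: k-group form; at each distinct event time the observed
  per-group events are compared with hypergeometric expectations, the summed
  covariance is inverted (pseudo-inverse) over k−1 groups, and the two-sided
  p comes from the χ² tail with k−1 df.  The subcohort comparison of the two
  unequal strata has df = 1; the whole-cohort comparison over three strata
  has df = 2.  No events anywhere yields statistic 0, p = 1 by convention.
* **One-sided Spearman**: rho from midranks.  For n ≤ 9 tie-free data the p
  is exact by enumerating all n! rank permutations; otherwise a
  t-approximation with n−2 df, evaluated with a continuity correction of
  half the tie-free rho lattice spacing (6/(n(n²−1))), which keeps the
  approximation within ~0.005 of the exact enumeration at n = 9.  The test
  direction defaults to the biologically assumed inverse correlation.
* **Mann–Whitney U**: midrank U; exact enumeration of all C(n₁+n₂, n₁)
  assignments for tie-free pooled samples of total size ≤ 12, else the normal
  approximation with tie and continuity corrections.  Size cutoffs are chosen
  so the exact branches finish in milliseconds; both branches are callable
  explicitly for testing.
* **ROC/AUC**: empirical curve over distinct thresholds, trapezoid AUC.  The
  AUC equals U/(n₁·n₀), so its p-value is the one-sided Mann–Whitney p for
  relapse scores exceeding control scores; a seeded label-permutation p is
  available as a cross-check.

## ddPCR quantification

Template molecules distribute over droplets approximately Poisson, so the
concentration is −ln(1 − k/n)/v copies/µL from k positive of n droplets with
droplet volume v.  The volume default is 0.85 nL (the QX200 EvaGreen
convention) and is overridable.  Saturated wells (k = n) are rejected, not
clipped — clipping would bias downstream ratios.  Technical duplicates are
averaged arithmetically on the concentration scale, and the replicate
coefficient of variation is recorded rather than used for exclusion.  Column
names in well exports vary by software version, so the reader takes a
column-name mapping with a documented default.

## The screen

Predicted-target lists are uppercased, deduplicated and intersected with a
minimum-database-support parameter (support 1 = the union pool, 2 =
pairwise-supported targets).  The differential test is a per-gene two-sided
Welch t by default; a moderated t is provided that shrinks per-gene pooled
variances toward a scaled inverse-chi-square prior fitted by moment matching
on log s² (prior df from the inverse-trigamma of the excess log-variance
spread).  This in-house empirical-Bayes scheme is in the LIMMA family but is
an approximation, not a LIMMA replication; the two methods rank genes almost
identically at large n (rank correlation > 0.99 in the tests).  Two-sided
p-values are used, with down-regulation imposed afterwards as a filter — the
screen's contract is "lower in relapse AND p < α", not a one-sided test.
There is no multiple-testing gate: the permissive α = 0.2 is paired with the
external database stringency, and a Benjamini–Hochberg column is emitted for
information only.  Genes with zero variance in both groups and equal means
get p = 1 by convention.  Output is ordered by p ascending with alphabetical
tie-break.

## The synthetic generator

`generate_cohort` draws the marker pair from a Gaussian copula whose
correlation is set by the closed form ρ_P = 2·sin(π·ρ_S/6), so the
*population* Spearman rho equals the configured target (−0.3 by default),
then maps to log-normal marginals (median 1, log-sd 1) — the minimal standard
choice for positive expression ratios.  Strata are then formed with the same
quartile operation the analysis uses, and relapse times are exponential with
the d > 0 stratum's hazard multiplied by a configurable ratio (default 3).
Censoring is administrative, uniform on 44–214 months.

The three cohort anchors — a 13/53 event fraction, a 77-month relapse-time
median, and the 44–214-month follow-up window — cannot hold simultaneously
for an exponential/uniform model (an exponential with median 77 censored on
that window yields roughly two-thirds events).  We treat the relapse:control
mix as the binding constraint, because the stratum analysis and the
recovery tests depend on it: by default the baseline hazard is solved
(closed-form per-stratum event probabilities + Brent root-finding) so the
marginal event probability equals `relapse_fraction` given the realized
strata and the censoring window.  Setting
`calibrate_event_fraction=False` instead fixes the latent relapse-time
median at `baseline_median_relapse_months`.

What the generator does *not* emulate: covariate-based case matching (only
the mix ratio), raw droplet counts (levels are drawn directly; the ddPCR
stage has its own micro-fixtures), batch effects, assay noise floors, or
non-proportional hazards.  Passing recovery tests therefore demonstrates
internal consistency of the pipeline under its own assumptions, not clinical
validity on real cohorts.

## Problem sizes and determinism

Every stochastic check is seeded.  The simulation scales used throughout —
2000 genes at 14 vs 14 for screen calibration, 2000 replications of 25 + 25
for log-rank type-I error, 200 replications at n = 160 for marker recovery,
n = 5000 for copula calibration — were chosen as the smallest sizes at which
the binomial/Monte-Carlo error of the measured rates is several times
smaller than the property bands they are checked against.  At these sizes
the full test suite and the acceptance script each run in well under a
minute on one CPU.

## Known limitations

* The moderated t is a simplified empirical-Bayes scheme, not LIMMA; at
  pilot-scale n its p-values differ slightly from LIMMA's even though
  rankings agree closely.
* Exact Spearman/Mann–Whitney branches require tie-free data; with ties the
  approximations are used at any n.
* The log-rank χ² reference is asymptotic; at very small n its p-values are
  only rank-concordant with the exact permutation null (this concordance is
  itself tested).
* The raw-ratio ROC mode is sensitive to the marginal scales of the two
  assays; the rank-ratio mode is the defensible default and both are
  reported.
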