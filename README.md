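# mirascore

Two-phase biomarker analysis for predicting local control after
breast-conserving therapy from the microRNA hsa-miR-375 and its validated
target gene RASD1, rebuilt as a tested, fully synthetic-data-capable
pipeline.

The scientific question: can the *joint* pattern of a microRNA and one of its
downstream targets — rather than either level alone — stratify early breast
cancer patients by their risk of local relapse?  Because miR-375 represses
RASD1, high miR-375 together with low RASD1 is the biologically coherent
high-risk signature.

## What the package computes

**Pilot screen** (`mirascore.screen`): in-silico miRNA-target prediction
lists (one plain-text file per database) are intersected, and each predicted
target is tested for down-regulation in relapse vs matched control samples on
a log-expression matrix.  The screen is deliberately permissive — a two-sided
Welch (or empirical-Bayes moderated) *t* at α = 0.2 with the direction filter
log-FC < 0 applied afterwards — because database support supplies the
stringency.

**ddPCR quantification** (`mirascore.ddpcr`): droplet counts are
Poisson-corrected, c = −ln(1 − k/n)/v copies/µL for k positive of n droplets
of volume v; technical duplicates are averaged and every target is normalized
to the EEF2 housekeeper, giving dimensionless per-patient levels.

**Combined marker** (`mirascore.marker`): within the cohort, each patient's
miR-375 and RASD1 levels are mapped to quartile indices 1–4 and subtracted,

d = q(miR-375) − q(RASD1) ∈ {−3, …, 3},

defining three strata: d > 0 (microRNA outranks its target; expected
high-risk), d = 0 (equal), d < 0 (target outranks the microRNA).  A
continuous companion score for ROC analysis is the miR-375/RASD1 ratio of
within-cohort fractional ranks (or of raw levels).

**Survival statistics** (`mirascore.survstats`): Kaplan–Meier product-limit
curves, the k-group log-rank test with hypergeometric per-time variance,
one-sided Spearman correlation (exact permutation enumeration at n ≤ 9),
Mann–Whitney U (exact at small n), and empirical ROC whose AUC p-value uses
the AUC = U/(n₁·n₀) identity.  All implemented in this package and
cross-checked in the test suite against lifelines, scipy and scikit-learn.

**Synthetic cohorts** (`mirascore.synth`): a Gaussian-copula generator with
log-normal marginals reproduces the assumed structure — negative marker rank
correlation, stratum-dependent exponential relapse hazard, uniform
administrative censoring on a 44–214-month follow-up window, a 13/53
relapse:control mix — so that the whole pipeline runs without patient data
and ships with a truth record for parameter-recovery testing.

## Worked example

```sh
python analysis/01_simulate_cohort.py   # synthetic cohort + screen matrix
python analysis/02_target_screen.py     # pilot screen
python analysis/03_combined_marker.py   # quartile marker + Spearman
python analysis/04_survival_roc.py      # KM, log-rank, ROC
```

On the default seed this prints

```
cohort: n=53, relapses=13, censored=40
...
150 predicted targets screened over 2000 genes (14 relapse vs 14 control)
36 targets down-regulated in relapse at p < 0.2
planted-truth recovery: 20/20
...
one-sided Spearman (inverse association assumed): rho = -0.176, p = 0.1034
patients with clearly unequal marker levels: 39/53 (74%)
...
log-rank, unequal strata only (n=39, df=1): chi2 = 1.556, p = 0.2123
log-rank, whole cohort       (n=53, df=2): chi2 = 2.561, p = 0.2779
ROC (rank ratio): AUC = 0.515, p = 0.4384
```

Reading: the 36 screen hits are the predicted targets whose expression drops
in relapse samples at the permissive threshold (all 20 genes planted by the
generator are among them); the negative rho is the assumed inverse
miR-375–RASD1 relation; 39 of 53 patients fall in the clearly unequal strata
used for the primary log-rank comparison; and at this cohort size a true
hazard ratio of 3 for the d > 0 stratum is *not* reliably significant — which
is exactly the power situation the recovery tests quantify at larger n.

The same stages are exposed as a CLI: `mirascore simulate|normalize|screen|
marker|survival|report --help`.

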