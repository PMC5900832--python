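# Methods

This note documents the models, numerical choices and limitations behind
`hdpoly`, in the spirit of a statistical package's methods appendix. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. Coupling estimation (dual GLM)

For a pair of network time courses the coupling strength is the average of the
two regression slopes obtained by using each series in turn as the dependent
variable, with nuisance regressors and an intercept always included. Two
choices deserve comment:

* **Z-scoring before the GLMs.** Without standardization the two slopes differ
  by the ratio of the series' variances and their average is unit-dependent;
  with it, the average is scale-free and reduces exactly to Pearson's r when
  the nuisance set is empty (asserted to 1e-10 in tests). The alternative
  (raw-scale betas) can be obtained by standardizing the inputs upstream; the
  estimator itself always z-scores.
* **Implementation.** `coupling_vector` residualizes all z-scored series on
  `[1, nuisance]` once and derives every pairwise average-beta from the
  residual cross-product matrix (the Frisch–Waugh identity); equality with the
  per-pair GLM implementation is tested to 1e-10. Constant series and
  rank-deficient nuisance designs raise errors that name the offending
  regressors.

The edge screen is deliberately uncorrected (per-edge two-tailed pooled t at
α = .02): it exists to define composites, not to control family-wise error.
Composites are descriptive outputs; they are never fed into the
cross-validated classifier, which consumes the full coupling vector. This
keeps the circularity of screen-then-average out of the CV loop. An edge
direction with no surviving edges yields an explicit "no composite defined"
result (`None`), never a silent zero.

## 2. Mixed-design ANOVA with covariate

`rm_anova` implements the classical univariate split-plot partition: between-
subject effects (group, centred covariate) are tested on subject means against
subjects-within-groups error; each within-subject stratum (factor, or factor
pair) is tested against its own interaction-with-subject error. Strata are
isolated by within-subject centering (single factor: subtract the subject
mean; factor pair: double-center each subject's table), after which
sum-to-zero contrast terms are fitted by least squares and Type III
sums-of-squares are obtained by drop-term model comparison. For W within
levels, G groups, n subjects and c covariates this yields the uncorrected
dfs (W−1, (W−1)(n−G−c)) for within effects and (G−1, n−G−c) between — the df
accounting that motivates treating the covariate as consuming one
between-subject df.

Validation: exact agreement with `pingouin.mixed_anova` (F and generalized eta
squared) on balanced no-covariate designs, and with R `car::Anova` Type III
sums of squares per stratum on an unbalanced covariate design (frozen oracle
values in the test suite). Greenhouse–Geisser epsilon is computed for
single-within designs but OFF by default; reported dfs are the sphericity-
unadjusted ones.

Generalized eta squared follows the Olejnik–Algina/Bakeman observed-factor
rules with all factors manipulated except the covariate: the denominator sums
the effect SS, every error stratum SS, and the SS of covariate-related
effects. It is invariant to affine rescaling of the response (tested).

## 3. Rank statistics

* **Mann–Whitney.** Both U conventions and the rank-sum W of the first sample
  are reported, because published "U" values are often rank sums (a U cannot
  exceed n1·n2). P-values are exact (no ties, n1·n2 ≤ 64) or normal with tie
  correction. The Hodges–Lehmann shift is the median of all n1·n2 pairwise
  differences (second minus first sample); its 95% CI uses the Moses
  order-statistic construction with the critical rank taken from an exact
  subset-sum null CDF of U (dynamic programme, verified against full
  enumeration) up to n1·n2 ≤ 2000, else its normal approximation.
* **Spearman CIs** use the Fisher-z interval 1.96/√(n−3). Published CIs for
  such correlations are sometimes inconsistent with any standard method at the
  stated n; no attempt is made to reverse-engineer nonstandard intervals.
* **Steiger's z** compares two dependent correlations sharing one variable via
  Fisher transforms and the pooled-correlation covariance term. By default it
  compares magnitudes (|r1| vs |r2|), flipping variable signs consistently
  (including the sign of the correlation between the two non-shared
  variables), since "explains more variance" is a magnitude claim. Type I
  error is calibration-tested at ~5% by simulation.
* **Normality check** is a Lilliefors-corrected one-sample KS against a normal
  with the sample's mean and SD. A reject flag accompanies (statistic, p); a
  pile-up (heavily discrete) distribution produces a large statistic and a
  rejection. A KS *statistic* of exactly 1 is unattainable for finite
  continuous data; software that prints "ks = 1" is reporting a reject flag.

## 4. Classifier

Preprocessing is a three-stage pipeline — standardize, residualize on age plus
site indicators, rank-based inverse-normal (Blom offset, average ranks for
ties) — refit on the training subjects of every fold and applied to held-out
subjects through the stored parameters; the inverse-normal step maps held-out
values by interpolation into the training population's reference distribution,
clamped at its extremes. The pipeline never sees labels, so per-fold
transforms are computed once per dataset and shared across label permutations
(mathematically identical to refitting per permutation, and what makes
199-permutation × hundreds-of-replicates calibration tractable). Note that
exact zero correlation with the covariates holds at the residualization stage;
the subsequent monotone inverse-normal step preserves it only approximately.

The SVM is the standard weighted soft-margin linear machine (C = 1, no inner
tuning loop, per-class costs proportional to inverse class frequency
normalized to mean 1). Any exact solver satisfies the contract; the
implementation calls libsvm — through scikit-learn's estimator for one-off
fits and through its low-level binding inside the LOO/permutation loops, where
per-call validation would otherwise dominate runtime. Equivalence of the two
routes is asserted in the tests to solver tolerance.

Evaluation: LOO predictions pooled into one confusion matrix; F1 with the
patient class positive, defined as 0 when nothing is predicted positive;
empirical p by the add-one rule (never zero). Permutations shuffle labels
(class counts preserved); all randomness flows from one master seed through
`numpy` SeedSequence spawning, so results are independent of execution order.

**Hyperplane distance.** When features outnumber subjects the max-margin
solution places nearly every *training* point exactly on the margin, so
training-model distances degenerate to ±1/‖w‖. The prognostic score is
therefore each subject's **held-out** distance — from the fold in which that
subject was not trained on — which stays graded and is the score the
median-split converter prediction uses. `hyperplane_scores` still computes
distances under any given model for the low-dimensional case and for scoring
external cohorts.

**External validation** fits preprocessing and the SVM on the training cohort
only and scores the test cohort once; the null distribution shuffles the
*test* cohort's labels against the fixed predictions. This choice (rather
than retraining per permutation or shuffling training labels) tests exactly
the hypothesis "the fixed model's assignments align with the true labels".
A `paper_mode` flag fits preprocessing once on the full sample inside CV — the
leaky variant some published pipelines use — for comparability only.

## 5. Synthetic cohort generator

The generator emulates the study conditions the analysis assumes; its defaults
are fixed once and are the conditions under which all recovery tests run.

* **Cohort:** 21 controls, 19 carriers; ages ~ N(45, 11²) clipped to [26, 68];
  CAG uniform on 39–45; two sites. Estimated years to diagnosis from the
  Langbehn point model (expected onset age 21.54 + exp(9.556 − 0.146·CAG));
  disease burden age × (CAG − 35.5); CAPs age × (CAG − 33.66)/432.3326 (≈1 at
  expected onset). Median split on estimated years (ties to "near") gives a
  10/9 near/far split at n = 19.
* **Latent onset:** the Langbehn estimate plus a scaled Student-t(3) deviation
  (default scale 4 y). The heavy tail produces occasional large misestimates,
  hence unexpected converters; conversion within follow-up is latent onset ≤
  5 y. The unexpected-converter rate rises monotonically with the deviation
  scale (tested over a 3-point grid).
* **Proximity ramp:** g = clip((15 − latent)/15, 0, 1.5) — zero beyond 15
  years from onset, 1 at onset, saturating for overdue subjects, and zero for
  controls. Fifteen years makes the far subgroup (median split ≈ 13–16 y)
  essentially control-like while grading the near subgroup, which is what
  produces the near/far dissociation downstream.
* **Features:** SCV baselines/slopes chosen at anatomically plausible mm³
  scales (e.g. caudate 7400 − 2000·g, noise SD 7% of baseline), CT baselines
  ~N(2.55, 0.25²) mm per parcel with global 0.05 and focal 0.12 mm·g thinning
  on 40 of 74 parcels, linear age slopes, additive per-site offsets drawn once
  per site (0.5 × each feature's noise SD) — the simplest mechanism that makes
  site residualization testable.
* **Time courses:** multivariate normal draws from a subject-specific target
  correlation matrix (background 0.08; ten planted hypo edges at 0.45 −
  0.25·g; five hyper edges at 0.10 + 0.15·g; off-diagonals shrunk if needed to
  keep the matrix positive definite), plus seven AR(1) nuisance series mixed
  in with random loadings and returned for regression. Empirical couplings
  converge to the targets with T (tested at T = 3000 to ±0.05).

**What the generator does not emulate:** spatial structure (no volumes or
surfaces), temporal autocorrelation of the network signals themselves,
scanner-specific noise spectra, longitudinal scans, somatic CAG instability,
or realistic inter-feature covariance within SCV/CT blocks. Passing recovery
tests therefore demonstrates that the pipeline detects the statistical
structure it targets — not that real cohorts carry that structure.

## 6. Problem sizes and determinism

Calibration experiments in the tests and acceptance script use desk-scale
sizes chosen by the package: chance-level calibration at n = 40 subjects ×
199 permutations × 20 seeds; p-uniformity at 200 replicates of n = 12 × 199
permutations; pattern recovery on the default 40-subject cohort with 199
permutations. Full-scale runs (1,000 permutations) are the CLI default.
Everything is reproducible bit-exactly under a fixed config and seed: one
`default_rng` stream drives the generator, and per-cell/per-permutation
streams are spawned deterministically.

## 7. Known limitations

* The univariate rm-ANOVA branch has no multivariate (Pillai) or mixed-model
  alternative; sphericity handling is GG-epsilon only, off by default.
* One continuous covariate and at most two within factors are supported —
  exactly the designs the analysis needs.
* The Langbehn survival/penetrance form is out of scope; only the point
  estimate of expected onset age is used.
* `partial_spearman` supports a single covariate; its CI uses a one-fewer-
  effective-observation Fisher interval, an approximation.
* With p ≫ n the feature weights of the SVM are not interpretable individually;
  no feature selection or probability calibration is provided by design.
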