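# Methods

`abapipe` implements a classification-biased brain-age workflow for AD vs.
CN prediction from tabular morphometric features (FreeSurfer-style ROI
volumes and thicknesses). This note documents the model chain, its
assumptions, the tunable parameters and their defaults, what the synthetic
cohort generator does and does not emulate, and the numerical and design
choices a maintainer should know about.

## The model chain

Each training/test execution runs six stages, every model fitted on the
training partition only:

1. **Standardization.** Per-feature z-scoring `(x − μ)/σ` with the
   (n−1)-denominator σ, fitted on the training rows and applied unchanged to
   both partitions. Chronological age is never standardized: it is the
   regression target and a classifier input, and keeping it in years keeps
   every MAE in years. Zero-variance features are an error at fit time
   (a relative floor of `1e-12·max(1, |μ|)` catches numerically constant
   columns). Missing values are rejected rather than imputed; table
   cleaning is assumed to have happened upstream. No ICV normalisation is
   performed and ICV is not treated specially by the loader.

2. **Outlier removal.** An isolation forest (t = 100 trees, sub-sampling
   size ψ = 256, height limit `ceil(log2 min(ψ, n))` — 8 at the default ψ)
   is fitted on the standardized training rows without using labels. Scores
   are `2^(−E[h(x)]/c(ψ))` with the usual average-path-length correction at
   unexpanded nodes, so they lie in (0, 1] and are right-skewed on clean
   data. The cutoff is the Tukey far-out fence on the *training* scores,
   `Q3 + 3·IQR`, with linear-interpolation quantiles (the cutoff value
   depends on this convention, so it is fixed and documented). Records
   scoring strictly above the cutoff are removed from training; flagged
   test records are excluded from metrics and reported separately by
   default (`include_flagged_test=True` forces them in). The forest is
   scikit-learn's `IsolationForest`; serialization exports the raw split
   arrays of every tree and an in-package path-length scorer reproduces the
   library scores from those arrays alone, which is also how a
   deserialized model scores.

3. **Ranking.** Features are ordered by decreasing absolute point-biserial
   correlation with the AD/CN label (Pearson correlation against the label
   coded 0/1). Ranking is invariant to per-feature affine rescaling, so it
   does not matter whether it sees raw or standardized values.
   Zero-variance values are defined to have r = 0; ties break
   lexicographically by feature name so the order is total and
   reproducible.

4. **Forward wrapper selection (F1).** One pass over the ranked list. For
   each candidate, the full downstream model (CN-only LASSO age regression
   plus (age, ABA) logistic classifier) is fitted on stratified inner-CV
   training splits of the outer-training partition and scored by
   classification accuracy on the inner validation splits; the same splits
   are used for every candidate so comparisons are paired. The top-ranked
   feature is always retained so the age model is never featureless.

   *Acceptance rule.* The obvious rule — accept on any strict improvement
   of mean inner accuracy — was measured to admit roughly five percent of
   pure-noise candidates on synthetic cohorts: with ~100 candidate
   features, F1 fills with features whose apparent gain is inner-CV noise.
   The default rule therefore demands consistency as well as improvement:
   a candidate is accepted iff the mean paired fold-wise accuracy
   difference exceeds `epsilon` (default 0), exceeds one standard error of
   those differences, and is positive in a majority of inner folds. A
   one-sided paired t-test at α = 0.05 was evaluated and rejected: once
   accuracy saturates it also rejects genuinely informative features whose
   marginal gain is small. `SelectionConfig(rule="strict")` restores the
   plain strict-improvement rule. Inner CV is stratified 5-fold by
   default; the wrapper's inner LASSO uses a fixed penalty
   (`lasso_alpha = 0.1` on standardized features, age in years) to keep
   candidate evaluation cheap, and `top_k` can truncate the candidate list
   (default: all features are examined).

5. **Apparent brain age (F2, ABA).** LASSO regression of chronological age
   on the offered subset F1, trained on *CN training subjects only*:
   `aba = a0 + Σ a_i f_i`, intercept unpenalized. The L1 penalty zeroes
   redundant coefficients, so the support F2 ⊆ F1 is an embedded second
   selection stage. Because the regression learns healthy ageing over
   disease-selected features, AD subjects receive systematically
   overestimated ages; the Age Deviation Score `ADS = ABA − age` (years)
   carries the signal. The penalty is `"auto"` by default: 5-fold CV on
   the CN training rows minimising mean absolute error over a 50-point
   logarithmic grid from 5 to 1e−3 (descending, warm-started; ties go to
   the sparser end). A fixed penalty is supported for reproducibility.
   Coefficients with magnitude ≤ 1e−12 after fitting are set to exactly
   zero so the support is well defined.

6. **Classification and decomposition.** A two-input logistic regression
   on (age, aba); in the package's sign convention a subject is AD when
   `c0 + c1·age + c2·aba < 0`, with exact boundary ties going to CN
   (conservative for a screening biomarker). The fit is unpenalized
   maximum likelihood; perfectly separated training data trigger a
   fallback to a weak ridge (C = 1000) with a warning. Substituting the
   ABA equation and dividing by the subject-specific denominator
   `D = c0 + c1·age + c2·a0` yields per-feature scores
   `s_i = −c2·a_i·f_i / D` with the identity
   `boundary = D·(1 − Σ s_i)`. The decision read off the score sum
   therefore depends on the sign of D: AD ⟺ Σs > 1 when D > 0 and
   AD ⟺ Σs < 1 when D < 0. The direction is derived from the runtime sign
   of D rather than assumed, and the equivalence with the boundary
   decision is exercised exhaustively in the tests — it is the module's
   central contract. D = 0 subjects are flagged boundary-degenerate and
   get no scores. Quartile context (five-number summaries of the training
   AD and CN score distributions per feature) situates an individual
   subject's scores against typical group profiles for box-plot style
   explanation.

## Evaluation protocol

The main estimator is repeated stratified k-fold cross-validation
(10 × 10-fold by default). Stratification is by diagnosis — the class
balance at n ≈ 100 per gender would otherwise produce class-empty folds;
stratification by cohort is not performed. Within each repeat the test
predictions of all folds are pooled into one confusion matrix (AD
positive); accuracy, AD recall and AD precision are reported in percent as
mean and SD *across repeats*. Regression quality (MAE in years, Pearson r
of ABA vs. age) is reported per diagnostic group from the pooled test
predictions. A single stratified holdout (80–20 by default) produces the
per-subject score reports and quartile context for explanation; a
cross-cohort mode trains on one set of cohort tags and tests on another,
mixed genders allowed. `fit_final_model` fits all stages on all rows and
serializes the bundle to JSON (floats round-trip exactly, so a reloaded
bundle reproduces predictions bit for bit).

All randomness flows from one master seed, expanded per repeat/fold/stage
through `numpy.random.SeedSequence`, so identical seeds give identical
results and fold results carry a stable SHA-256 hash of every fitted
sub-model. The leakage test perturbs test partitions after the fold split
and asserts those hashes unchanged.

Ablations: `use_ffs=False` skips the wrapper and offers every feature to
the LASSO — the "no feature selection" configuration (M5-style) against
which the full method (M6-style) is compared. On cohorts containing
age-informative but disease-irrelevant features the comparison shows the
signature of the classification bias: the full method has *lower* CN
correlation between ABA and age, yet higher classification accuracy.

## The synthetic cohort generator

Real multi-site AD/CN morphometry tables are access-controlled, so the
generator emulates their statistical structure with a linear-Gaussian law
chosen deliberately — every downstream model is linear, so parameter
recovery is analyzable:

    effective_age = age + acceleration · 1[AD]
    feature_j     = baseline_j − slope_j · effective_age_j + N(0, noise_sd²)

* Demographics follow a reference multi-site composition: ten gender ×
  cohort × group strata with truncated-normal ages (means ≈ 65–76 y,
  SDs ≈ 6–9 y, range ≈ 55–91 y), including one CN-only younger cohort.
  The stock 1,901-subject composition is available as `table1_config()`;
  the default study fixture scales it proportionally to 1,000 subjects.
* Features come in three kinds: **AD-informative** (ageing slope *and* AD
  acceleration — the ground-truth set a biased selector should recover),
  **age-only** (same slope, no acceleration — informative about age,
  useless for diagnosis given age), and **pure noise**. The default
  fixture uses 5 + 15 + 80 of 100. The age-only block exists because the
  defining qualitative contrast of the method — selection lowers CN r
  while raising accuracy — only occurs when age-informative but
  disease-irrelevant features are available to an unbiased age model.
* Defaults: slope 0.03 units/year, noise SD 0.21, AD acceleration 8
  years. These give a per-feature group separation of d ≈ 1.14 given age
  (8 × 0.03/0.21) and a five-feature Mahalanobis separation of ≈ 2.56,
  i.e. a Bayes-optimal accuracy near 92% at the ~25% AD prevalence of the
  demographic composition — a difficulty comparable to the real task, not
  a separable toy.
* Outliers are planted by displacing a random subject's whole feature
  vector by ±`outlier_magnitude` (default 10) noise-SDs per feature with
  random signs — not by label flipping. The contamination fixture plants
  20 among 800 clean records.
* `bayes_reference` computes the exact posterior P(AD | features, age)
  under the generative law; its accuracy upper-bounds any pipeline run on
  the table. It uses the overall AD fraction as prior and deliberately
  ignores gender and cohort tags as evidence: the pipeline does not use
  cohort either, and a CN-only cohort tag would otherwise make the
  yardstick unreachable. It also conservatively ignores the small
  age-distribution differences between groups.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: site/scanner batch effects, correlated
feature blocks (real ROI volumes are strongly inter-correlated),
non-linear or non-Gaussian ageing trajectories, label noise in clinical
diagnoses, MCI or longitudinal structure, and heavier-tailed anatomical
variability. Recovery results here certify the machinery, not clinical
performance.

## Numerical choices

* Quantiles everywhere (Tukey fence, quartile context) use linear
  interpolation between order statistics.
* LASSO: scikit-learn coordinate descent, `tol = 1e-7`, up to 10⁴
  iterations; `penalty = 0` falls back to ordinary least squares.
* Logistic: lbfgs, up to 500 iterations (200 inside the wrapper's inner
  loop, where the separation fallback warning is suppressed).
* Strict `>` at the outlier cutoff: a record scoring exactly the cutoff is
  kept.
* Scaled-down problem sizes are used for the shipped study conditions:
  the default fixture has 1,000 subjects and 100 features, repeated CV in
  the acceptance analysis runs 2 × 5-fold. These sizes were chosen so the
  full analysis reproduces on a laptop-class single core in about a
  minute while keeping every qualitative contrast of the method intact.

## Known limitations

* The wrapper is a single forward pass without backtracking; an accepted
  feature is never revisited (the LASSO stage prunes, but only within F1).
* The acceptance rule's one-SE/majority guard trades a small risk of
  rejecting weakly informative features for a large reduction in noise
  acceptances; on cohorts where the informative effects are much weaker
  than the defaults, `rule="strict"` with a positive `epsilon` may be
  preferable.
* Per-gender analysis is a convention of the pipeline's users, not
  enforced by `run_fold`; cross-cohort validation deliberately mixes
  genders.
* ABA is not an estimate of biological brain age: it is biased by design,
  and its CN correlation with age *decreases* as the classification bias
  strengthens.
* No brain-age bias correction (regression-to-the-mean adjustment) is
  applied, and no nonlinear age models are available.
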