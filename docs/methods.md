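# Methods

## Estimands

Two raters independently assign each of N subjects to one of n
categories on a shared scale (a fully-crossed design). With joint
proportions p_ij (rater A row, rater B column), row marginals p_i and
column marginals q_j, every statistic in the package is a
chance-corrected weighted agreement rate

    kappa = (P_o - P_e) / (1 - P_e)
    P_o   = sum_ij w_ij p_ij
    P_e   = sum_ij w_ij p_i q_j

with an agreement-weight matrix w that is symmetric, unit-diagonal and
valued in [0, 1]. Identity weights give Cohen's kappa (exact matches
only); the power scheme w_ij = 1 - (|i-j|/(n-1))^m gives the linear
(m = 1) and quadratic (m = 2) weighted kappas. The equivalent form
kappa = 1 - (1 - P_o)/(1 - P_e) reads as one minus the ratio of
observed to chance-expected weighted disagreement.

Conventions fixed here:

- Category indices are 0-based consecutive integers in declared scale
  order. The normalised distance |i-j|/(n-1) is unchanged by a 1-based
  convention, so only the documentation, not the numbers, depends on
  this choice.
- Categories declared on the scale but never used keep their zero row
  and column: weight distances are a property of the declared scale,
  not the observed one.
- Any real exponent m >= 1 is accepted; only m = 1 and m = 2 carry
  conventional names. For n = 2 every power weighting equals the
  identity, so weighted and Cohen's kappa coincide on 2x2 tables.
- Custom weight matrices are accepted but validated (symmetry, unit
  diagonal, range); the choice of weights beyond the power family is a
  subject-matter judgment the package does not automate.
- kappa is undefined when P_e = 1, which happens exactly when both
  raters place every subject in one and the same category. That raises
  `UndefinedKappaError`; no sentinel value is returned.

## Inference

**Asymptotic.** The standard error is the Fleiss–Cohen–Everitt
large-sample variance of weighted kappa under the non-null
distribution,

    N var = [ sum_ij p_ij { w_ij (1-P_e) - (wbar_i. + wbar_.j)(1-P_o) }^2
              - (P_o P_e - 2 P_e + P_o)^2 ] / (1 - P_e)^4

with wbar_i. = sum_j q_j w_ij and wbar_.j = sum_i p_i w_ij; identity
weights recover the classical non-null variance of Cohen's kappa. The
1-alpha interval is Wald (point ± z_{1-alpha/2} se, clipped to
[-1, 1]) and the test of kappa = 0 is the two-sided Wald test on the
same se, which makes "p < alpha" and "CI excludes 0" logically
equivalent — the reporting convention the bundled reanalysis follows.
The non-null (rather than null-hypothesis) variance is used for both
so that this equivalence holds exactly. A zero se yields a degenerate
point interval flagged in the output (p = 0 unless the point is 0).

**Bootstrap.** Nonparametric percentile bootstrap resampling subjects
with replacement (default n_boot = 2000, explicit seed mandatory).
Resampling the table's cells multinomially is the same distribution and
is what `bootstrap_ci_from_table` does by expanding counts to
subject-level pairs. Replicates on which kappa is undefined are
dropped and counted; more than 50% dropped aborts with a diagnostic.
The bootstrap p-value is twice the smaller tail proportion of
replicates across zero (capped at 1). Percentile rather than BCa
intervals are used for transparency; at the bundled sample size
(N = 31) the two CI routes agree to within 0.08 on each bound, which
the tests assert.

**Defaults.** alpha = 0.05, n_boot = 2000. Monte-Carlo checks in the
test suite: the asymptotic se is within 15% of the empirical SD of the
estimator at N = 2000 (500 replicates), and the 95% CI covers the
population kappa in 93–97% of 1000 simulated datasets of N = 200 drawn
from the bundled testing-R1 proportions.

## Interpretation and statistic selection

Magnitude labels use the Landis–Koch bands — <=0 no agreement,
(0, 0.20] slight, (0.20, 0.40] fair, (0.40, 0.60] moderate,
(0.60, 0.80] substantial, (0.80, 1] almost perfect — as right-closed
intervals, so 0.40 is "fair". The bands are the field's default
convention and are configurable; they are applied to the
full-precision point estimate, not the rounded one.

A significance gate (default on) reports "no agreement" whenever the
test of kappa = 0 is not significant at alpha, regardless of the point
estimate. This mirrors a common reporting rule but is not universal,
hence the flag.

Statistic selection is deterministic in (n_categories, is_ordinal):
two categories -> Cohen's kappa (weighting cannot discriminate);
three or more nominal categories -> Cohen's kappa (no defensible
distance); three or more ordered categories -> weighted kappa,
reporting both the linear and quadratic weightings, since they answer
slightly different questions about how disagreement severity should
count.

## Simulator

`JointRatingModel` is the population analogue of a contingency table: a
joint probability over category pairs, from which population kappas
come in closed form. Samples are i.i.d. draws from that joint, one
generator stream per run, subjects drawn in index order — reproducible
at the sequence level given the seed. The simulator emulates exactly
the exchangeable fully-crossed design the estimators assume; it does
not model rater dependence (raters influencing each other), drift over
subjects, or missing ratings, so passing recovery/coverage checks says
nothing about those violations in real data.

The prevalence-paradox demonstration uses 2x2 models that hold the raw
observed agreement P_o fixed while skewing both raters' marginals
symmetrically: both off-diagonal cells carry (1-P_o)/2 and the diagonal
splits so the first-category marginal equals the requested skew s.
This is feasible only for s in [(1-P_o)/2, (1+P_o)/2]; infeasible grid
points are returned as flagged rows rather than dropped. At P_o = 0.8
the balanced model gives kappa = 0.6 and kappa declines monotonically
as s grows — chance agreement rises with imbalance while raw agreement
stands still, which is the paradox.

The default grid (s = 0.50 to 0.95 in steps of 0.05 at P_o = 0.8) was
chosen to span balance to near-degeneracy and to include one infeasible
point, exercising the flagged-row path.

## Bundled data and reporting

The six 3x3 RECIST response-assessment matrices (PR/SD/PD vs a
reference standard; R1, R2 and an automated segmentation method on a
testing dataset and a validation cohort, N = 31 each) are bundled as
raw counts with category order PR < SD < PD — the order of worsening
response, which is what the weighted statistics depend on. The
agreement values originally reported alongside these matrices
(`kappa_star`) were computed by an unknown method; they are carried as
metadata in reports and never recomputed or treated as a target.

All computation is done in full floating precision; only rendered text
reports round, to 2 decimals with ties away from zero, matching the
convention of published agreement tables. JSON reports serialise at
full precision, and the report's embedded count matrix is sufficient to
reproduce every serialised statistic bit-for-bit (asserted in tests).

## Numerical and design notes

- Degenerate inputs: empty tables, non-square matrices, negative or
  fractional counts, unknown labels (reported with the offending
  subject id) are rejected at construction, not at estimation.
- The brute-force estimator (`brute_force_kappa`) tallies observed
  agreement per subject and expected agreement over all ordered subject
  pairs; it exists purely as an independent oracle for the matrix
  computation and the two agree to 1e-12 on randomised datasets.
- Problem sizes in the statistical test battery (1000 replicates of
  N = 200 for coverage; 10 seeds of N = 20,000 for bias; 500
  replicates of N = 2000 for the se check) are desk-scale choices that
  keep the whole suite in a few seconds while leaving Monte-Carlo error
  well inside the asserted tolerances.
- Known limitations: two raters only (no Fleiss' kappa or
  Krippendorff's alpha), no missing-rating handling, no exact
  small-sample or Bayesian inference, no tests against non-zero
  reference kappas.
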