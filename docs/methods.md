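# Methods

This note documents the models, numerical conventions and design
choices behind netpheno, and what the synthetic-data validation does and
does not establish about real resting-state data.

## Network construction

A subject's T × R ROI time-series matrix is reduced to a Pearson
correlation matrix (columns must have nonzero variance; the offending
ROI is named otherwise). Negative correlations are zeroed by default —
positive-edge networks have better test–retest properties, and the
binary pipeline analyzes positive coupling only. An `absolute` mode
(|r|) is available as a configuration flag for sensitivity analyses, as
is a Fisher r-to-z transform; note the z-transform is monotone on
nonnegative values, so it cannot change the thresholded graphs, only the
connectivity values used in the association stage.

**Sparsity thresholding.** Sparsity S is the fraction of retained edges
out of R(R−1)/2 pairs. At each S in the sweep (default 0.10–0.30 in
steps of 0.01, i.e. 21 thresholds; the step is configurable) the
`round(S·R(R−1)/2)` largest positive off-diagonal values become edges.
Rounding is half-away-from-zero; ties in correlation value are broken by
(i, j) lexicographic order so results are reproducible (ties have
measure zero in real data but occur in constructed fixtures). If fewer
strictly positive pairs exist than the target, the edge count is clamped
and a warning is recorded in the stack's provenance. Fixing the edge
count per threshold rather than a correlation cutoff means all subjects
share network density, removing overall-correlation-strength differences
between groups; it also sidesteps the > vs ≥ ambiguity of a
correlation-valued cutoff. Slices are thresholded independently and are
not guaranteed to be nested.

## Nodal metrics and AUC

Degree is the row sum of the boolean adjacency matrix. Shortest-path
lengths are computed by simultaneous breadth-first search (all source
rows expanded one level at a time with boolean matrix products), with
unreachable pairs at +∞. Nodal global efficiency is the inverse harmonic
mean of the lengths from node *i*, `(1/(N−1)) Σ_{j≠i} 1/L_ij`;
unreachable targets contribute 0 (the 1/∞ limit), which keeps the metric
defined on the disconnected graphs that necessarily occur at S = 0.10.
Efficiency lies in [0, 1] at every threshold.

The AUC over the sweep uses the composite trapezoid rule on the exact
sparsity grid. No smoothing or renormalization is applied, so a constant
profile v integrates to v·(S_max − S_min).

## Group screening

Per node, the (degree-AUC, efficiency-AUC) pair enters a multivariate
general linear model with group plus covariates; the group effect is
tested with Pillai's trace V. With a single-df effect and p = 2
dependent variables the conversion F = [V/(1−V)]·(df_e − 1)/2 with
(2, df_e − 1) degrees of freedom is exact. Univariate ANCOVAs test each
metric separately; partial eta² is SS_group/(SS_group + SS_resid).
Implementation is by QR residual projection, vectorized across nodes;
unit tests pin the results to statsmodels' `anova_lm` and `MANOVA` on
fixtures.

Covariate handling: age and motion are standardized (conditioning), sex
and site enter as drop-first indicator columns. Rank-deficient designs
raise with the collinear columns named. Constant metrics yield NaN
statistics flagged in the output rather than an exception, so one
degenerate node does not abort a screen.

FDR uses Benjamini–Hochberg step-up. Three separate families are
corrected across nodes — MANCOVA, degree-ANCOVA, efficiency-ANCOVA —
with a `joint-ancova` option pooling the two univariate families;
"consistent" nodes are those significant after FDR in all three tests.
ANCOVAs are run for all nodes regardless of the MANCOVA outcome, and
directions are coded W/E from the sign of the adjusted group difference
(E = group 1 higher), reported only where the corresponding test
survives FDR.

## Phenotype association

Partial correlation residualizes both variables on the covariates (sex,
age, motion by default; always with an intercept) by least squares and
correlates the residuals; p-values use the t distribution with
n − 2 − k df. The metric screen spans (consistent nodes × 2 metrics) as
one BH family. Functional-connectivity screens are run per seed node
over its R − 1 connections (one family per seed, a configurable
choice), only for nodes with at least one AHS-associated metric.
Connectivity is the raw Pearson correlation of the two time series by
default, with a Fisher-z flag. Subjects without an AHS score are dropped
with a logged count.

## Prediction and permutation calibration

Significantly associated metrics are sign-unified (negatively associated
metrics are negated) and averaged within family into `T_deg` and
`T_eg`. Intrasample prediction fits ordinary least squares on the
training nine folds and predicts the held-out fold; the estimate is the
Pearson correlation between out-of-fold predictions and observations
over all subjects. Classification uses unpenalized logistic regression
with out-of-fold class assignment by thresholding the predicted
probability of class 1 at 0.5, reporting overall and per-group
accuracies (0 = Western, 1 = Eastern coding).

Fold assignment is uniform random for regression and stratified by class
for classification (this prevents single-class training folds; the
choice of partitioning scheme was otherwise open). The permutation null
reshuffles the outcome across subjects and reruns the full
cross-validation, 1000 times by default, drawing a fresh fold seed per
repetition; the 95% interval is read at the sorted 25th and 975th
positions (1-based; round-half-up scaling for other n_perm), and
"significant" means the observed estimate exceeds the upper bound. A
permutation p-value (1 + #{null ≥ observed})/(n_perm + 1) is reported
alongside. Only the outcome is permuted, not the covariates.

**Leakage.** By default, direction unification and composite membership
are fixed on the full sample before cross-validation — the convention
this analysis lineage uses, but a known source of optimism because
selection sees the test folds. The `leakage_free` flag instead re-estimates
membership and signs within every training fold (over all
consistent-node metrics). The acceptance tests calibrate the default
path by re-running the sign unification inside every permutation
repetition, so the null distribution carries the same selection optimism
as the observed estimate.

**CPM.** The connectome-based predictive modeling variant screens every
nodal metric within each training fold by zero-order Pearson correlation
with the score (two-sided p < 0.05), sign-unifies on training data,
averages into fold-specific composites and fits OLS. Folds with no
selected metric fall back to predicting the training mean, with a
warning. Metrics selected in all 10 folds form the stable set used for
the cross-sample classifier, whose signs are taken from the AHS cohort.

## Synthetic cohorts

The generator emulates a two-group resting-state study:

- **Population connectome.** A symmetric nonnegative weight matrix with
  a Bernoulli(density) edge pattern and Uniform(0.2, 0.6) weights. The
  implied covariance is weights + (λ + noise_sd²)·I, where λ is the
  smallest ridge making the matrix positive definite plus a 0.01 margin
  (recomputed per weight matrix so per-subject variation stays
  sampleable); noise_sd models observation noise and shrinks all
  implied correlations.
- **Group effect.** In group 1, every edge incident to an effect node is
  scaled by (1 + delta) — each edge is scaled once even if both ends are
  effect nodes. Effects are planted on edges, never on metrics, so they
  reach the statistics only through the full analysis pipeline. Because
  edge counts are fixed per threshold, strengthening some nodes' edges
  necessarily displaces edges elsewhere; neighbouring nodes can
  therefore show real compensatory differences, which is a property of
  sparsity-normalized pipelines, not an artifact.
- **Individual variation.** Each subject jitters per-node connection
  strengths (multiplicative 1 + Normal(0, 0.15) gains), giving the
  within-group metric variance that phenotype coupling requires.
- **Phenotype.** The AHS-like score is a weighted sum of the subject's
  *noiseless* nodal metrics — computed by running the actual
  thresholding and AUC code on the subject's implied correlation
  matrix — plus Gaussian noise. A target-correlation option sets the
  noise so the noiseless signal correlates with the score at a chosen
  level; measured metrics then correlate lower by the metric's
  reliability (about 0.5–0.7 at T = 150, R = 20), mirroring attenuation
  in real data.
- **Covariates.** Age is Normal (group shift −9 years by default), sex
  Bernoulli (−0.2 group shift), motion lognormal (+0.1 log shift), site
  a 3-level categorical with group-dependent mixing. Defaults mirror the
  confounding structure of a multi-site two-culture sample. Covariates
  shift between groups but do not causally affect the simulated brain
  signal, so they exercise covariate adjustment without biasing null
  calibration.
- An optional AR(1) flag adds temporal autocorrelation while preserving
  the stationary covariance.

What the generator does *not* emulate: hemodynamic response and BOLD
spectral structure, spatially structured noise, site-specific scanner
effects beyond covariate shifts, non-Gaussian marginals, and realistic
network topology (small-worldness, modules). Passing recovery tests
therefore demonstrates the statistical machinery is correct and
calibrated under the stated generative model — not that effect sizes
will transfer to real R-fMRI cohorts.

## Operating points and problem sizes

Simulation tests run at a desk scale chosen to keep the full suite fast
while preserving the regime of interest (T comfortably above R, tens of
nodes, hundreds of subjects): R = 20 nodes, T = 150 timepoints.

- Null calibration: 200 cohorts, 60 subjects/group; per-node rejection
  at α = 0.05 within 5% ± 2%, and zero consistent nodes after FDR in
  ≥ 95% of cohorts.
- Effect recovery: delta = 0.7 on 4 nodes, 60 subjects/group; all four
  recovered with correct directions in ≥ 80% of 50 replicates.
- Prediction: coupling with noiseless-signal correlation 0.45, which
  yields a measured-composite population correlation near 0.25 (an
  effect size typical of individual-differences neuroimaging) at 300
  subjects; significant against a
  200-permutation null in ≥ 80% of 20 replicates, and non-significant
  under null coupling in ≥ 90%. The replicated tests use 200
  permutations (a reduced-repetition mode); single runs and the
  acceptance script use the full 1000.
- Classification: delta = 0.7, 120 subjects/group; accuracy ≈ 0.8
  against a null upper bound ≈ 0.57, and chance level under label
  shuffling.

## Known limitations

- The MANCOVA F conversion is exact only for the single-df group
  effect; multi-level group factors are out of scope.
- Permutation reshuffles outcomes only; covariate–outcome dependence
  under the null is not preserved (no Freedman–Lane scheme).
- Edge-level CPM (correlating individual connections rather than nodal
  metrics) is not implemented; the CPM variant here screens nodal
  metrics, matching the analysis it validates.
- The generator's target-correlation option conditions on the realized
  cohort, so the coupling is exact for the generated sample rather than
  an asymptotic population value.
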