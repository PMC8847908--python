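# netpheno

Graph-theoretical analysis of resting-state functional connectomes with
covariate-adjusted group screening and permutation-calibrated phenotype
prediction — plus a synthetic-cohort generator with planted ground truth
so that every stage of the pipeline can be validated end to end without
access to human imaging data.

The package is aimed at researchers who start from preprocessed ROI time
series (one T × R matrix per subject, e.g. 90 AAL parcels) and a
phenotype table (group membership, age, sex, head motion, scan site, and
optionally a holistic–analytic thinking score, "AHS"), and who want to
ask: *do nodal network properties differ between groups, do they track
the phenotype, and can they predict it out of sample?*

## The method

For each subject the Pearson correlation matrix of the ROI time series
is computed, negative correlations are zeroed, and the matrix is
binarized over a sparsity sweep 0.10 ≤ S ≤ 0.30 (step 0.01): at sparsity
S the strongest `round(S·R(R−1)/2)` positive pairs become edges, so all
subjects share the same edge count at every threshold. On each binary
graph two nodal metrics are computed:

- degree `K_i` — the number of direct neighbours of node *i*;
- nodal global efficiency
  `E_i_global = (1/(N−1)) Σ_{j≠i} 1/min{L_ij}`,
  the inverse harmonic mean of shortest-path lengths from node *i*
  (unreachable nodes contribute 0).

Each metric's profile over the sweep is summarized by its area under the
curve (AUC, composite trapezoid), giving one degree-AUC and one
efficiency-AUC value per node per subject. Downstream:

1. **Group screening** — per node, a MANCOVA (Pillai's trace) on the
   metric pair and ANCOVAs on each metric, adjusting for age, sex, head
   motion and site; Benjamini–Hochberg FDR across nodes per test family.
   Nodes significant in all three tests are the "consistent" nodes.
2. **Phenotype association** — partial correlation (controlling sex,
   age, motion) of the AHS score with each consistent node's metrics,
   and with the functional connectivity of AHS-associated nodes to every
   other node; FDR within each screen.
3. **Prediction** — significantly associated metrics are sign-unified
   and averaged into two composites (`T_deg`, `T_eg`) that enter
   (a) 10-fold cross-validated linear regression of the AHS score
   (estimate: Pearson r between out-of-fold predictions and
   observations), and (b) 10-fold logistic regression classifying group
   membership (estimate: accuracy at the 0.5 probability cutoff).
   Significance comes from 1000 outcome permutations; the null 95%
   interval is read at the sorted 25th/975th positions. A
   connectome-based predictive modeling (CPM) variant re-screens all
   nodal metrics within every training fold and keeps metrics selected
   in all 10 folds for the cross-sample classifier.

The synthetic-data module generates two-group cohorts from multivariate
Gaussian time series whose covariance carries planted edge effects at
designated nodes, an AHS-like score linearly coupled to noiseless nodal
metrics, and confounded covariates — so type-I error, effect recovery,
and prediction power are all testable against known truth.

## Worked example

```python
import netpheno as nph

net = nph.make_ground_truth(n_nodes=20, density=0.4,
                            effect_nodes={2, 5, 11, 17}, effect_delta=0.7, seed=0)
spec = nph.CohortSpec(n_per_group=100, n_timepoints=150, seed=1,
                      phenotype_weights={(2, "degree_auc"): 1.0,
                                         (5, "efficiency_auc"): 10.0},
                      phenotype_target_r=0.45)
cohort = nph.generate_cohort(spec, net)

deg, eff, labels = nph.compute_cohort_metrics(cohort.timeseries)
screen = nph.screen_nodes(deg, eff, cohort.phenotypes, labels)
print("consistent nodes:", screen.consistent_nodes)

assoc = nph.metric_ahs_screen(deg, eff, labels, cohort.phenotypes,
                              nodes=screen.consistent_nodes)
print("AHS-associated metrics:", assoc.selected)

M = nph.metric_table(deg, eff, labels)
signs = {f"{'deg' if m == 'degree_auc' else 'eff'}:{roi}": s
         for roi, m, s in assoc.selected}
comp = nph.build_composites(
    nph.unify_directions(M, signs),
    [k for k in signs if k.startswith("deg:")],
    [k for k in signs if k.startswith("eff:")], signs)
y = cohort.phenotypes["ahs"].to_numpy()
outcome = nph.calibrated_predict_continuous(comp.X, y, k=10, n_perm=1000, seed=1)
print(f"intrasample r = {outcome.estimate:.3f}, "
      f"null 95% CI = [{outcome.ci95[0]:.3f}, {outcome.ci95[1]:.3f}], "
      f"p_perm = {outcome.p_perm:.4f}")
```

Output:

```
consistent nodes: ['roi001', 'roi002', 'roi004', 'roi005', 'roi006', 'roi008', 'roi011', 'roi016', 'roi017', 'roi018', 'roi019']
AHS-associated metrics: [('roi002', 'degree_auc', 1), ('roi002', 'efficiency_auc', 1), ('roi005', 'degree_auc', 1), ('roi005', 'efficiency_auc', 1), ('roi018', 'degree_auc', -1), ('roi018', 'efficiency_auc', -1)]
intrasample r = 0.311, null 95% CI = [-0.314, 0.114], p_perm = 0.0010
```

The screen flags the four planted effect nodes (2, 5, 11, 17) plus
neighbours whose connectivity shifted with them; both phenotype-coupled
metrics are recovered with their planted signs; and the out-of-fold
prediction (r = 0.31) clearly exceeds the permutation null's upper bound
(0.11), so the composite predictors carry real phenotype information.

A `netpheno` console script exposes the same stages
(`simulate`, `construct`, `metrics`, `screen`, `associate`,
`predict-ahs`, `classify-culture`, `cpm`, `run-all`); see
`netpheno --help`.

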