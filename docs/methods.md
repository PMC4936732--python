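# Methods

## Cohort model and variable schema

The analysis operates on one record per patient with 13 categorical
admission predictors — sex, age band, injury cause, major extracranial
injury (`ec`), the three Glasgow Coma Scale components (`eye`, `motor`,
`verbal`), pupillary reactivity (`pupils`), and five CT findings
(`phm`, `sah`, `oblt`, `mdls`, `hmt`) — plus a binary six-month outcome
whose positive class is death or severe disability. Raw cohorts may
carry the trial's missing-data codes ("no data", "unable to assess",
"scan not done", "alive, disability unknown"); the complete-case filter
excludes any record with a missing code in any predictor or the
outcome, with "alive, disability unknown" counted as a missing outcome.
No imputation is performed anywhere in the package.

Frequency summaries report counts and percentages to two decimals
(half-up), in a three-panel layout (complete cases / incomplete cases /
entire cohort). Note that the published table's printed percentages are
internally inconsistent with its stated denominator by up to ~0.4
percentage points; this package always reports count/denominator.

## Synthetic cohort generator

The generator exists so that every downstream stage can be validated
against a known truth. It has three layers:

**Dependence structure.** A predictor Bayesian network with edges
age → cause → ec (injury mechanism shifts from road traffic accidents
toward falls with age; extracranial injury is most likely after RTA)
and a severity block. Severity is constructed as a 4-level ordinal
latent variable with graded-response CPTs for each assessment and
imaging variable, then collapsed onto the observed motor-response node:
motor's marginal is the latent mixture, and every other severity-linked
variable gets the exact single-parent CPT
P(child | motor) = Σ_s P(child | s) P(s | motor). This keeps all CPTs
single-parent and exactly marginalizable while inducing realistic
positive association among GCS components, pupils and CT findings
(motor–verbal Cramér's V ≈ 0.3 at the defaults). The cost is that the
children are conditionally independent given *motor* rather than given
the latent severity itself — a deliberate simplification.

**Calibration.** Target marginals default to the trial's complete-data
frequency table (category counts normalized within each variable;
e.g. P(male) ≈ 0.8216, poor outcome ≈ 0.3978). In topological order,
each variable's CPT columns are multiplied by per-category factors
(equivalently, additive log-odds shifts) iterated to a fixed point
against the *exactly* computed marginal (variable elimination), to
1e-6 absolute per category. Because parents are calibrated first and a
child's shift does not disturb its ancestors, one pass suffices; the
fixed-point update converges in a handful of sweeps per variable. The
outcome intercept is then solved by Brent root-finding against the
exact poor-outcome rate, computed by enumerating the linear predictor's
distribution within each weakly connected DAG component (≤ 11,520
configurations) and combining components by independence.

**Outcome mechanism.** Poor outcome is Bernoulli(σ(b₀ + Σ_v β_v[x_v])).
Default coefficients are monotone in each GCS component's ordering
(motor spans 2.1 log-odds from "no response" to "follows commands"),
positive for pupil abnormality (up to 1.4), age (up to 1.6 for >55),
extracranial injury (0.55) and the CT mass-effect signs (oblt 0.65,
mdls 0.55, hmt 0.45), small for petechial/subarachnoid blood, and
near-zero for sex and cause. Magnitudes were chosen once to give the
complete 13-predictor model an out-of-sample AUC near 0.83 and a
qualitatively clinical importance ordering (motor/age/pupils dominant);
they live in `generator.DEFAULT_OUTCOME_COEFFICIENTS`.

**Missingness.** MCAR throughout, at the trial's rates: "scan not
done" hits all five imaging variables jointly with probability
2063/10008; among scanned records, imaging "no data" is likewise joint
at 128/7945 (the trial reports 128 scanned patients with findings
missing — independent per-variable rates would roughly triple the
CT-incomplete count); "no data" for cause (143/10008) and ec
(238/10008), unassessable pupils (538/10008) and unknown outcome
(453/10008) are independent per record. Under independence the
expected complete-case retention is ≈ 67.9% — slightly below the
trial's 69.4%, because real missingness overlaps across variables;
`MissingnessConfig.expected_retention()` exposes the configured value.

What the generator does *not* emulate: informative (MNAR) missingness,
continuous covariates, treatment allocation, income-region structure,
higher-order interactions in the outcome mechanism, and conditional
frequencies beyond what the single-parent CPTs encode. Tests passing
on this generator therefore certify the *procedures* (ranking,
selection, inference), not clinical conclusions about real cohorts.

## Logistic models and cross-validation

Predictors are dummy-coded one block per variable with the first listed
category as reference (29 columns for the complete model); age is
categorical, not a linear score. Fits are maximum-likelihood logistic
regression (Newton/IRLS; a singular Hessian, e.g. from collinear
blocks, falls back to L-BFGS, where the likelihood is still well
defined); non-convergence is flagged and selection refuses to proceed
on flagged fits.

Out-of-sample predictions use repeated K-fold cross-validation,
default 5 folds × 6 cycles (both configurable). Each cycle draws a
fresh random partition from a seed sequence `(split_seed, cycle)` that
depends only on the record count — never on the predictor subset — so
any two models share fold memberships exactly (asserted via a fold
hash). ROC inputs pool all (record, cycle) predictions by default;
per-record averaging across cycles is available as an option.
Training-fold indicator columns with zero variance (a category absent
from the fold) are dropped for that fit only. Predicted probabilities
are clipped to (1e-12, 1−1e-12).

Nagelkerke R² = Cox–Snell / (1 − exp(2·ll_null/n)) uses full-data fits
(no CV), mirroring the classical goodness-of-fit ranking; the ROC
rankings use CV predictions. AIC backward elimination drops the block
whose removal most lowers AIC and stops at a local minimum.

## ROC machinery

Curves are empirical, one operating point per distinct threshold with
corner points (sp=0, se=1) and (sp=1, se=0); ties take half credit, so
trapezoidal AUC equals the Mann–Whitney statistic exactly. Partial
areas integrate the piecewise-linear curve over a band with linear
interpolation at band edges; the sensitivity-axis pAUC integrates
specificity with respect to sensitivity (curve transposition), so one
integrator serves both axes, and pAUC over [0,1] equals the AUC
exactly. Standardization is McClish's: ½·(1 + (raw − min)/(max − min))
with min the chance-diagonal area in the band and max the band width;
values below 0.5 indicate below-chance performance.

Model comparisons are paired (identical records and splits):

- **Full AUC** — DeLong's test with midrank placement values; z =
  ΔAUC/√var(Δ) against the normal; p defined as 1 when var(Δ)=0 and
  Δ=0.
- **Partial AUC** — the classical DeLong covariance is not defined for
  partial areas, so pAUC comparisons use a stratified paired bootstrap:
  per-class multinomial record weights (exactly equivalent to
  resampling positives and negatives separately with replacement, and
  immune to single-class resamples by construction), the same weights
  applied to both models, z = observed Δ standardized pAUC / bootstrap
  SD, two-sided normal p. Over the full band this reduces to a
  bootstrap AUC test, which is how its agreement with DeLong is
  checked. Confidence intervals are stratified percentile bootstrap
  (2000 replicates by default).

Every result is labelled with the method that produced it.

## Importance ranking and skeletonization

Drop-one importance: the complete model's pooled CV predictions give
`metric_full`; each leave-one-out model, on identical splits, gives
`metric_without`; `percent_drop = 100·(metric_full −
metric_without)/metric_full`. Negative drops are legitimate (removing
a variable can improve out-of-sample performance — overfitting in the
complete model) and are reported as-is. Ties break alphabetically.

Skeletonization fixes the ranking from the complete model and removes
the lowest-ranked remaining predictor at each step, producing models
1..p−1; each is compared against the complete model (two-sided, paired,
as above). The selected "most simplistic" model is the last with
p ≥ α *before the first significant comparison* (α = 0.05 default);
its retained set is the key predictors. If the very first comparison
is already significant the complete model is selected and flagged
(`selected_index = -1`). On synthetic cohorts the two-sided rule can
stop early by detecting a significant *improvement* from removing noise
predictors; this is reported honestly rather than converted to a
one-sided drop test, and the selected set is then a superset of the
informative predictors.

## Bayesian networks

Structure learning is greedy hill-climbing over add/delete/reverse
single-edge moves, accepting the best strictly improving move
(tolerance 1e-9), scored by decomposable BIC
(Σ_v max-ll(v | parents) − ½·free·ln n); BIC is the standard score of
the hill-climbing literature the analysis draws on, which names only
the search. Whitelist edges (key predictor → outcome in the pipeline;
the published analysis fixes the edge but not its direction — the
orientation is configurable) are present in every candidate and never
deleted or reversed; blacklisted edges are never added. Restart 0
starts from the whitelist-only graph; later restarts add random
whitelist-consistent edges (p = 0.15 each); the best local optimum
wins; everything is deterministic given the seed. Structure recovery
is judged by Markov-equivalence class (skeleton + v-structures), since
score-equivalent DAGs are indistinguishable by BIC.

Parameters are conditional frequencies with an optional uniform
pseudo-count (pipeline default 1.0); never-observed parent
configurations get the uniform distribution and are flagged. Queries
use exact variable elimination (greedy smallest-factor ordering);
zero-probability evidence raises an error naming the assignment.
Categories absent from a cohort remain in the state space with zero
(or smoothed) mass.

## Pipeline and seeds

One master seed fans out to stage seeds via numpy `SeedSequence([master,
stage_index])` folded to 31 bits, so each stage is independently
reproducible and a full run is byte-deterministic. The pipeline writes
the frequency table, four importance tables (Nagelkerke, AUC, pAUC_SP,
pAUC_SE), the AIC trace, both selection traces with a `+`-mark layout
mirroring the published model tables, and the two constrained networks
with CPTs, DOT files and scripted conditional-probability queries
(extracranial injury given cause; cause given age band).

## Validation problem sizes

The test suite validates: generator calibration on a 10,008-record raw
cohort and 50,000–200,000-record samples (3-binomial-SE bands); ROC
integrators against pair-counting and knot-aware grid integration on
100 random score sets (1e-12 / 1e-9); DeLong type-I error on 1000
paired null trials at n=300 and agreement with a 20,000-replicate
bootstrap; planted-signal recovery over 50 cohorts of n=5000 (two
informative predictors among ten, 5-fold CV, one cycle, 200 bootstrap
replicates per comparison); BN chain recovery at n=10,000 against
exhaustive scoring of all 25 three-node DAGs, inference against joint
enumeration on ≤6-node networks, and CPT recovery at n=100,000. These
sizes are the package's validation choices; all are configurable.

## Known limitations

- The paired bootstrap p for pAUC differences assumes approximate
  normality of the bootstrap distribution of Δ; for very small cohorts
  or extreme bands a percentile-interval decision may be preferable.
- Pooling (record, cycle) predictions treats repeated predictions of a
  record as exchangeable observations; DeLong variance on pooled
  predictions is therefore conservative about split noise but ignores
  the record-level duplication. Per-record averaging is available.
- Hill-climbing finds local optima; restarts mitigate but do not
  guarantee global optimality beyond the small networks where the
  exhaustive check applies.
- The complete-case analysis reproduces the trial's own exclusion
  strategy and inherits its selection effects by design.
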