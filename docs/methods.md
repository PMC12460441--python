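# Methods

`woerisk` implements a weight-of-evidence (WoE) risk-scoring pipeline for a
binary clinical outcome — here, musculoskeletal (MSK) injury in the year
after return-to-play from a sports-related concussion — observed together
with a large, heterogeneous, partly missing set of predictors collected at a
pre-injury baseline and three post-injury timepoints (acute, asymptomatic,
return-to-play). This note records the model, the defaults and why they are
set where they are, what the synthetic cohort generator does and does not
emulate, and the numerical and design choices that were genuinely open.

## The model

Let Y ∈ {0, 1} be the outcome and x = [x₁, …, x_P] the predictors. Each
predictor is discretized into bins on the training split, and each bin b of
variable i receives the weight of evidence

    woe_b = ln[ ((n1_b + s)/(N1 + sB)) / ((n0_b + s)/(N0 + sB)) ],

the (Laplace-smoothed, pseudo-count s over B bins) log-ratio of the bin's
share among events to its share among non-events. Positive values are
evidence for the event. Missing values form their own bin and get a WoE like
any other bin — this is the pipeline's entire imputation mechanism, and it
uses the fact that missingness itself can carry outcome information. The
discriminatory power of a binned variable is its information value
IV = Σ_b (p1_b − p0_b)·woe_b ≥ 0.

The risk model is logistic regression on the transformed variables:

    log[P(Y=1|x) / P(Y=0|x)] ≈ w₀ + Σᵢ wᵢ·WoEᵢ(xᵢ),
    P(Y=1|x) = σ(w₀ + Σᵢ wᵢ·WoEᵢ(xᵢ)),  σ(z) = 1/(1+e^{-z}).

If the predictors contributed evidence independently, the WoE decomposition
would be exact with all wᵢ = 1 (the naive-Bayes correspondence); the fitted
weights correct for redundancy and noise. Fitting is three-staged:

1. **L1 path.** Penalized fits of −loglik + λ·Σ|wᵢ| (intercept unpenalized)
   on a log-spaced grid of 100 penalties from λ_max (the analytically
   computed smallest λ at which every coefficient is zero; the fit there is
   the closed-form prevalence-only model) down to 10⁻³·λ_max. The per-λ
   optimizations are scikit-learn saga fits, warm-started along the path;
   statsmodels' independent L1 optimizer reproduces the mid-path
   coefficients to ~10⁻⁴ in the test suite.
2. **Corrected-AIC selection.** Each path point is scored by
   AICc = −2·loglik + 2k + 2k(k+1)/(n−k−1), with loglik the unpenalized
   log-likelihood at the penalized coefficients and k the number of active
   parameters *including the intercept* (it is a fitted parameter). The
   active set of the AICc-minimizing λ is selected; exact ties resolve to
   the sparser model. AICc is undefined for n ≤ k+1; such dense points get
   +∞ and can never be chosen.
3. **L2 refit.** The selected variables are refit under −loglik +
   (α/2)·‖w‖², whose unique optimum tolerates the collinearity that
   correlated timepoints produce (duplicated columns receive equal, finite
   coefficients). Default α = 1/n_train — a deliberately light touch whose
   job is uniqueness, not shrinkage.

A raw-variable benchmark model runs the same three stages on mean-imputed,
one-hot-encoded, standardized original variables (indicator columns are not
standardized; zero-variance columns are dropped with a warning).

**Explanation.** For a linear model the exact Shapley contribution of
variable i to a subject's log-odds is φᵢ = wᵢ·(WoEᵢ(xᵢ) − mean WoEᵢ), with
the mean taken over the training split and stored in the serialized model;
the base value w₀ + Σᵢ wᵢ·mean WoEᵢ plus the contributions reconstructs the
logit exactly (the suite checks ≤ 10⁻¹⁰ per subject). Importance is the
training-set mean of |φᵢ|.

## Binning

Continuous variables are pre-cut at up to 20 empirical quantiles. Cut values
are lower-interpolated order statistics, so the partition depends only on
ranks and is invariant under strictly monotone transforms of the variable
(property-tested). Categorical levels are ordered by training event rate so
that groups of adjacent levels act like ordinal segments. A dynamic program
then merges contiguous pre-bins into at most `max_bins` final bins
maximizing total IV, subject to every bin holding at least
`min_bin_fraction` of training subjects. Because the smoothing couples each
bin's IV term to the total bin count B, terms are additive only at fixed B;
the DP therefore runs once per exact segment count and takes the best
feasible count — this keeps the optimizer exact, and the suite checks it
against brute-force enumeration of every contiguous segmentation on
hundreds of random instances. When the occupancy constraint is
unsatisfiable the variable collapses to a single bin (logged), never an
error.

Defaults, with rationale:

| parameter | default | why |
|---|---|---|
| `max_prebins` | 20 | 5%-quantile resolution for bin edges |
| `max_bins` | 5 (+ missing bin) | scorecard practice; caps overfit bins at small n |
| `min_bin_fraction` | 0.05 | forbids micro-bins whose WoE is noise |
| `smoothing` | 0.5 | keeps every WoE finite for any count table |
| `grid_size`, `lambda_min_ratio` | 100, 10⁻³ | standard path resolution/depth |
| `l2_strength` | 1/n_train | uniqueness under collinearity |
| `test_fraction` | 0.2 | reproduces the 96/59 train and 24/15 test composition of a 194-subject cohort (round-half-up per class) |
| `target_fpr` | 1/15 | one false alarm among 15 non-events, the operating point the evaluation reports by default |

No monotonicity constraint is imposed on WoE across bins: the method is
meant to capture non-monotone risk (e.g., a U-shaped relation between a
timing measure and injury).

Application is total: missing → missing-bin WoE (0 if no missing training
values existed), out-of-range continuous values → nearest edge bin, unseen
categories → 0 (neutral evidence). The split-stability protocol additionally
rejects splits in which a categorical level appears only in the test half,
because no training evidence exists for it.

## Evaluation

ROC and precision-recall curves scan every distinct score as a threshold
with tied scores grouped. AUC is the trapezoidal area, equal to the
Mann-Whitney rank statistic (cross-checked to 10⁻¹⁰, with ties); average
precision is the step-wise sum Σ(R_k − R_{k−1})·P_k. Both are invariant to
monotone transforms of the scores. The operating point under an FPR budget
maximizes TPR subject to fpr ≤ target, ties toward the larger threshold
(fewer false alarms); the best-F1 scan resolves ties toward the lower
threshold (higher recall). Score distributions of the two outcome groups are
compared by a two-sided Mann-Whitney U — exact null when the combined
sample is ≤ 25 and tie-free, tie-corrected normal approximation otherwise.
The test is a package choice; nothing in the methodology pins a particular
two-sample test. Calibration is summarized by an equal-width reliability
table (empty bins reported with count 0).

## The synthetic cohort generator

No real athlete data are distributed, so every claim the tests make is about
cohorts drawn from a generator whose truth is recorded. Outcomes are
Bernoulli draws of σ(intercept + Σ per-variable offsets), where informative
variables contribute piecewise-constant (bin-structured) log-odds offsets —
equal-probability latent slices for continuous variables, per-level offsets
for categorical and binary ones. The per-subject generating log-odds and the
informative set are stored, so the Bayes-optimal AUC is computable and upper-
bounds any fitted model. Continuous variables can share Gaussian-factor
correlation blocks (default within-block correlation 0.6, emulating the
strong correlation between timepoints of the same measure). Missingness is
MCAR by default or MAR-on-outcome (per-group missingness odds differing by a
configurable factor with the pooled rate held at the target). Difference
features (baseline minus later timepoint, missing when either operand is)
are derived exactly as the analysis expects.

The default study-shaped cohort mirrors the emulated study: 194 subjects,
135 predictors (18 measures × 4 timepoints, 54 derived differences, sport
with 10 uneven levels, and 8 demographic/history variables), ten informative
variables, ~35% of cells missing, prevalence ≈ 0.6, and a Bayes AUC ≈ 0.81.
The selection-recovery spec used by the acceptance study is deliberately
cleaner: 40 independent continuous variables, 8 informative with tercile
offsets ±1.0 (odds ratio ≈ 7.4 between extreme terciles), no missingness.

What the generator does **not** emulate: clinically realistic score ranges
for specific instruments, within-subject longitudinal trajectories,
informative missingness tied to timepoints, or inter-sport differences in
assessment distributions. Passing tests therefore demonstrate that the
pipeline recovers bin-structured signal under the stated statistical
conditions — not that any particular clinical dataset would yield a
particular AUC. Notably, at the study's own scale (155 training subjects,
135 candidate variables, 35% missing cells) the fitted model's held-out AUC
on the default synthetic cohort sits well below both the generator's Bayes
ceiling and the performance reported on the real data, which suggests the
real cohort's signal is stronger and more redundant than this simple
emulation.

## Known properties and limitations

- **Supervised-transform likelihood inflation.** Because the WoE transform
  is fitted on the training outcome, every transformed column — informative
  or not — carries in-sample association far exceeding the AICc penalty when
  n is large relative to the per-variable bin count. At n_train = 2000 with
  40 candidates, AICc therefore retains most spuriously binned noise
  variables; the classical "select almost nothing under the null" behaviour
  holds only when labels are permuted against a *fixed* transformed matrix.
  The retained noise variables carry no out-of-sample signal (held-out AUC
  stays at chance under the full-pipeline null) but do cost accuracy: in the
  recovery study the mean held-out AUC sits ≈ 0.055 below the Bayes optimum,
  of which roughly half is WoE bin-edge estimation noise (the gap with the
  oracle variable set is ≈ 0.027) and half is noise-variable contamination.
  At small n (hundreds of subjects, as in the emulated study) AICc's
  complexity term does bind and selection is genuinely sparse.
- **Non-collapsibility.** With several strong independent predictors the
  fitted WoE coefficients exceed 1 (≈ 1.37 at tercile offsets ±1.0), because
  each marginal WoE is flattened by the other variables' variation; the
  naive-Bayes correspondence wᵢ ≈ 1 is recovered in the weak-effect regime
  (≈ 1.1 at ±0.5).
- **Stratified-split rounding.** Per-class test counts are
  round-half-up(test_fraction × class size); with two classes of five at
  fraction 0.5 this yields a six-subject test set, i.e. the overall test
  fraction is only approximately honoured on tiny cohorts.
- **Degenerate inputs.** All-missing variables reduce to a missing-only
  scheme; constant variables to a single bin with zero IV; an empty selected
  set yields the prevalence-only model; one-class evaluation inputs raise.
- **Determinism.** Every stochastic step (generation, splitting, solver)
  is seeded; per-run stability seeds are master + 1000·run + attempt, with
  rejected splits resampled at the incremented attempt and an abort after
  1000 consecutive rejections. Reruns of the workflow with an identical
  configuration produce bit-identical artifacts.

## Problem sizes used by the shipped studies

The acceptance studies run at the sizes their claims name: the confusion and
split arithmetic at the printed 39/194-subject compositions, the binning
oracle on 200 random ≤8-pre-bin instances, SHAP accuracy and the permutation
null at n = 2000, calibration at n = 10000, and the recovery study as 50
replicates of a 4000-subject cohort split evenly into training and test
halves. The repeated-split protocol in the unit suite exercises smaller
cohorts (hundreds of subjects, ≤ 12 variables) so the whole suite stays
fast.
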