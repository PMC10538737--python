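# Methods

## Model and procedure

The package tests conditional feature importance for a binary outcome
Y ∈ {0, 1} with feature vector **X** and risk function
π(**x**) = Pr(Y=1 | **X**=**x**). The importance of feature j is measured
through the per-observation change in Bernoulli log-likelihood when the
validation column j is replaced by a random permutation of itself
(a draw without replacement from its own empirical marginal):

M_ij = Y_i log[π̂(x_i)/π̂(x_i^(j))] + (1−Y_i) log[(1−π̂(x_i))/(1−π̂(x_i^(j)))].

Under conditional independence of X_j and Y given the other features — and
an estimator that has learned that independence — the permuted and
original predictions have the same distribution and E[M_ij] = 0; a
positive mean indicates the estimator's fit genuinely uses X_j. The
procedure is:

1. split the data into a fitting portion and a validation portion
   (stratified 80/20 by default, or K-fold cross-fitting so every
   observation is scored exactly once by an estimator not trained on it);
2. fit π̂ on the fitting portion only;
3. for each clinical feature, draw `n_perm` permutations (default 100) of
   its validation column (all encoded columns of one categorical feature
   move jointly), score every (permutation, observation) pair, and form
   the mean score M̂_j;
4. compute δ = M̂_j / se(M̂_j), a one-sided normal p-value, and declare
   features with p < α (default 0.05) important. No multiplicity
   adjustment is applied by default; Bonferroni/BH are available as a
   flag.

Cross-fitting is essential: scored on the training rows, an overfitted
estimator shows "importance" for every feature it memorized.

## Variance estimator

The mean score is an incomplete U-statistic: each summand M_ij couples
observation i with the donor row whose value it received, and one
permutation couples all validation rows at once. The naive standard error
s/√n_V over permutation-averaged per-observation scores ignores the
positive cross-observation covariance this sharing induces and is
anti-conservative — in a null-calibration simulation (logistic learner,
n = 300, 50 permutations) it yielded a pooled type-I error of ~0.077 at
α = 0.05, with low-prevalence binary features worst affected. The default
estimator (`variance_mode="mean"`) therefore uses the Hájek projection of
the pair kernel: with row means r_i (scores where i is the observation)
and column means c_i (scores where i donated its value),

    g_i = (r_i + c_i)/2,
    se² = 4·Var(g)/n_V + Var(per-permutation means)/n_perm.

The second term is the Monte-Carlo noise from sampling only `n_perm` of
the n_V! permutations and vanishes as `n_perm` grows. With this estimator
the same simulation gives a pooled type-I error of ~0.049. Two
alternatives are kept for comparison: `"simple"` (the naive s/√n_V) and
`"unscaled"` (the per-observation SD itself, i.e. a δ that does not scale
with n_V; a convention some implementations report, far too conservative
as a test of the mean).

Degenerate inputs are handled by convention: a constant (or ignored)
feature produces identically zero scores, se = 0, and p = 1; p-values are
floored at 1e−16 and displayed as "<0.001" below that display threshold;
predicted probabilities are clipped to [1e−6, 1−1e−6] so all log-ratios
are finite.

Known limitation: for a binary feature with only a handful of carriers in
the validation set, the score distribution is a few large spikes among
near-zeros; the normal approximation is then skewed and per-feature
type-I error can deviate in either direction (inflated to ~0.10 at
prevalence ≈ 0.1 with n_V = 60 under the naive SE; conservative to ~0
under the projection SE for prevalence < 0.02). Pooled over a realistic
feature panel the test is well calibrated; for single rare features at
small n_V the p-values should be read with caution. K-fold cross-fitting,
which scores all n observations, is the recommended mitigation and is what
the study-scale runs use.

## Learners

All learners return a `RiskEstimator` (deterministic, clipped
probabilities). The neural-network learner is a feed-forward classifier
(scikit-learn `MLPClassifier`: ReLU, Adam on binary cross-entropy,
minibatches, L2 penalty) with hidden layers 50/40/30/20 by default —
epochs (100), batch size (32), learning rate (1e−3) and L2 (1e−4) are
unstated in the motivating analysis and exposed in `DnnEnsembleConfig`.
Continuous columns are standardized by training-set statistics inside
every learner that needs it; binary/dummy columns pass through.

The **stable ensemble** fits one network per bootstrap resample
(`n_bags`, default 100), scores each by cross-entropy on its own
out-of-bag rows, and retains the networks at or below the ensemble's mean
OOB loss (`keep_rule="below_mean"`; a `top_k:<fraction>` rule is
available). Retention can only lower the retained-set mean OOB loss, and
the filter always keeps at least the best network. OOB scoring was chosen
because it needs no extra hold-out and each network is judged on rows it
never saw; the bag count and exact filter are design choices of this
package, guided only by the "many could be better than all" principle.
Automated tests exercise a reduced configuration (10 bags, 30 epochs,
which this package's stability check shows already halves the refit SD of
test log-loss relative to single networks).

Random forest defaults to 1,000 trees with a small cross-validated grid
(max_features, min_samples_leaf); the SVM (RBF) gets its probabilities
from sigmoid calibration on CV folds, since a margin classifier emits no
probabilities of its own; logistic regression is fitted unpenalized, with
an automatic ridge fallback (and warning) when the design is singular —
common when a very rare feature has no carriers in a training split.
Fitting on a single-class outcome is refused by every learner.

## Synthetic cohorts

`pe_study_spec()` emulates the motivating cohort: 18 independent binary
features at the published prevalences (e.g. PE history 80/758 = 10.55%,
hypertension 64.25%, down to hemoptysis 7/758), a 3-level smoking status
(57.0/35.4/7.7%), and Gaussian age (52.20 ± 16.20), BMI (31.50 ± 9.21)
and heart rate (100.46 ± 19.05). The outcome follows
Y ~ Bernoulli(expit(b₀ + η)) where η contains main effects on PE history
(β = 1.8), chronic prednisone use (0.9) and DVT history (1.2), a
PE-history × prednisone interaction (0.6), and a centered quadratic in
standardized heart rate (0.4), so the risk is a genuinely nonlinear
function of the features. Coefficients are this package's choices, on the
log-odds (binary) / per-SD (continuous) scale, sized so the emulated
study reproduces the qualitative importance pattern of its clinical
counterpart — one dominant history effect plus moderate secondary effects;
prior PE is clinically the strongest known risk factor, hence the largest
coefficient. The intercept b₀ is root-found (Brent) so that a 100,000-draw
probe of E[expit(b₀+η)] hits the target prevalence (default 0.191) within
0.005; with no signal terms it is exactly logit(target).

Every simulated cohort carries its ground truth (`signal_features`), so
type-I error and power are directly measurable. `make_null_cohort()`
zeroes all coefficients; `three_signal_spec()` puts three strong main
effects (two prevalent binaries + age) among 22 features for
power/ranking studies.

What the generator does **not** emulate: feature correlations (Table-style
summaries give only marginals, so features are independent; real
comorbidities co-occur), missing data, measurement error, or any
covariate shift. Passing tests therefore demonstrate the statistical
machinery — calibration, power, selection-then-prediction — under a
faithful marginal structure, not performance on the real cohort, whose
deposited file can be analysed directly via `read_cohort`.

## Simulation sizes and numerical choices

Simulation-backed checks use sizes chosen to make their Monte-Carlo error
small relative to the asserted margins: null calibration pools 22 features
over 500 replicates at n = 300 with 50 permutations (binomial envelopes
are always computed for the replicate count actually used); power/ranking
uses 50 replicates at n = 2000; the selection-then-prediction comparison
averages 5 seeds at the study scale (n = 758, 65-patient test split); the
stability check refits 20 times. Splits are drawn with numpy's PCG64
generator from explicit seeds, per-feature permutation streams are spawned
from a root `SeedSequence` (all derived seeds < 2³¹), and every reported
run writes a manifest (seeds, configs, versions, split indices) from which
it can be replayed bit-identically. Ties in AUC are handled by midranks;
PR-AUC is the step-wise average-precision form; the classification cutoff
applies strictly-greater at 0.5.
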