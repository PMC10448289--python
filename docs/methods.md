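# Methods

This note documents the models, the synthetic-data generator, and the
numerical choices behind `socialrl`, in the spirit of a package methods
appendix: what is computed, under which assumptions, and what a green test
does and does not establish.

## Q-learning model of the selection task

Each of the six faces f carries an expected value Q(f) ∈ [0, 1],
initialized at 0.5 so that the starting point is the indifference point and
values remain interpretable as reward probabilities (outcomes are coded
happy = 1, angry = 0). After a choice c with outcome r, only the chosen
face's value is updated:

    Q(c) ← Q(c) + α · (r − Q(c))

where α = α_reward when the prediction error is positive and α_punish when
negative. A zero prediction error is unreachable for Q strictly inside
(0, 1); at the boundary the convention is α_reward for r = 1 and α_punish
for r = 0 (where the update is zero regardless), which removes the
undefined branch without affecting any likelihood value. Choices follow a
two-option softmax with inverse temperature β ≥ 0; β = 0 is random choice.
The single-rate model is the exact constraint α_reward = α_punish: at any
such parameter point the two models' likelihoods coincide identically,
which the suite asserts.

Test-phase choices are generated from the frozen end-of-training values
(no updating, no feedback) and are never fit; they enter the analysis only
through the accuracy metrics.

## Estimation

**Per-subject MLE** (default path). The negative log-likelihood of one
subject-session's training sequence is minimized by L-BFGS-B on transformed
scales — logit for the learning rates, log for β with a cap (default 20)
that prevents degenerate determinism. One start sits at a plausible center
(α ≈ 0.27, β = 5) and the rest (default 3) are drawn from a seeded RNG, so
fits are deterministic given a seed. A fit is flagged `flat_likelihood`
when it beats a coin-flip model by less than 0.05 nats per trial or lands
at β < 0.2; such parameters are weakly identified and should not be
over-interpreted downstream.

Identifiability caveat: for agents whose generating β is low (noisy
choices), the *global* MLE occasionally sits on an α–β ridge far from the
generating point — this is a property of the likelihood, not of the
optimizer, and is the reason hierarchical estimation exists in this
literature. Recovery studies in the test suite therefore use the
hierarchical fit; the MLE path is validated on median absolute error.

**Hierarchical Bayesian fit.** Per-subject transformed parameters θ_i are
partially pooled through Normal(μ_d, σ_d) group distributions with
weakly-informative hyperpriors μ_d ~ Normal(0, 1) and σ_d ~ HalfNormal(1).
Sampling is Metropolis-within-Gibbs in the centered parameterization:
random-walk proposals per subject (scales adapted toward ~30% acceptance
during warmup), an exact conjugate Gibbs draw for μ (which never touches
the data likelihood), and a random-walk step on log σ with the Jacobian
term included. Defaults are 600 warmup + 400 retained draws × 2 chains;
convergence is summarized by split-R-hat on the group means and a value
above 1.1 is carried as a warning in the result — never silently dropped.
Point estimates are posterior means of the per-subject transformed
parameters; pointwise per-trial log-likelihoods are stored per retained
draw for model comparison.

Both sessions are fit independently per subject; the mixed-model stage
treats session as a repeated measure on the resulting estimates.

## Model comparison

For hierarchical fits, expected log pointwise predictive density is
estimated by Pareto-smoothed importance sampling (PSIS-LOO, via arviz) with
the trial as the pointwise unit, and LOOIC = −2·elpd. For MLE fits, which
carry no draws, the stage reports AIC and labels it as such; the per-model
penalty is constant across observations, so paired pointwise differences —
and hence the SE of a model difference, 2·√(n·Var(Δelpd_i)) — remain
meaningful. Two models are flagged "similar fit" when |ΔLOOIC| is within
that SE. Comparisons are grouped by condition × session, mirroring how the
candidate models are adjudicated per group.

## Behavioral metrics

Test trials are partitioned into *choose-reward* (p80 with an intermediate
face), *avoid-punish* (p20 with an intermediate face), and *excluded* (the
p80–p20 training pair and intermediate-only pairs); with the default
schedule of 15 pairs × 4 repetitions this is 16/16/28 trials per session. A
trial is correct when the face with the higher reward probability was
chosen.

Update weights are per-item ratios w = (post − pre)/(feedback − pre),
averaged per subject within the categories of the chosen scheme. For
poor-performance items the prediction-error sign convention reverses
(feedback *below* the pre-rating is a positive error). Zero-PE items leave
the ratio undefined and are excluded with the reason recorded (~1 in 101
items under the uniform-offset feedback rule). Weights are deliberately not
clipped to [0, 1]: overshooting and counter-updating are exactly what the
outlier screen is meant to catch, not hide. An alternative estimator
(regression of post − pre on feedback − pre through the origin) would
down-weight small-denominator items; the ratio-then-mean default matches
the "one instance of updating per item" reading and keeps the noiseless
round-trip exact.

**Outlier screening.** The weight table is fit by the specified mixed model
(default weight ~ condition × category, random intercept per subject);
each observation's influence is the case-deletion change in the GLS fixed
effects with variance components held at the full-data fit,

    D_i = (β − β_(−i))' (X' V⁻¹ X) (β − β_(−i)) / p,

computed in closed form via the Sherman–Morrison structure of the
random-intercept covariance. Observations with D_i > 4/n are removed in a
single pass. Note that a 4/n threshold flags roughly the |r| > 2 tail of
*any* continuous data (~5% per pass), so screening is not exactly
idempotent; this is inherent to the conventional threshold rather than a
defect. Both the statistic and the threshold are arguments.

## Inference stage

Factors are effects-coded (±1/2; sum-to-zero for >2 levels), so the
intercept is the grand mean and a two-factor interaction coefficient equals
the difference-in-differences it induces. The linear mixed models are REML
fits (statsmodels MixedLM) with the fixed-effect covariance recomputed in
closed form as (X'V⁻¹X)⁻¹ at the estimated variance components — the
Hessian-based covariance degrades when the random-intercept variance sits
near the boundary. Degrees of freedom use a between-within (containment)
assignment: coefficients constant within participants test against
(participants − between-parameters), others against (observations −
participants − within-parameters). Satterthwaite-type df are not available
in the installed stack; for the balanced designs generated here the two
agree to well within rounding.

The trial-level accuracy model is a logistic mixed GLMM fit by variational
Bayes (statsmodels BinomialBayesMixedGLM); fixed effects are reported as
odds ratios with z = posterior mean / posterior sd, the latent residual
variance is the logistic constant π²/3, and extreme estimates (a signature
of complete separation) are carried as warnings.

Estimated marginal means are formed over the factor reference grid with
equal cell weights; pairwise contrasts within a slice are adjusted by the
studentized-range (Tukey) distribution with the family equal to the slice
(a family of one comparison is left unadjusted, and the adjusted p is never
allowed below the unadjusted p). Cohen's d divides a contrast by
√(τ₀₀ + σ²), the total random SD; the convention is stated here because
reported d values depend on it.

## Synthetic cohort generator

The generator emulates the study's stated structure: 51 + 55 subjects in
two arms, two sessions of the selection task, and session-2-only speech
records. Where the source material defers details to an unavailable
supplement, defaults were chosen once at the scale typical of the paradigm
and are configurable:

| parameter | default | rationale |
| --- | --- | --- |
| training trials | 240 (20 per pair per block × 4 blocks) | typical paradigm scale; enough trials for recovery |
| test trials | 60 (15 recombined pairs × 4) | "all possible pairs" with stable proportions |
| true learning rates | logit-Normal(−1.2, 0.5) ≈ 0.23 median | matches the reported group-mean scale (~0.20–0.26) |
| true β | log-Normal(1.6, 0.3) ≈ 5 | mid-range softmax sensitivity |
| pre-ratings | uniform integers 20–80 | keeps feedback/post clipping rare so the noiseless round-trip is exercisable |
| speech noise sd | 6 rating points | implies update-weight residual spread ≈ 0.24 at typical |feedback − pre| ≈ 25, the scale of reported weight-model residuals |
| condition/session shifts | 0 | the null world; non-null scenarios are config-set effect sizes |

The non-null scenario used by the power property sets the
session × condition learning-rate coefficient to −0.04 (difference-in-
differences scale). Per-subject random substreams are spawned from the
master seed, so any subject regenerates in isolation and identical seeds
give byte-identical tables.

`simulate_rate_table` additionally generates learning-rate tables directly
from the mixed-model world (grand mean 0.23, subject SD 0.04, residual SD
0.08, ICC ≈ 0.2) for calibration studies that would be infeasible through
the full simulate-then-fit pipeline.

**What green tests establish — and what they do not.** The generator's
agents are exactly the fitted model (no lapses, no perseveration, no
session carry-over, no reaction times), its speech noise is Gaussian and
item-independent, and feedback offsets are exactly uniform. Recovery and
calibration results on this world validate the estimators and the
inferential machinery; they do not certify the substantive findings of any
real dataset, whose generative process is richer than the model.

## Known limitations

- The hierarchical sampler is a desk-scale Metropolis-within-Gibbs, not
  NUTS; mixing is adequate at cohort sizes used in the tests (R-hat < 1.1)
  but warmup/draws should be increased for production-size cohorts.
- The GLMM route is variational, which can mildly understate posterior
  spread; its z statistics are approximations.
- PSIS-LOO diagnostics (Pareto k) can be large for trials that are highly
  influential under a subject's posterior; they are reported per
  observation rather than suppressed.
- Between-within df are exact only for balanced designs; unbalanced
  real-data tables will show small differences from Satterthwaite-based
  software.
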