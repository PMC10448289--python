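# socialrl

A tested, reusable pipeline for studying **social reinforcement learning** —
how people update expectancies about other people and about their own social
performance from rewarding and punishing social feedback — in the two-task
paradigm used in computational-psychiatry studies of social anxiety and
interpretation-bias training (CBM-I).

The package simulates both behavioral tasks with agents whose parameters are
known, fits the computational models, and runs the full statistical stage,
so that every estimator in the pipeline can be validated by parameter
recovery on synthetic cohorts. It is aimed at researchers who want to
re-analyze trial-level data from this paradigm, or to run design/power
analyses before collecting it.

## The tasks and models

**Social probabilistic selection task.** Six neutral faces carry fixed
reward probabilities: chosen faces become happy with probability 0.8, 0.7,
0.6, 0.4, 0.3, or 0.2 (complementary 80/20, 70/30, 60/40 training pairs),
and angry otherwise. After training, all 15 recombined pairs are presented
without feedback. Training choices are modeled by Q-learning with separate
learning rates for positive and negative prediction errors:

    Q_{t+1}(c) = Q_t(c) + α · δ_t,   δ_t = r_t − Q_t(c),
    α = α_reward if δ_t > 0, else α_punish

with outcomes coded happy = 1 / angry = 0, values initialized at 0.5, and a
softmax (logistic) choice rule with inverse temperature β:

    P(choose a over b) = 1 / (1 + exp(−β (Q(a) − Q(b))))

The nested single-rate model imposes α_reward = α_punish; the two models
are compared per condition and session by LOOIC (−2 × PSIS-LOO elpd) for
hierarchical fits, with a clearly-labeled AIC fallback for point (MLE)
fits. Test-phase behavior is summarized as *choose-reward* and
*avoid-punish* accuracy — the proportion of correct choices in pairs where
the 80% (respectively 20%) face meets an intermediate face.

**Speech expectancies task.** Participants rate 20 statements about an
upcoming speech (10 describing good performance, 10 poor) on a 0–100 scale,
see false feedback (their own rating plus a uniform integer in [−50, 50],
clipped to [0, 100]), and re-rate. Each item yields a single-shot **update
weight**

    w = (post − pre) / (feedback − pre)

aggregated per subject under four schemes (one overall weight, by
prediction-error valence, by item valence, or all four cells), with
influence-based screening of extreme weights (case-deletion Cook's-distance
analogue, threshold 4/n).

**Inference stage.** Linear mixed models on learning rates
(session × condition × PE valence) and update weights (condition ×
valence), a trial-level logistic mixed model on test accuracy, all with a
participant random intercept, effects-coded factors, Tukey-adjusted
pairwise contrasts of estimated marginal means, and Cohen's *d*
standardized by the total random SD.

## Worked example

```sh
socialrl simulate --seed 17 --out-dir run            # 106-subject cohort
socialrl fit-rl --model dual   --trials run/trials.csv --seed 1 --out run/dual.json
socialrl fit-rl --model single --trials run/trials.csv --seed 1 --out run/single.json
socialrl compare-models --fits-a run/dual.json --fits-b run/single.json \
    --design run/design.csv --out run/loo.csv
```

On a 16-subject demo cohort (`cohort: {n_cbmi: 8, n_ema: 8}`) this prints a
comparison table like:

```
condition,session,looic_dual,looic_single,delta_looic,se_delta,preferred,similar_fit,criterion
CBM-I,1,1362.14,1378.25,-16.11,11.16,dual,False,aic
CBM-I,2,1451.70,1466.94,-15.24,11.95,dual,False,aic
EMA-only,1,1543.88,1554.03,-10.15,11.33,dual,True,aic
EMA-only,2,1784.69,1779.33,5.36,9.87,single,True,aic
```

`delta_looic < 0` favors the dual-rate model; `similar_fit` is set when the
difference is within its paired standard error (here the dual model wins
clearly for the CBM-I groups and the models are comparable for EMA-only —
the pattern that motivates keeping the more complex model). Continuing,

```sh
socialrl accuracy --trials run/trials.csv --out run/acc.csv
socialrl speech-weights --speech run/speech.csv --scheme pe_valence \
    --screen-outliers --out run/w.csv
socialrl infer --learning-rates run/dual.json --accuracy run/acc.trials.csv \
    --weights run/w.csv --design run/design.csv --out run/report
```

writes `run/report/report.md` with the four model tables (estimates, CIs,
t(df)/z, p, variance components, ICC, R²) and the Tukey-adjusted contrasts.
Ground-truth parameters for every synthetic subject are kept in
`run/truth.json`, so recovered estimates can be compared against what
generated the data.

The same stages are importable as functions (`socialrl.simulate_study`,
`socialrl.fit_mle`, `socialrl.fit_hierarchical`, `socialrl.loo`,
`socialrl.fit_lmm`, ...); see `docs/methods.md` for the modeling details
and numerical choices.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-simulates the task environment's outcome sampler from scratch (100,000
draws per face pair) and writes the empirical happy-outcome percentages for
the better faces of the two strongest training pairs.
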