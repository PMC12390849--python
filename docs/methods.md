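# Methods

This note documents the models, procedures, numerical choices and known
limitations of the package, in the spirit of a methods appendix.

## Behavioural data model

A *session* is an ordered sequence of trials; each trial records an action
`a_t` (0-based integer), a second-stage state `s_t` (equal to the action in
single-outcome tasks), a reward `r_t` (binary, or 0–100 for the restless
bandit), a validity mask, and — in the original two-stage task only — a
second-stage action. Missing trials keep their position with `mask=False`
and placeholder codes: models carry their state through them unchanged and
losses skip them. Files are plain CSV (`subject, session, trial, action,
state, reward, mask[, action2][, block]`).

For cross-validation, sessions are cut into consecutive blocks of
approximately 150 trials. A trailing fragment shorter than half the target
is merged into the preceding block of the same session; blocks never span
sessions (sessions are independent histories). Blocks are shuffled once
with the given seed and dealt round-robin into folds, balancing temporal
structure across folds.

## Task simulators

The simulators generate the study conditions of well-known published
paradigms:

| task | key parameters |
|---|---|
| reversal (fixed blocks) | p_reward 0.7/0.3, 80-trial blocks, reversal trial uniform in [30, 50] |
| reversal (performance-triggered) | p_reward 0.75/0.25 + neutral 0.5/0.5; switch 10 trials after an exponential moving average (tau = 8 trials) of correct choices crosses 0.75; neutral blocks switch at 10%/trial after trial 15 |
| two-stage (reduced) | transitions 0.8/0.2, p_reward 0.8/0.2, 2%/trial switches after a 10-trial minimum |
| two-stage (performance-triggered) | as above with neutral 0.4/0.4 blocks, 20-trial post-threshold delay, neutral switches 10%/trial after trial 40 |
| transition-reversal two-stage | additionally two transition regimes (0.8/0.2 vs 0.2/0.8); from non-neutral blocks, reward reversal / transition reversal / either neutral block with probability 1/4 each |
| three-armed reversal | contingencies 90/50/10 (then 80/40/20 from trial 80); best arm rotates after 9 of the last 10 best-arm outcomes were rewarded (sliding window) |
| four-armed restless bandit | arm means follow a reflected Gaussian walk on [0, 100], step s.d. 4 (default); the emitted reward is the chosen arm's current mean |
| original two-stage | transitions 0.7/0.3; four second-stage option reward probabilities drift as reflected walks (s.d. 0.025) within [0.25, 0.75] |

All randomness in one simulation flows from a single seeded generator, so
runs are bit-reproducible. The simulators record per-trial block labels and
the currently correct action, which the behavioural metrics consume.

Two literal details are undetermined by the sources and were fixed once:
the restless-bandit schedules are a reflected Gaussian walk rather than the
original deposited schedules (same statistical structure: bounded,
strongly lag-1 autocorrelated), and "9 out of 10 consecutive rewards" is
read as a sliding window over outcomes of choices of the currently best
arm. A step s.d. of 0 is allowed as the degenerate constant walk; negative
values are rejected.

The meta-RL environment wraps the reduced two-stage task in three
within-trial periods (Delay 1, Go, Delay 2) with a fixation requirement:
any non-fixation action during a delay, or fixating at Go, costs −0.1. The
observation is `[state one-hot (S0/S1/S2), fixation/go flag, previous-step
reward, previous-step action one-hot]`. Reward probabilities 0.8/0.2 swap
with probability 0.025 per trial. The closed-form oracle reward rate is
`0.8 * 0.8 + 0.2 * 0.2 = 0.68`; chance is 0.5.

## Cognitive models

Every model is a small discrete dynamical system: named state variables
(values Q, state values V, beliefs, perseveration traces X, transition
estimates), a per-trial update driven by the previous trial's
(action, state, reward), and a softmax policy over actions. Values and
traces start at 0; beliefs and transition estimates at 0.5 (the symmetric
counterpart of the networks' zero initial hidden state). Continuous
rewards are rescaled to [0, 1] before entering update rules so that
learning-rate semantics stay uniform; the scale is absorbed by the inverse
temperature (or reward sensitivity) during fitting.

The catalogue covers: Bayesian latent-state inference with emission
probability `p_emit` (a free parameter in (0.5, 1]; fixing it to the task's
true value gives the ideal-observer variant) and per-trial switch
probability `p_r`; anticorrelated (d = 1) and independent (d = n)
model-free learners, with value forgetting to zero or to the 1/2 midpoint;
the drift-to-the-other rule; single- and multi-trial perseveration;
reward-as-cue learning over (previous state × previous reward) augmented
states (d = 8); Q(0)-style two-stage backup (d = 4); model-based learners
with anticorrelated, independent, or forgetting state values and a known
transition matrix; the model-free/model-based mixture; the compositional
family for the transition-reversal task (state values, TD(λ) action
values, a learned transition model updated toward 1/0 for the chosen
action and relaxed toward 0.5 for the unchosen, motor-level values indexed
by (action, pre-previous state), choice and motor-level perseveration,
bias and rotation-bias terms — the full model has 13 dynamical variables);
utility and reference-point models for the three- and four-armed human
tasks; and seven variants for the original two-stage task (anticorrelated
and independent model-free, transition-weighted max model-based, mixtures,
and the reward-utility variant with motor-twin updates at the unvisited
second-stage state).

Two printed conventions coexist and are both kept: the reversal-task
forgetting rules multiply by the retention factor `D`, whereas the
transition-reversal components specify forgetting *rates* `f_Q`, `f_T`
(implemented as `x <- (1 - f_Q) x` and relaxation toward 0.5). The
Bayesian policy applies the inverse temperature to the beliefs themselves
(softmax of `beta * Pr(h)`), as printed, not to their log-odds; the two
parameterizations differ only in how `beta` rescales the logit, and the
printed form keeps the fitted `beta` comparable across models.

Implementations are vectorized across sessions; a test transcribes every
model's equations into slow scalar code and requires agreement of the
policy traces to 1e-10 over 1000 random trials.

## Tiny recurrent networks

Three architectures over d hidden units: the vanilla GRU (sigmoid gates,
tanh candidate, convex update) driven by the numeric input vector
(previous action, state, reward); the switching GRU, where recurrent
weights and biases are selected by the discrete input condition (4
conditions for single-outcome tasks, 8 when the second-stage state is
informative); and switching linear networks `h' = W^(x) h + b^(x)`,
optionally with symmetric `W`. The initial hidden state is 0 and the first
trial's policy is read from it before any input. Readouts are linear with
*no bias* — scores are a function of the hidden state alone, so the logit
is a well-defined state coordinate for the portrait analyses — followed by
softmax over two (or n) output units. A vanilla GRU maps exactly onto a
switching GRU by folding each condition's input projection into per-code
biases; this equivalence is tested to 1e-10.

Defaults follow the reporting convention: d = 1 models default to the
switching GRU, d ≥ 2 to the vanilla GRU. Weights are initialized uniformly
at scale 1/sqrt(d); the initialization seed is a hyperparameter (three
seeds by default).

Because no automatic-differentiation library is part of the dependency
set, the package includes a compact reverse-mode engine
(`tinyrnn.autodiff`): a tape of numpy arrays with exact gradients
(verified against central differences) and an Adam optimizer. Training
runs full-batch backpropagation through time over all blocks
(~150-trial sequences), which is fast at these model sizes.

## Fitting and model comparison

The objective is the trial-averaged negative log-likelihood of next-action
prediction; for the original two-stage task both stages contribute.
Probabilities are floored at 1e-12 (with a warning) for numerical safety.

Cognitive models are optimized with L-BFGS on smoothly reparameterized
parameters — logistic for [0, 1] rates, a scaled logistic for (0.5, 1]
emission probabilities, softplus for nonnegative inverse temperatures,
identity for unbounded utilities — with 3 random restarts (the restart
seed is the model's only hyperparameter). Networks are trained with Adam
(learning rate 0.005), an L1 penalty on recurrent weights (grid 1e-5 …
1e-1), and early stopping when the validation NLL has not improved for 200
epochs ("iteration steps" is read as epochs: with full-batch training the
two coincide); the best-validation checkpoint is returned.

Nested cross-validation: blocks are dealt into 10 folds; each fold serves
once as the unseen test set; within the remaining nine, each fold serves
once as validation while the other eight train, for every hyperparameter
combination; the model with the best trial-weighted NLL on the held-in
(train + validation) trials is selected and scored once on the test fold.
The aggregate is the trial-weighted mean over test folds. Inner-loop
selection weighting is by trials (the literal reading of "average
performance on the training and validation datasets"). Information-criterion
comparison (AIC/BIC) is deliberately out of scope.

For single-block human data the interspersed protocol samples disjoint
train/validation/test trial-index sets (e.g. 120/20/20 of 160 trials)
without replacement; the whole sequence is always fed as input and only
the losses are restricted to the index sets.

Behavioural dimensionality d* is the largest d whose model significantly
outperforms all smaller models (paired one-sided t-tests of per-fold NLLs
at 0.05, no multiple-testing correction) — equivalently, the smallest d
that beats all smaller models while no larger model also does; if nothing
beats the simplest model, d* is the smallest d examined.

## Knowledge distillation

The teacher is a 20-unit GRU whose input is extended by a subject-embedding
vector (a trainable linear map of the subject's one-hot code; the embedding
width is selected on the target subject's validation data). The M/O split
follows the published discipline: 25% of the target subject M's blocks are
held out as M-test; the rest split 90/10 into M-training/M-validation;
every other subject's blocks split 90/10 (O-training/O-validation). The
teacher trains on M+O-training with early stopping on M+O-validation and
never sees M-test (asserted).

Students are tiny networks trained to minimize the cross-entropy between
the teacher's and the student's next-trial action probabilities (no
temperature), on M-training data augmented fourfold by the task's
symmetry — flipping action codes, state codes, or both; rewards and block
structure unchanged. Teacher targets for an augmented copy are the
teacher's own policies on that (flipped) input sequence. Students are
selected by the distillation loss on M-validation and evaluated on M-test
against actual choices. Augmentation applies to two-action, two-state
tasks with probabilistic transitions; tasks without the symmetry are
rejected.

Teachers are trained on raw (unaugmented) data so that real asymmetries —
e.g. a side bias — remain learnable. The precise representational claim,
which the test suite checks, is functional: a teacher trained on augmented
data implements an action-mirror-symmetric policy (mirrored input
sequences yield mirrored outputs, asymmetry ≈ 0.01), while a raw-data
teacher on biased data breaks that symmetry (≈ 0.9). Note a symmetric
policy can still *express* a side preference on asymmetric histories (by
majority-following), so marginal choice probabilities do not separate the
two — function symmetry does.

A cross-subject (zero-shot) protocol is also provided: subjects are dealt
into six folds; students for held-out subjects are trained on
action-augmented blocks purely against teacher policies, validated and
tested on the original block.

## Dynamical-systems interpretation

For one-dimensional models the state coordinate is the logit
`L(t) = log Pr(A1)/Pr(A2)` (for softmax policies, the score difference).
Per input condition I, the phase portrait shows `dL = L(t+1) - L(t)`
against `L`, both for the trials actually visited and for a swept grid of
the scalar state (512 points over the 0.5–99.5 percentile range of
observed states — beyond that range the portrait is extrapolation). Fixed
points are located by sign-change bracketing plus bisection to
|dL| < 1e-8 and labelled by the discrete-map criterion: stable iff
`-2 < g'(L*) < 0`, with `g'` from central differences. Preference
setpoints iterate one input's map from the median observed state (any
start in the basin gives the same limit) until |dL| < 1e-8 (cap 10^4
iterations; non-convergent conditions are flagged with their drift sign)
and are normalized by the largest magnitude, so `max_I |u_I| = 1` whenever
any fixed point is nonzero. The effective learning rate is the secant
slope `alpha(L) = -g(L)/(L - L*)`, equal to `-g'(L*)` at the fixed point;
the identity `alpha(L) = -g'(L) - alpha'(L)(L - L*)` is verified
numerically.

For two-variable models with diagonal readouts, the one-step change is
evaluated on a 2-D grid per condition, with attractors found by iterating
to convergence. Dynamical regression fits, separately per input
condition, ordinary least squares of each coordinate's one-step change on
all current coordinates (plus the continuous reward, where applicable),
assembling the slopes into the input-dependent state-transition matrix
**A**; rank-deficient designs (or fewer than d + 2 pairs) are flagged
rather than estimated. On noiseless model-free generators the regression
recovers the update rule exactly, because those models *are* per-condition
affine maps.

## Meta-RL agent

The agent is a 48-unit LSTM with a softmax actor over {A1, A2, Fixate} and
a scalar critic, trained by advantage actor-critic: policy-gradient loss
with bootstrapped discounted returns (discount 0.9 per period), value
regression (weight 0.5), and entropy regularization annealed linearly from
0.05 to 0.003 over the first 60% of training — the high initial entropy
prevents premature collapse onto a penalty-incurring habit, the low final
value allows exploitation. Optimization is Adam (2e-3) with global
gradient-norm clipping at 1.0, over 16 parallel environments and 8-trial
(24-step) truncated unrolls with the recurrent state carried across
updates. The default budget is 600,000 trials (a few minutes on one CPU);
at that budget agents earn ≈ 0.59–0.63 rewards per trial across seeds,
between chance (0.5) and the oracle (0.68). Evaluation can sample or act
greedily and exports per-trial behaviour (choice at Go, second-stage
state, outcome, and the Go-time logit) in the standard session format for
downstream fitting and portrait analysis.

## What the synthetic data does and does not show

The generators reproduce the tasks' *structural* statistics (transition
and reward probabilities, block-switch rules, drift autocorrelation) and
the agents are exact implementations of the cognitive models, so
recovery tests demonstrate that the estimation and interpretation
machinery is correct: parameters, predictive ceilings, dimensionality and
update rules are recovered because the data really were generated by the
assumed class. Real behavioural data contain ingredients the synthetic
population lacks — lapses, slow drifts in motivation, individual
differences outside the fitted family, finite and irregular session
structure — so passing these tests bounds estimation error, not model
misspecification on real subjects. The deposited datasets of the emulated
experiments can be converted to the session CSV (one row per trial with
the columns above) and run through the identical pipeline.

## Problem sizes used in the validation suite

Chosen as the package's standard desk-scale configuration: simulator
checks at 1e5 trials (3-binomial-s.e. tolerances); oracle-equivalence at
1e3 trials per model; cognitive parameter recovery at 1e4 trials;
network-vs-generator recovery at 2e4 trials (d = 1 switching GRU, within
0.01 nats of the generator held out); dimensionality recovery at 1e4
trials with 5 rotating train/validation/test folds and one hyperparameter
set per d (the full nested loop is exercised separately on cheap models);
distillation benefit on 20 synthetic subjects × 400 trials with 10
student/solo seed pairs; meta-RL training at the 600k-trial default
budget.

## Known limitations

- Cognitive-model gradients are finite-difference (L-BFGS); exact for the
  small parameter counts involved but not suited to hundreds of
  parameters.
- The dimensionality estimator inherits the caveats of its definition:
  limited data or very slow latent variables can underestimate d*, and
  strongly nonlinear dynamics can require more embedding dimensions than
  the generative process has.
- Phase portraits require a genuinely one-dimensional model; for larger
  models the package offers per-condition linearizations and 2-D fields,
  not a full nonlinear reduction. Symbolic regression of the learned
  update rules is out of scope (the drift-to-the-other rule it would
  discover is included as an explicit cognitive model instead).
- The meta-RL training loop is a minimal A2C; it reaches clearly
  above-chance, below-oracle performance at the default budget but is not
  tuned to the asymptotic performance a long GPU run would give. A
  consequence: whether the agent's behaviour is better captured by the
  Bayesian inference model than by the model-based learner depends on how
  far training has progressed. Stronger agents (≈0.63 reward/trial) show
  the Bayesian signature clearly (held-out NLL 0.14 vs 0.18 in one run);
  weaker ones (≈0.59) can still be better fit by the value-based model,
  so that comparison is reported by the tooling rather than guaranteed.
- Readers' deposited datasets are supported through the generic session
  CSV only; no loaders for their native layouts are included.
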