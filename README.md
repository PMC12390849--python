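# tinyrnn

Tiny recurrent neural networks and classical cognitive models for
trial-by-trial choice behaviour.

## The problem

In reward-learning experiments — reversal learning, two-stage ("two-step")
bandits, restless bandits — a subject makes one choice per trial and
receives probabilistic feedback. Cognitive modelling asks which learning
rule generated the choice sequence. The classical approach fits hand-written
models (model-free and model-based reinforcement learning, Bayesian
inference, perseveration variants) by maximum likelihood and compares them
out of sample. This package implements that workflow *and* its flexible
counterpart: very small gated recurrent networks (1–20 units) whose hidden
units play the role of the cognitive models' dynamical variables. Because
the networks are tiny, a fitted network can be read as a discrete dynamical
system and compared, variable for variable, with the classical models.

It is intended for computational cognitive scientists who have (or
simulate) trial-by-trial choice data and want to (1) measure how much
behavioural structure their hand-written models miss, (2) estimate how many
dynamical variables the behaviour actually uses, and (3) extract the
learning rule a fitted network implements.

## What is inside

- **Task simulators** (`tinyrnn.task_envs`) for six paradigms: two-action
  reversal learning (fixed-block and performance-triggered variants), the
  reduced two-stage task, the transition-reversal two-stage task,
  three-armed reversal learning, the four-armed restless bandit
  (continuous rewards), and the original two-stage task with two choice
  stages — plus a three-period (Delay 1 / Go / Delay 2) meta-RL wrapper of
  the two-stage task.
- **A catalogue of ~45 classical cognitive models** (`tinyrnn.cognitive`):
  Bayesian latent-state inference; model-free learners with anticorrelated,
  independent, forgetting, forgetting-to-mean, drift-to-the-other and
  reward-as-cue value updates; perseveration variants; model-based learners
  with known or learned transitions; compositional models for the
  transition-reversal task (up to 13 dynamical variables); utility and
  reference-point models for the human tasks. Each model is a per-trial
  state update `x_t -> x_{t+1}` plus a softmax policy.
- **Tiny recurrent choice models** (`tinyrnn.rnn`): vanilla GRU,
  *switching* GRU (one set of recurrent weights and biases per discrete
  input condition), and switching linear networks, with full or diagonal
  bias-free linear readouts. A vanilla GRU can be transformed exactly into
  an equivalent switching GRU.
- **Fitting** (`tinyrnn.fitting`): trial-averaged negative log-likelihood
  `-sum_t log Pr(a_t | past observations)`, smooth reparameterization so all
  models share gradient machinery, Adam with L1 on recurrent weights and
  early stopping for networks, nested cross-validation over ~150-trial
  blocks, the interspersed split protocol for single-block human data, and
  a statistical estimator of the behavioural dimensionality d*.
- **Knowledge distillation** (`tinyrnn.distillation`): a 20-unit teacher
  with learned subject embeddings trained on pooled data; tiny per-subject
  students trained to match the teacher's output probabilities on
  symmetry-augmented data.
- **Interpretation** (`tinyrnn.interpretation`): logits
  `L = log Pr(A1)/Pr(A2)`, phase portraits (dL vs L per input condition),
  fixed points with the discrete-map stability criterion
  `-2 < g'(L*) < 0`, normalized preference setpoints
  `u_I = L*_I / max_I |L*_I|`, effective learning rates
  `alpha(L) = -g(L)/(L - L*)`, two-dimensional vector fields, and
  dynamical regression (per-condition linearization into a state-transition
  matrix **A**).
- **Behaviour metrics** (`tinyrnn.behaviour`): stay probabilities by
  transition and reward type, reversal-aligned choice curves, and a
  behaviour-feature identifier (a small recurrent classifier that validates
  a discovered strategy against an alternative on simulated data).
- **Meta-RL** (`tinyrnn.metarl`): an LSTM actor-critic agent trained with
  advantage actor-critic on the three-period two-stage environment, whose
  behaviour can be exported and analysed like any subject's.

All network training runs on a small reverse-mode automatic-differentiation
engine included in the package (`tinyrnn.autodiff`); everything is
float64 numpy and fully seed-deterministic.

## Worked example

Simulate a rat-style two-stage session from an anticorrelated model-free
learner, refit the model, and read its phase portrait:

```python
import numpy as np
import tinyrnn as tr
from tinyrnn.cognitive import CognitiveAgent, make_model
from tinyrnn.fitting import FitConfig, fit_cognitive, _nll_per_trial
from tinyrnn.interpretation import phase_portrait
from tinyrnn.task_data import segment_blocks

cfg = tr.task_envs.two_stage_miller()          # p_reward 0.8/0.2, 2%/trial switches
agent = CognitiveAgent(make_model("mf1"), {"alpha": 0.5, "beta": 3.0})
data = tr.simulate_task(cfg, agent, 5000, seed=1)

part = segment_blocks(data, target_len=150, n_folds=10, seed=0)
train = part.extract(data, [b for b in part.blocks if b.fold != 0])
test = part.extract(data, part.fold_blocks(0))

fit, _ = fit_cognitive(make_model("mf1"), train, FitConfig(n_restarts=2), seed=0)
print(fit.params["alpha"], fit.params["beta"])   # 0.495, 3.012
print(_nll_per_trial(fit, test))                 # 0.2533

por = phase_portrait(fit, cfg, data)
L, dL = por.curves[(0, 0, 1.0)]                  # input: chose A1, reached S1, rewarded
print(np.polyfit(L, dL, 1)[0])                   # -0.495  (slope = -alpha)
```

The recovered learning rate (0.495) and inverse temperature (3.012) match
the generating values (0.5, 3.0); the held-out NLL of 0.2533 nats/trial is
the generator's own predictability on this data. The phase-portrait slope
under any input condition equals `-alpha` — the signature of a constant
learning rate — and the rewarded conditions pull the logit toward fixed
points at `±2*beta`.

Stay probabilities show the model-free signature (stay after reward
regardless of transition type):

```
common rewarded    0.986      rare rewarded    0.971
common unrewarded  0.737      rare unrewarded  0.811
```

A command-line interface wraps the same operations
(`tinyrnn simulate|fit|distill|interpret|metarl-train|metarl-eval`; see
`tinyrnn --help`).

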