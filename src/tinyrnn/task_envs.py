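"""Generative simulators for the behavioural tasks.

Six task families are covered, mirroring the structure of published
reward-learning experiments:

* ``reversal`` — two-action probabilistic reversal learning.  Action ``A_i``
  deterministically leads to state ``S_i`` where reward is delivered.  Two
  parameterizations are provided: fixed 80-trial blocks with a reversal
  trial drawn uniformly within a window (monkey-style), and performance
  triggered switches via an exponential moving average of correct choices
  with neutral blocks (mouse-style).
* ``two_stage`` — a first-stage action leads probabilistically (common 0.8 /
  rare 0.2) to one of two reward-bearing second-stage states.
* ``transition_reversal`` — two-stage task whose action-state transition
  probabilities also reverse in blocks.
* ``three_armed`` — three-armed reversal learning with a
  9-out-of-10-consecutive-rewards switch rule and a mid-task contingency
  change.
* ``four_armed`` — restless four-armed bandit with continuous rewards
  (0-100) drifting as a reflected Gaussian random walk.
* ``original_two_stage`` — two choice stages; second-stage option reward
  probabilities drift within [0.25, 0.75].

A meta-RL environment wraps the two-stage task into three within-trial
periods (Delay 1, Go, Delay 2) with fixation requirements.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .task_data import Session, SessionData

__all__ = [
    "TaskConfig",
    "EnvState",
    "simulate_task",
    "drifting_bandit_walk",
    "analytic_baselines",
    "MetaRLEnv",
    "metarl_env_step",
    "RandomAgent",
    "FixedAgent",
    "reversal_bartolo",
    "reversal_akam",
    "two_stage_miller",
    "two_stage_akam",
    "transition_reversal_akam",
    "three_armed_reversal",
    "four_armed_bandit",
    "original_two_stage",
    "metarl_two_stage",
]


class ConfigurationError(ValueError):
    pass


class ContractError(ValueError):
    """An agent violated the simulation contract (e.g. wrong policy arity)."""


@dataclass
class TaskConfig:
    """Task parameters; probabilities are validated on construction.

    ``reward_types`` lists the reward probability per state for each block
    type; ``neutral_types`` marks which of those are neutral.
    ``transition_types`` lists (n_actions, n_states) transition tables (one
    entry unless transitions themselves reverse).
    """

    task_id: str
    n_actions: int
    n_states: int
    reward_range: tuple[float, float] = (0.0, 1.0)
    reward_types: list[tuple[float, ...]] | None = None
    neutral_types: tuple[int, ...] = ()
    transition_types: list[list[list[float]]] | None = None
    # block-switch rule: 'prob', 'ema', 'fixed_reversal', 'consecutive', 'none'
    switch_rule: str = "none"
    switch_prob: float = 0.02
    min_block_len: int = 10
    ema_tau: float = 8.0
    ema_threshold: float = 0.75
    post_threshold_delay: int = 10
    neutral_switch_prob: float = 0.10
    neutral_min_len: int = 15
    block_len: int = 80
    reversal_range: tuple[int, int] = (30, 50)
    consecutive_window: int = 10
    consecutive_needed: int = 9
    stage_shift_trial: int | None = None
    reward_types_stage2: list[tuple[float, ...]] | None = None
    drift_sd: float = 4.0
    drift_bounds: tuple[float, float] = (0.0, 100.0)
    prob_drift_sd: float = 0.025
    prob_bounds: tuple[float, float] = (0.25, 0.75)
    n_trials: int = 1000
    continuous_reward: bool = False
    two_choice_stages: bool = False

    def __post_init__(self) -> None:
        for types in (self.reward_types, self.reward_types_stage2):
            if types is not None:
                for probs in types:
                    if any(not (0.0 <= p <= 1.0) for p in probs):
                        raise ConfigurationError(f"reward probability outside [0,1]: {probs}")
        if self.transition_types is not None:
            for table in self.transition_types:
                arr = np.asarray(table, dtype=float)
                if arr.shape != (self.n_actions, self.n_states):
                    raise ConfigurationError("transition table shape mismatch")
                if np.any(arr < 0) or not np.allclose(arr.sum(axis=1), 1.0):
                    raise ConfigurationError("transition table rows must sum to 1")

    def transition(self, regime: int = 0) -> np.ndarray:
        if self.transition_types is None:
            # actions map deterministically onto states (single-outcome task)
            return np.eye(self.n_actions, self.n_states)
        return np.asarray(self.transition_types[regime], dtype=float)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TaskConfig":
        with open(path) as fh:
            raw = json.load(fh)
        for key in ("reward_range", "neutral_types", "reversal_range", "drift_bounds",
                    "prob_bounds"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if raw.get("reward_types") is not None:
            raw["reward_types"] = [tuple(t) for t in raw["reward_types"]]
        if raw.get("reward_types_stage2") is not None:
            raw["reward_types_stage2"] = [tuple(t) for t in raw["reward_types_stage2"]]
        return cls(**raw)


# ---------------------------------------------------------------------------
# Standard configurations (the study conditions of the emulated experiments)


def reversal_bartolo() -> TaskConfig:
    return TaskConfig(
        task_id="reversal", n_actions=2, n_states=2,
        reward_types=[(0.7, 0.3), (0.3, 0.7)],
        switch_rule="fixed_reversal", block_len=80, reversal_range=(30, 50),
        n_trials=1000,
    )


def reversal_akam() -> TaskConfig:
    return TaskConfig(
        task_id="reversal", n_actions=2, n_states=2,
        reward_types=[(0.75, 0.25), (0.25, 0.75), (0.5, 0.5)],
        neutral_types=(2,),
        switch_rule="ema", ema_tau=8.0, ema_threshold=0.75,
        post_threshold_delay=10, neutral_switch_prob=0.10, neutral_min_len=15,
        n_trials=1000,
    )


def two_stage_miller() -> TaskConfig:
    return TaskConfig(
        task_id="two_stage", n_actions=2, n_states=2,
        reward_types=[(0.8, 0.2), (0.2, 0.8)],
        transition_types=[[[0.8, 0.2], [0.2, 0.8]]],
        switch_rule="prob", switch_prob=0.02, min_block_len=10,
        n_trials=1000,
    )


def two_stage_akam() -> TaskConfig:
    return TaskConfig(
        task_id="two_stage", n_actions=2, n_states=2,
        reward_types=[(0.8, 0.2), (0.2, 0.8), (0.4, 0.4)],
        neutral_types=(2,),
        transition_types=[[[0.8, 0.2], [0.2, 0.8]]],
        switch_rule="ema", ema_tau=8.0, ema_threshold=0.75,
        post_threshold_delay=20, neutral_switch_prob=0.10, neutral_min_len=40,
        n_trials=1000,
    )


def transition_reversal_akam() -> TaskConfig:
    return TaskConfig(
        task_id="transition_reversal", n_actions=2, n_states=2,
        reward_types=[(0.8, 0.2), (0.2, 0.8), (0.4, 0.4)],
        neutral_types=(2,),
        transition_types=[[[0.8, 0.2], [0.2, 0.8]], [[0.2, 0.8], [0.8, 0.2]]],
        switch_rule="ema", ema_tau=8.0, ema_threshold=0.75,
        post_threshold_delay=20, neutral_switch_prob=0.10, neutral_min_len=40,
        n_trials=1000,
    )


def three_armed_reversal() -> TaskConfig:
    return TaskConfig(
        task_id="three_armed", n_actions=3, n_states=3,
        reward_types=[(0.9, 0.5, 0.1), (0.1, 0.9, 0.5), (0.5, 0.1, 0.9)],
        reward_types_stage2=[(0.8, 0.4, 0.2), (0.2, 0.8, 0.4), (0.4, 0.2, 0.8)],
        stage_shift_trial=80,
        switch_rule="consecutive", consecutive_window=10, consecutive_needed=9,
        n_trials=160,
    )


def four_armed_bandit() -> TaskConfig:
    return TaskConfig(
        task_id="four_armed", n_actions=4, n_states=4,
        reward_range=(0.0, 100.0), continuous_reward=True,
        drift_sd=4.0, drift_bounds=(0.0, 100.0),
        switch_rule="none", n_trials=150,
    )


def original_two_stage() -> TaskConfig:
    return TaskConfig(
        task_id="original_two_stage", n_actions=2, n_states=2,
        transition_types=[[[0.7, 0.3], [0.3, 0.7]]],
        prob_drift_sd=0.025, prob_bounds=(0.25, 0.75),
        switch_rule="none", two_choice_stages=True, n_trials=200,
    )


TASK_REGISTRY = {}


def _register(fn):
    TASK_REGISTRY[fn.__name__] = fn
    return fn


for _fn in (reversal_bartolo, reversal_akam, two_stage_miller, two_stage_akam,
            transition_reversal_akam, three_armed_reversal, four_armed_bandit,
            original_two_stage):
    _register(_fn)


@_register
def metarl_two_stage() -> TaskConfig:
    return TaskConfig(
        task_id="two_stage", n_actions=2, n_states=2,
        reward_types=[(0.8, 0.2), (0.2, 0.8)],
        transition_types=[[[0.8, 0.2], [0.2, 0.8]]],
        switch_rule="prob", switch_prob=0.025, min_block_len=0,
        n_trials=1000,
    )


# ---------------------------------------------------------------------------
# Built-in agents


class RandomAgent:
    """Uniform random policy (optionally with given probabilities)."""

    def __init__(self, n_actions: int, probs=None):
        self.probs = np.full(n_actions, 1.0 / n_actions) if probs is None else np.asarray(probs)

    def reset(self) -> None:
        pass

    def policy(self) -> np.ndarray:
        return self.probs

    def policy2(self, state: int) -> np.ndarray:  # second-stage choice, if any
        return self.probs

    def update(self, action, state, reward, action2=None) -> None:
        pass


class FixedAgent(RandomAgent):
    """Always take one action (probability 1)."""

    def __init__(self, n_actions: int, action: int):
        probs = np.zeros(n_actions)
        probs[action] = 1.0
        super().__init__(n_actions, probs)


# ---------------------------------------------------------------------------
# Environment state and block-switch machinery


@dataclass
class EnvState:
    """Latent state of the simulated environment."""

    block_type: int = 0
    regime: int = 0                 # transition regime (transition-reversal task)
    ema: float = 0.0                # exponential moving average of correct choices
    trials_in_block: int = 0
    countdown: int = -1             # trials until a scheduled (EMA-triggered) switch
    block_counter: int = 0
    reversal_trial: int = -1        # within-block reversal (fixed_reversal rule)
    arm_means: np.ndarray | None = None
    stage2_probs: np.ndarray | None = None
    recent_best_outcomes: list = field(default_factory=list)
    contingency_stage: int = 0


def _reward_probs(config: TaskConfig, env: EnvState) -> np.ndarray:
    types = config.reward_types
    if env.contingency_stage == 1 and config.reward_types_stage2 is not None:
        types = config.reward_types_stage2
    return np.asarray(types[env.block_type], dtype=float)


def _correct_action(config: TaskConfig, env: EnvState) -> int:
    probs = _reward_probs(config, env)
    expected = config.transition(env.regime) @ probs
    return int(np.argmax(expected))


def _nonneutral_types(config: TaskConfig) -> list[int]:
    return [i for i in range(len(config.reward_types)) if i not in config.neutral_types]


def _switch_block(config: TaskConfig, env: EnvState, rng: np.random.Generator) -> None:
    """Apply one block transition according to the task's rules."""
    nonneutral = _nonneutral_types(config)
    if config.task_id == "transition_reversal" and env.block_type not in config.neutral_types:
        # equal probability: reward reversal, transition reversal, or one of
        # the two neutral blocks (neutral reward under either regime)
        move = rng.integers(4)
        if move == 0:
            env.block_type = [t for t in nonneutral if t != env.block_type][0]
        elif move == 1:
            env.regime = 1 - env.regime
        else:
            env.block_type = config.neutral_types[0]
            if move == 3:
                env.regime = 1 - env.regime
    elif env.block_type in config.neutral_types:
        env.block_type = int(rng.choice(nonneutral))
    elif config.neutral_types and config.switch_rule == "ema":
        # from non-neutral: equal probability to the other non-neutral or neutral
        others = [t for t in nonneutral if t != env.block_type] + list(config.neutral_types)
        env.block_type = int(rng.choice(others))
    else:
        choices = [t for t in nonneutral if t != env.block_type]
        env.block_type = int(rng.choice(choices))
    env.trials_in_block = 0
    env.countdown = -1
    env.ema = 0.0
    env.block_counter += 1
    env.recent_best_outcomes = []


def _update_blocks(config: TaskConfig, env: EnvState, action: int, reward: float,
                   t: int, rng: np.random.Generator) -> None:
    env.trials_in_block += 1
    if config.stage_shift_trial is not None and t + 1 == config.stage_shift_trial:
        env.contingency_stage = 1
    rule = config.switch_rule
    if rule == "none":
        return
    if rule == "prob":
        if env.trials_in_block >= config.min_block_len and rng.random() < config.switch_prob:
            _switch_block(config, env, rng)
    elif rule == "fixed_reversal":
        if env.reversal_trial < 0:
            env.reversal_trial = int(rng.integers(config.reversal_range[0],
                                                  config.reversal_range[1] + 1))
        if env.trials_in_block == env.reversal_trial:
            _switch_block(config, env, rng)
            env.reversal_trial = -1
        elif env.trials_in_block >= config.block_len:
            env.trials_in_block = 0  # new 80-trial block; same contingency until reversal
    elif rule == "ema":
        if env.block_type in config.neutral_types:
            if (env.trials_in_block > config.neutral_min_len
                    and rng.random() < config.neutral_switch_prob):
                _switch_block(config, env, rng)
        else:
            correct = float(action == _correct_action(config, env))
            env.ema += (correct - env.ema) / config.ema_tau
            if env.countdown < 0 and env.ema >= config.ema_threshold:
                env.countdown = config.post_threshold_delay
            if env.countdown >= 0:
                env.countdown -= 1
                if env.countdown == 0:
                    _switch_block(config, env, rng)
    elif rule == "consecutive":
        best = _correct_action(config, env)
        if action == best:
            env.recent_best_outcomes.append(float(reward > 0))
            window = env.recent_best_outcomes[-config.consecutive_window:]
            env.recent_best_outcomes = window
            if (len(window) == config.consecutive_window
                    and sum(window) >= config.consecutive_needed):
                _switch_block(config, env, rng)
    else:  # pragma: no cover
        raise ConfigurationError(f"unknown switch rule {rule!r}")


# ---------------------------------------------------------------------------
# Drifting-bandit reward schedule


def drifting_bandit_walk(config: TaskConfig, n_trials: int, seed: int) -> np.ndarray:
    """Per-trial mean reward for each arm of the restless bandit.

    A Gaussian random walk with step s.d. ``config.drift_sd``, reflected at
    the configured bounds, giving temporally autocorrelated trajectories.
    Returns an array of shape ``(n_trials, n_actions)``.
    """
    if config.drift_sd < 0:
        raise ConfigurationError("drift step scale must be non-negative")
    lo, hi = config.drift_bounds
    rng = np.random.default_rng(seed)
    means = np.empty((n_trials, config.n_actions))
    x = rng.uniform(lo, hi, size=config.n_actions)
    for t in range(n_trials):
        means[t] = x
        x = x + rng.normal(0.0, config.drift_sd, size=config.n_actions) if config.drift_sd > 0 else x
        # reflect into [lo, hi]
        x = np.where(x < lo, 2 * lo - x, x)
        x = np.where(x > hi, 2 * hi - x, x)
        x = np.clip(x, lo, hi)  # guards pathological double reflections
    return means


def _prob_walk(config: TaskConfig, n_trials: int, rng: np.random.Generator) -> np.ndarray:
    """Drifting second-stage option reward probabilities (original two-stage)."""
    lo, hi = config.prob_bounds
    probs = np.empty((n_trials, 4))  # options B1, B2, C1, C2
    x = rng.uniform(lo, hi, size=4)
    for t in range(n_trials):
        probs[t] = x
        x = x + rng.normal(0.0, config.prob_drift_sd, size=4)
        x = np.where(x < lo, 2 * lo - x, x)
        x = np.where(x > hi, 2 * hi - x, x)
        x = np.clip(x, lo, hi)
    return probs


# ---------------------------------------------------------------------------
# Trial-level simulation


def _draw(rng: np.random.Generator, probs: np.ndarray) -> int:
    return int(rng.choice(len(probs), p=probs))


def simulate_task(config: TaskConfig, agent, n_trials: int, seed: int,
                  subject_id: str = "sim", session_id: str = "s0") -> SessionData:
    """Simulate one session of ``n_trials`` trials under ``config``.

    The agent must expose ``reset()``, ``policy() -> (n_actions,) probability
    vector``, and ``update(action, state, reward, action2=None)``; tasks with
    a second choice stage additionally require ``policy2(state)``.  All
    randomness flows from one generator seeded with ``seed``, so repeated
    calls are bit-reproducible.
    """
    rng = np.random.default_rng(seed)
    env = EnvState()
    if config.reward_types is not None:
        env.block_type = int(rng.choice(_nonneutral_types(config)))
    if config.task_id == "four_armed":
        env.arm_means = drifting_bandit_walk(config, n_trials,
                                             int(rng.integers(2 ** 31)))
    if config.task_id == "original_two_stage":
        env.stage2_probs = _prob_walk(config, n_trials, rng)

    agent.reset()
    actions = np.empty(n_trials, dtype=int)
    states = np.empty(n_trials, dtype=int)
    rewards = np.empty(n_trials, dtype=float)
    blocks = np.empty(n_trials, dtype=int)
    correct = np.empty(n_trials, dtype=int)
    btype = np.empty(n_trials, dtype=int)
    tin = np.empty(n_trials, dtype=int)
    actions2 = np.empty(n_trials, dtype=int) if config.two_choice_stages else None

    for t in range(n_trials):
        correct[t] = _correct_action(config, env) if config.reward_types is not None else -1
        btype[t] = env.block_type
        tin[t] = env.trials_in_block
        probs = np.asarray(agent.policy(), dtype=float)
        if probs.shape != (config.n_actions,):
            raise ContractError(
                f"agent returned policy of arity {probs.shape}, expected ({config.n_actions},)")
        a = _draw(rng, probs)
        s = _draw(rng, config.transition(env.regime)[a])
        a2 = None
        if config.task_id == "four_armed":
            r = float(env.arm_means[t, a])
        elif config.task_id == "original_two_stage":
            probs2 = np.asarray(agent.policy2(s), dtype=float)
            if probs2.shape != (2,):
                raise ContractError("second-stage policy must have arity 2")
            a2 = _draw(rng, probs2)
            r = float(rng.random() < env.stage2_probs[t, 2 * s + a2])
        else:
            p = _reward_probs(config, env)
            r = float(rng.random() < p[s])
        actions[t], states[t], rewards[t], blocks[t] = a, s, r, env.block_counter
        if actions2 is not None:
            actions2[t] = a2
        agent.update(a, s, r, a2)
        _update_blocks(config, env, a, r, t, rng)

    mask = np.ones(n_trials, dtype=bool)
    session = Session(session_id, actions, states, rewards, mask, actions2, blocks,
                      extras={"correct_action": correct, "block_type": btype,
                              "trials_in_block": tin})
    return SessionData(subject_id, [session])


# ---------------------------------------------------------------------------
# Analytic baselines


def analytic_baselines(config: TaskConfig) -> tuple[float, float]:
    """Closed-form oracle and chance per-trial reward rates for a
    binary-reward two-stage configuration.

    ``oracle = p_common * p_high + (1 - p_common) * p_low`` (always take the
    action commonly leading to the currently-rewarding state); ``chance`` is
    the mean expected reward over actions.
    """
    if config.continuous_reward or config.reward_types is None:
        raise ConfigurationError("analytic baselines require a binary-reward task")
    trans = config.transition()
    probs = np.asarray(config.reward_types[0], dtype=float)
    expected = trans @ probs                      # expected reward per action
    oracle = float(np.max(expected))
    chance = float(np.mean(expected))
    return oracle, chance


# ---------------------------------------------------------------------------
# Meta-RL environment (three periods per trial)

DELAY1, GO, DELAY2 = 0, 1, 2
A1, A2, FIXATE = 0, 1, 2
PERIOD_NAMES = ("Delay1", "Go", "Delay2")


class MetaRLEnv:
    """Two-stage task wrapped in a three-period trial structure.

    Periods run Delay 1 -> Go -> Delay 2.  The observation is a vector of
    ``[state one-hot (S0/S1/S2), fixation/go scalar, previous reward,
    previous one-hot action (A1/A2/F)]``.  Choosing ``A1``/``A2`` outside Go,
    or fixating at Go, incurs a -0.1 penalty.  Second-stage reward
    probabilities are 0.8/0.2 and switch with probability 0.025 per trial.
    """

    OBS_DIM = 8
    N_ACTIONS = 3

    def __init__(self, config: TaskConfig | None = None, seed: int = 0):
        self.config = config or metarl_two_stage()
        self.rng = np.random.default_rng(seed)
        self.reset()

    @property
    def good_state(self) -> int:
        """State currently carrying the high reward probability."""
        return int(np.argmax(self.config.reward_types[self.block_type]))

    def _obs(self, state: int, fixation: float, prev_reward: float,
             prev_action: int | None) -> np.ndarray:
        obs = np.zeros(self.OBS_DIM)
        obs[state] = 1.0          # 0 = S0 (choice state), 1/2 = S1/S2
        obs[3] = fixation         # 1 = fixation required, 0 = go
        obs[4] = prev_reward
        if prev_action is not None:
            obs[5 + prev_action] = 1.0
        return obs

    def reset(self) -> np.ndarray:
        self.block_type = int(self.rng.integers(2))
        self.period = DELAY1
        self.second_state = 0
        self.trial_reward = 0.0
        return self._obs(0, 1.0, 0.0, None)

    def step(self, action: int):
        """Advance one period. Returns ``(observation, reward, trial_done, info)``.

        The returned observation is for the *next* period and carries this
        step's reward and one-hot action as the previous-time-step signals.
        """
        if action not in (A1, A2, FIXATE):
            raise ContractError(f"invalid action {action}")
        reward = 0.0
        info: dict = {}
        if self.period == DELAY1:
            if action != FIXATE:
                reward = -0.1
            self.period = GO
            obs = self._obs(0, 0.0, reward, action)
            done = False
        elif self.period == GO:
            if action == FIXATE:
                reward = -0.1
                # no choice made: stay at the choice state, no outcome
                self.second_state = 0
                self.trial_reward = 0.0
            else:
                trans = self.config.transition()[action]
                self.second_state = 1 + _draw(self.rng, trans)
                p = self.config.reward_types[self.block_type][self.second_state - 1]
                self.trial_reward = float(self.rng.random() < p)
            self.period = DELAY2
            obs = self._obs(self.second_state, 1.0, reward, action)
            done = False
        else:  # DELAY2: the second-stage reward is delivered here
            if action != FIXATE:
                reward = -0.1
            reward += self.trial_reward
            info["trial_reward"] = self.trial_reward
            info["second_state"] = self.second_state
            if self.rng.random() < self.config.switch_prob:
                self.block_type = 1 - self.block_type
            self.period = DELAY1
            obs = self._obs(0, 1.0, reward, action)
            done = True
        return obs, reward, done, info


def metarl_env_step(env: MetaRLEnv, action: int):
    """Functional wrapper over :meth:`MetaRLEnv.step`."""
    return env.step(action)
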