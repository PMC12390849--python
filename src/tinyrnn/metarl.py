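"""Task-optimized meta-reinforcement-learning agents.

A recurrent agent (LSTM core, 48 units by default) is trained with
advantage actor-critic (A2C) on the three-period two-stage environment:
the actor head emits a policy over {A1, A2, Fixate}, the critic head a
scalar state-value baseline.  Training uses the policy-gradient loss with
the advantage (bootstrapped discounted return minus baseline), a value
regression loss, and entropy regularization, over short truncated unrolls
of parallel environments.

The trained agent's trial-by-trial behaviour can be exported as session
data and handed to the fitting and interpretation modules like any other
subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .task_data import Session, SessionData
from .task_envs import A1, A2, FIXATE, GO, MetaRLEnv, TaskConfig, metarl_two_stage

__all__ = [
    "AgentSpec",
    "A2CAgent",
    "train_a2c",
    "evaluate_agent",
    "OraclePolicy",
    "UniformPolicy",
]


@dataclass
class AgentSpec:
    """A2C agent architecture and training hyperparameters."""

    core_size: int = 48
    n_actions: int = 3
    obs_dim: int = MetaRLEnv.OBS_DIM
    discount: float = 0.9
    policy_weight: float = 1.0
    value_weight: float = 0.5
    entropy_weight: float = 0.05      # annealed linearly to entropy_final
    entropy_final: float = 0.003
    anneal_fraction: float = 0.6      # fraction of training over which to anneal
    grad_clip: float = 1.0            # global gradient-norm clip (0 disables)
    learning_rate: float = 2e-3
    n_envs: int = 16
    unroll_trials: int = 8          # trials (3 steps each) per update

    def __post_init__(self) -> None:
        if not (0.0 <= self.discount <= 1.0):
            raise ValueError("discount must lie in [0, 1]")
        if min(self.policy_weight, self.value_weight, self.entropy_weight) < 0:
            raise ValueError("loss weights must be non-negative")


def _init_agent_params(spec: AgentSpec, rng: np.random.Generator) -> dict:
    d, n_in = spec.core_size, spec.obs_dim
    scale = 1.0 / np.sqrt(d)
    def u(*shape):
        return rng.uniform(-scale, scale, size=shape)
    return {
        "Wi": u(n_in, 4 * d), "Wh": u(d, 4 * d), "b": np.zeros(4 * d),
        "Wp": u(d, spec.n_actions), "bp": np.zeros(spec.n_actions),
        "Wv": u(d, 1), "bv": np.zeros(1),
    }


def _lstm_step_np(params: dict, h: np.ndarray, c: np.ndarray, x: np.ndarray):
    d = h.shape[1]
    z = x @ params["Wi"] + h @ params["Wh"] + params["b"]
    def sig(v):
        return 1.0 / (1.0 + np.exp(-v))
    i, f, g, o = (z[:, :d], z[:, d:2 * d], z[:, 2 * d:3 * d], z[:, 3 * d:])
    c_new = sig(f) * c + sig(i) * np.tanh(g)
    h_new = sig(o) * np.tanh(c_new)
    return h_new, c_new


def _lstm_step_ad(params: dict, h: Tensor, c: Tensor, x: Tensor, d: int):
    z = x @ params["Wi"] + h @ params["Wh"] + params["b"]
    i = ad.sigmoid(z[:, :d])
    f = ad.sigmoid(z[:, d:2 * d])
    g = ad.tanh(z[:, 2 * d:3 * d])
    o = ad.sigmoid(z[:, 3 * d:])
    c_new = f * c + i * g
    h_new = o * ad.tanh(c_new)
    return h_new, c_new


class A2CAgent:
    """LSTM actor-critic agent bound to numpy parameters."""

    def __init__(self, spec: AgentSpec, params: dict[str, np.ndarray]):
        self.spec = spec
        self.params = params

    @classmethod
    def create(cls, spec: AgentSpec, seed: int = 0) -> "A2CAgent":
        return cls(spec, _init_agent_params(spec, np.random.default_rng(seed)))

    def initial_state(self, batch: int):
        d = self.spec.core_size
        return np.zeros((batch, d)), np.zeros((batch, d))

    def policy_value(self, h: np.ndarray):
        logits = h @ self.params["Wp"] + self.params["bp"]
        z = logits - logits.max(axis=-1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=-1, keepdims=True)
        v = (h @ self.params["Wv"] + self.params["bv"])[:, 0]
        return p, v, logits

    def step(self, state, obs: np.ndarray):
        h, c = _lstm_step_np(self.params, state[0], state[1], obs)
        return (h, c)


def train_a2c(spec: AgentSpec, env_config: TaskConfig | None = None,
              n_trials: int = 600_000, seed: int = 0
              ) -> tuple[A2CAgent, dict]:
    """Train an A2C agent on the meta-RL two-stage environment.

    ``n_trials`` is the total training budget summed over the parallel
    environments.  Returns the trained agent and a learning curve of mean
    reward per trial (one point per ~1000 trials).  Deterministic given
    ``seed``.
    """
    env_config = env_config or metarl_two_stage()
    rng = np.random.default_rng(seed)
    B = spec.n_envs
    envs = [MetaRLEnv(env_config, seed=int(rng.integers(2 ** 31))) for _ in range(B)]
    obs = np.stack([e.reset() for e in envs])
    params = {k: Tensor(v, requires_grad=True)
              for k, v in _init_agent_params(spec, rng).items()}
    opt = Adam(params, lr=spec.learning_rate)
    d = spec.core_size
    h_np = np.zeros((B, d))
    c_np = np.zeros((B, d))

    n_updates = max(1, n_trials // (B * spec.unroll_trials))
    steps_per_unroll = 3 * spec.unroll_trials
    curve = []
    reward_acc, trial_acc = 0.0, 0
    curve_every = max(1, 1000 // (B * spec.unroll_trials))

    for update in range(n_updates):
        h = Tensor(h_np.copy())
        c = Tensor(c_np.copy())
        logps, entropies, values, rewards, act_hot = [], [], [], [], []
        for _ in range(steps_per_unroll):
            h, c = _lstm_step_ad(params, h, c, Tensor(obs), d)
            logits = h @ params["Wp"] + params["bp"]
            logp = ad.log_softmax(logits)
            p = np.exp(logp.data)
            v = (h @ params["Wv"] + params["bv"])[:, 0]
            acts = np.array([rng.choice(spec.n_actions, p=p[i]) for i in range(B)])
            hot = np.zeros((B, spec.n_actions))
            hot[np.arange(B), acts] = 1.0
            step_r = np.empty(B)
            new_obs = np.empty_like(obs)
            for i, env in enumerate(envs):
                o, r, done, _ = env.step(int(acts[i]))
                new_obs[i] = o
                step_r[i] = r
            obs = new_obs
            logps.append(logp)
            # entropy must differentiate through the probabilities too
            entropies.append(-(logp.exp() * logp).sum(axis=-1))
            values.append(v)
            rewards.append(step_r)
            act_hot.append(hot)
        # bootstrapped discounted returns
        with_boot, _ = _lstm_step_np({k: t.data for k, t in params.items()},
                                     h.data, c.data, obs)
        v_boot = (with_boot @ params["Wv"].data + params["bv"].data)[:, 0]
        R = v_boot
        returns = np.empty((steps_per_unroll, B))
        for t in reversed(range(steps_per_unroll)):
            R = rewards[t] + spec.discount * R
            returns[t] = R
        policy_loss = Tensor(0.0)
        value_loss = Tensor(0.0)
        entropy_term = Tensor(0.0)
        n_terms = steps_per_unroll * B
        for t in range(steps_per_unroll):
            adv = returns[t] - values[t].data          # advantage, no gradient
            chosen_logp = (logps[t] * act_hot[t]).sum(axis=-1)
            policy_loss = policy_loss + (chosen_logp * (-adv)).sum()
            diff = values[t] - returns[t]
            value_loss = value_loss + (diff * diff).sum()
            entropy_term = entropy_term + entropies[t].sum()
        # anneal entropy pressure, then hold at the final value
        frac = min(1.0, update / max(spec.anneal_fraction * (n_updates - 1), 1))
        ent_w = spec.entropy_weight + frac * (spec.entropy_final - spec.entropy_weight)
        loss = (spec.policy_weight * policy_loss
                + spec.value_weight * value_loss
                - ent_w * entropy_term) * (1.0 / n_terms)
        if not np.isfinite(loss.data):
            raise FloatingPointError(f"non-finite A2C loss at update {update}")
        opt.zero_grad()
        loss.backward()
        if spec.grad_clip > 0:
            norm = np.sqrt(sum(float((t.grad ** 2).sum())
                               for t in params.values() if t.grad is not None))
            if norm > spec.grad_clip:
                scale = spec.grad_clip / norm
                for t in params.values():
                    if t.grad is not None:
                        t.grad *= scale
        opt.step()
        h_np, c_np = h.data, c.data                    # truncated BPTT boundary

        reward_acc += float(np.sum(rewards))
        trial_acc += B * spec.unroll_trials
        if (update + 1) % curve_every == 0:
            curve.append(reward_acc / trial_acc)
            reward_acc, trial_acc = 0.0, 0

    agent = A2CAgent(spec, {k: t.data for k, t in params.items()})
    return agent, {"curve": curve, "n_trials": n_updates * B * spec.unroll_trials}


# ---------------------------------------------------------------------------
# Baseline policies and evaluation


class OraclePolicy:
    """Cheating baseline: fixates in delays and, at Go, takes the action
    whose common transition leads to the currently high-reward state."""

    def act(self, env: MetaRLEnv, obs) -> int:
        if env.period != GO:
            return FIXATE
        trans = env.config.transition()
        return A1 if trans[A1, env.good_state] >= trans[A2, env.good_state] else A2


class UniformPolicy:
    """Fixates in delays, chooses uniformly between A1/A2 at Go."""

    def __init__(self, seed: int = 0):
        self.rng = np.random.default_rng(seed)

    def act(self, env: MetaRLEnv, obs) -> int:
        return FIXATE if env.period != GO else int(self.rng.integers(2))


def evaluate_agent(agent, env_config: TaskConfig | None = None,
                   n_trials: int = 10_000, seed: int = 0, sample: bool = True
                   ) -> tuple[float, SessionData, dict]:
    """Run an agent (trained or baseline) and report mean reward per trial.

    Returns ``(mean_reward, session_data, extras)`` where the session data
    holds one row per trial (action at Go, arrived second-stage state,
    trial outcome; trials where the agent fixated at Go are masked out) and
    ``extras`` carries the per-trial Go logits log Pr(A1)/Pr(A2), ready for
    the interpretation module.
    """
    env_config = env_config or metarl_two_stage()
    env = MetaRLEnv(env_config, seed=seed)
    rng = np.random.default_rng(seed + 1)
    obs = env.reset()
    is_net = isinstance(agent, A2CAgent)
    if is_net:
        state = agent.initial_state(1)
    total = 0.0
    actions = np.zeros(n_trials, dtype=int)
    states = np.zeros(n_trials, dtype=int)
    rewards = np.zeros(n_trials, dtype=float)
    mask = np.zeros(n_trials, dtype=bool)
    logits = np.full(n_trials, np.nan)
    for trial in range(n_trials):
        for _ in range(3):
            at_go = env.period == GO
            if is_net:
                state = agent.step(state, obs[None, :])
                p, v, raw = agent.policy_value(state[0])
                p = p[0]
                if at_go:
                    logits[trial] = raw[0, A1] - raw[0, A2]
                if sample:
                    a = int(rng.choice(agent.spec.n_actions, p=p))
                else:
                    a = int(np.argmax(p))
            else:
                a = agent.act(env, obs)
            obs, r, done, info = env.step(a)
            total += r
            if at_go and a in (A1, A2):
                actions[trial] = a
                mask[trial] = True
            if done:
                states[trial] = max(info["second_state"] - 1, 0)
                rewards[trial] = info["trial_reward"]
    session = Session("metarl", actions, states, rewards, mask,
                      extras={"go_logit": logits})
    data = SessionData("agent", [session])
    return total / n_trials, data, {"go_logits": logits}
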