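"""Standard behavioural summaries and the behaviour-feature identifier.

Stay probabilities (probability of repeating the previous action,
stratified by transition type and reward outcome) are the classical
diagnostic separating model-free from model-based control in two-stage
tasks; reversal-aligned choice curves show adaptation speed around block
switches.  The behaviour-feature identifier is a model-agnostic validation
tool: a small recurrent classifier trained to discriminate behavioural
sequences simulated from two model classes, which can then score empirical
sequences for the presence of the discovered strategy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .rnn import RNNSpec, encode_vector
from .task_data import Session, SessionData
from .task_envs import TaskConfig, simulate_task

__all__ = [
    "stay_probability",
    "reversal_curve",
    "feature_identifier",
    "IdentifierResult",
]


def stay_probability(data: SessionData, task_config: TaskConfig) -> pd.DataFrame:
    """Stay probability per trial type.

    Trial types are {common, rare} x {rewarded, unrewarded} for tasks with
    probabilistic transitions, else {rewarded, unrewarded}.  Transitions
    across session boundaries are never counted.  Types with no trials get
    NaN (absent), not 0.
    """
    has_transitions = task_config.transition_types is not None
    trans = task_config.transition()
    types = ([(c, r) for c in ("common", "rare") for r in ("rewarded", "unrewarded")]
             if has_transitions else [(r,) for r in ("rewarded", "unrewarded")])
    counts: dict[tuple, list[int]] = {key: [0, 0] for key in types}  # [stays, total]
    for sess in data.sessions:
        for t in range(sess.n_trials - 1):
            if not (sess.mask[t] and sess.mask[t + 1]):
                continue
            rew = "rewarded" if sess.reward[t] > 0.5 else "unrewarded"
            if has_transitions:
                common = trans[sess.action[t], sess.state[t]] >= 0.5
                key = ("common" if common else "rare", rew)
            else:
                key = (rew,)
            counts[key][1] += 1
            counts[key][0] += int(sess.action[t + 1] == sess.action[t])
    rows = []
    for key, (stays, total) in counts.items():
        rows.append({
            **{f"type{i}": k for i, k in enumerate(key)},
            "stay_prob": stays / total if total else np.nan,
            "n": total,
        })
    df = pd.DataFrame(rows)
    names = [c for c in df.columns if c.startswith("type")]
    return df.set_index(names)


def reversal_curve(data: SessionData, window: int = 10,
                   correct_actions: list[np.ndarray] | None = None
                   ) -> pd.DataFrame:
    """Choice accuracy aligned to block reversals.

    For each lag in [-window, window) relative to a block switch (lag 0 is
    the first trial of the new block), the fraction of trials on which the
    currently high-reward action was chosen, averaged over blocks.
    ``correct_actions`` (one array per session) overrides the simulator's
    recorded ground truth.  Windows extending beyond a block are truncated.
    """
    rows = []
    for i, sess in enumerate(data.sessions):
        if correct_actions is not None:
            correct = np.asarray(correct_actions[i])
        elif sess.extras is not None and "correct_action" in sess.extras:
            correct = sess.extras["correct_action"]
        else:
            raise ValueError("no correct-action information for reversal_curve; "
                             "pass correct_actions")
        if sess.block is None:
            raise ValueError("reversal_curve requires block labels")
        switches = np.flatnonzero(np.diff(sess.block) != 0) + 1
        for sw in switches:
            for lag in range(-window, window):
                t = sw + lag
                if t < 0 or t >= sess.n_trials or not sess.mask[t]:
                    continue
                rows.append({"lag": lag,
                             "correct": int(sess.action[t] == correct[t])})
    if not rows:
        return pd.DataFrame(columns=["lag", "p_correct", "sem", "n"]).set_index("lag")
    df = pd.DataFrame(rows)
    out = df.groupby("lag")["correct"].agg(["mean", "sem", "count"])
    out.columns = ["p_correct", "sem", "n"]
    return out


# ---------------------------------------------------------------------------
# Behaviour-feature identifier


def _encode_batch(sessions: list[Session], spec: RNNSpec) -> np.ndarray:
    T = max(s.n_trials for s in sessions)
    X = np.zeros((T, len(sessions), 3))
    for i, s in enumerate(sessions):
        X[: s.n_trials, i] = encode_vector(s.action, s.state, s.reward, spec)
    return X


def _forward_np(params: dict, X: np.ndarray) -> np.ndarray:
    """Pr(positive class) for a batch of encoded sequences."""
    T, B, _ = X.shape
    d = params["Whr"].shape[0]
    h = np.zeros((B, d))
    def sig(v):
        return 1.0 / (1.0 + np.exp(-v))
    for t in range(T):
        x = X[t]
        r = sig(x @ params["Wir"] + params["bir"] + h @ params["Whr"] + params["bhr"])
        z = sig(x @ params["Wiz"] + params["biz"] + h @ params["Whz"] + params["bhz"])
        n = np.tanh(x @ params["Win"] + params["bin"]
                    + r * (h @ params["Whn"] + params["bhn"]))
        h = (1 - z) * n + z * h
    logits = h @ params["Wout"] + params["bout"]
    z = logits - logits.max(axis=-1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=-1, keepdims=True)
    return p[:, 1]


@dataclass
class IdentifierResult:
    accuracy: float                 # held-out accuracy
    scores_pos: np.ndarray          # per held-out sequence: Pr(positive class)
    scores_neg: np.ndarray
    params: dict                    # trained encoder + head parameters
    spec: RNNSpec | None = None

    def score_sequences(self, sessions: list[Session]) -> np.ndarray:
        """Pr(positive class) for new behavioural sequences (e.g. data)."""
        return _forward_np(self.params, _encode_batch(sessions, self.spec))


def feature_identifier(positive_agent_factory, negative_agent_factory,
                       task_config: TaskConfig, n_sequences: int = 100,
                       seq_len: int = 200, seed: int = 0, d: int = 8,
                       epochs: int = 150, lr: float = 0.01,
                       test_fraction: float = 0.25) -> IdentifierResult:
    """Train a recurrent classifier to discriminate behaviour simulated
    from two model classes under identical task settings.

    The factories take a seed and return simulation agents; ``n_sequences``
    sequences of ``seq_len`` trials are simulated per class (balanced).  A
    GRU encoder (``d`` units) reads each sequence and a softmax head
    classifies it.  Returns held-out accuracy and per-sequence class
    scores; accuracy near 0.5 on identical classes indicates
    non-identifiability (and guards against information leakage).
    """
    rng = np.random.default_rng(seed)
    spec = RNNSpec(architecture="gru", d=max(d, 2), encoding="vector",
                   n_actions=task_config.n_actions,
                   continuous_reward=task_config.continuous_reward)
    sessions, labels = [], []
    for _ in range(n_sequences):
        for label, factory in ((1, positive_agent_factory),
                               (0, negative_agent_factory)):
            sim_seed = int(rng.integers(2 ** 31))
            data = simulate_task(task_config, factory(sim_seed), seq_len,
                                 seed=sim_seed)
            sessions.append(data.sessions[0])
            labels.append(label)
    labels = np.array(labels)
    order = rng.permutation(len(sessions))
    n_test = int(round(test_fraction * len(sessions)))
    test_idx, train_idx = order[:n_test], order[n_test:]

    X = _encode_batch(sessions, spec)
    scale = 1.0 / np.sqrt(d)
    def u(*shape):
        return rng.uniform(-scale, scale, size=shape)
    params_np = {}
    for g in ("r", "z", "n"):
        params_np[f"Wi{g}"] = u(3, d)
        params_np[f"Wh{g}"] = u(d, d)
        params_np[f"bi{g}"] = u(d)
        params_np[f"bh{g}"] = u(d)
    params_np["Wout"] = u(d, 2)
    params_np["bout"] = np.zeros(2)
    params = {k: Tensor(v, requires_grad=True) for k, v in params_np.items()}
    opt = Adam(params, lr=lr)
    Xtr = X[:, train_idx]
    hot = np.zeros((len(train_idx), 2))
    hot[np.arange(len(train_idx)), labels[train_idx]] = 1.0

    for _ in range(epochs):
        opt.zero_grad()
        h = Tensor(np.zeros((len(train_idx), d)))
        for t in range(Xtr.shape[0]):
            x = Tensor(Xtr[t])
            r = ad.sigmoid(x @ params["Wir"] + params["bir"]
                           + h @ params["Whr"] + params["bhr"])
            z = ad.sigmoid(x @ params["Wiz"] + params["biz"]
                           + h @ params["Whz"] + params["bhz"])
            n = ad.tanh(x @ params["Win"] + params["bin"]
                        + r * (h @ params["Whn"] + params["bhn"]))
            h = (1.0 - z) * n + z * h
        logp = ad.log_softmax(h @ params["Wout"] + params["bout"])
        loss = -(logp * hot).sum() / len(train_idx)
        loss.backward()
        opt.step()

    final = {k: t.data for k, t in params.items()}
    p_test = _forward_np(final, X[:, test_idx])
    pred = (p_test > 0.5).astype(int)
    acc = float((pred == labels[test_idx]).mean())
    return IdentifierResult(accuracy=acc,
                            scores_pos=p_test[labels[test_idx] == 1],
                            scores_neg=p_test[labels[test_idx] == 0],
                            params=final, spec=spec)
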