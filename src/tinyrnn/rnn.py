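"""Tiny recurrent choice models.

Three recurrent architectures over 1-20 hidden units (dynamical variables):

* ``gru`` — a vanilla gated recurrent unit driven by a numeric input vector
  (previous action, second-stage state, reward);
* ``switching_gru`` — recurrent weights and biases selected per discrete
  input condition (all combinations of previous action/state/reward), a
  generalization of the vanilla GRU for discrete inputs;
* ``slin`` / ``slin_symmetric`` — switching *linear* dynamics
  ``h' = W^(x) h + b^(x)``, optionally with symmetric ``W``.

The initial hidden state is 0 and the first trial's policy is read out from
it before any input.  Readouts are linear with no bias — the action scores
are a function of the hidden state alone, which keeps the logit a valid
state coordinate for the dynamical-systems analyses — followed by softmax.

Two execution paths share one parameter container: a plain-numpy forward
used for evaluation, simulation and interpretation, and an autodiff forward
(:mod:`.autodiff`) used during training.  Tests pin them to each other.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .cognitive import PolicyTrace, softmax_policy
from .task_data import Session, SessionData

__all__ = [
    "RNNSpec",
    "RNNModel",
    "RNNAgent",
    "default_spec",
    "init_params",
    "encode_selector",
    "encode_vector",
    "gru_step",
    "switching_gru_step",
    "slin_step",
    "readout_scores",
    "forward_log_policies",
    "to_switching",
    "save_checkpoint",
    "load_checkpoint",
]

ARCHITECTURES = ("gru", "switching_gru", "slin", "slin_symmetric")


class SpecError(ValueError):
    pass


@dataclass
class RNNSpec:
    """Architecture description.

    ``n_codes`` is the size of the discrete input alphabet for selector
    encodings: 4 for single-outcome tasks (action x reward), 8 when the
    second-stage state is informative (action x state x reward).
    """

    architecture: str = "switching_gru"
    d: int = 1
    n_actions: int = 2
    n_states: int = 2
    encoding: str = "selector"          # 'selector' | 'vector'
    readout: str = "full"               # 'full' | 'diagonal'
    states_informative: bool = False    # True for two-stage style tasks
    input_dim: int = 3                  # vector encoding width
    continuous_reward: bool = False

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise SpecError(f"unknown architecture {self.architecture!r}")
        if self.d < 1:
            raise SpecError("hidden size d must be >= 1")
        if self.architecture == "gru" and self.encoding == "selector":
            raise SpecError("vanilla GRU uses the vector encoding")
        if self.architecture != "gru" and self.encoding == "vector":
            raise SpecError("switching architectures use the selector encoding")
        if self.encoding == "selector" and self.continuous_reward:
            raise SpecError("selector encoding requires binary rewards")
        if self.readout == "diagonal" and self.d != self.n_actions:
            raise SpecError("diagonal readout requires d == action count")

    @property
    def n_codes(self) -> int:
        n = self.n_actions * 2
        if self.states_informative:
            n *= self.n_states
        return n


def default_spec(d: int, states_informative: bool = False, **kw) -> RNNSpec:
    """d=1 models default to the switching GRU, d>=2 to the vanilla GRU."""
    arch = "switching_gru" if d == 1 else "gru"
    enc = "selector" if arch == "switching_gru" else "vector"
    return RNNSpec(architecture=arch, d=d, encoding=enc,
                   states_informative=states_informative, **kw)


# ---------------------------------------------------------------------------
# Input encodings


def encode_selector(action, state, reward, spec: RNNSpec) -> np.ndarray:
    """Map (previous action, state, reward) to a discrete input code.

    Ordering: code = ((action * n_states) + state) * 2 + reward when states
    are informative, else action * 2 + reward.  In single-outcome tasks the
    state equals the action, so both forms agree on the four codes.
    """
    a = np.asarray(action, dtype=int)
    s = np.asarray(state, dtype=int)
    r = np.asarray(reward, dtype=float)
    if np.any((r != 0) & (r != 1)):
        raise SpecError("selector encoding requires binary rewards")
    if spec.states_informative:
        return (a * spec.n_states + s) * 2 + r.astype(int)
    return a * 2 + r.astype(int)


def encode_vector(action, state, reward, spec: RNNSpec) -> np.ndarray:
    """Numeric input vector (action, state, reward); continuous rewards are
    rescaled from [0, 100] to [0, 1]."""
    a = np.asarray(action, dtype=float)
    s = np.asarray(state, dtype=float)
    r = np.asarray(reward, dtype=float)
    if spec.continuous_reward:
        r = r / 100.0
    return np.stack([a, s, r], axis=-1)


def _code_to_vector(code: int, spec: RNNSpec) -> np.ndarray:
    """Vector encoding of a discrete code (used by the exact transform)."""
    r = code % 2
    rest = code // 2
    if spec.states_informative:
        a, s = divmod(rest, spec.n_states)
    else:
        a = rest
        s = a
    return np.array([float(a), float(s), float(r)])


# ---------------------------------------------------------------------------
# Parameter initialization

_GATES = ("r", "z", "n")


def init_params(spec: RNNSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Small-uniform initialization, scale 1/sqrt(d)."""
    scale = 1.0 / np.sqrt(spec.d)
    def u(*shape):
        return rng.uniform(-scale, scale, size=shape)
    p: dict[str, np.ndarray] = {}
    K, d, n_in = spec.n_codes, spec.d, spec.input_dim
    if spec.architecture == "gru":
        for g in _GATES:
            p[f"Wi{g}"] = u(n_in, d)
            p[f"Wh{g}"] = u(d, d)
            p[f"bi{g}"] = u(d)
            p[f"bh{g}"] = u(d)
    elif spec.architecture == "switching_gru":
        for g in _GATES:
            p[f"Wh{g}"] = u(K, d, d)
            p[f"bi{g}"] = u(K, d)
            p[f"bh{g}"] = u(K, d)
    else:
        W = u(K, d, d)
        if spec.architecture == "slin_symmetric":
            W = (W + np.swapaxes(W, 1, 2)) / 2.0
        p["W"] = W
        p["b"] = u(K, d)
    if spec.readout == "diagonal":
        p["beta"] = u(d)
    else:
        p["beta"] = u(d, spec.n_actions)
    return p


RECURRENT_KEYS = ("Whr", "Whz", "Whn", "W")  # weights carrying the L1 penalty


# ---------------------------------------------------------------------------
# Plain-numpy steps (evaluation / interpretation path)


def _sig(x):
    return 1.0 / (1.0 + np.exp(-x))


def gru_step(params: dict, h: np.ndarray, x: np.ndarray) -> np.ndarray:
    """One vanilla GRU update; ``h`` (B, d), ``x`` (B, input_dim)."""
    if x.shape[-1] != params["Wir"].shape[0]:
        raise SpecError("input dimension mismatch")
    r = _sig(x @ params["Wir"] + params["bir"] + h @ params["Whr"] + params["bhr"])
    z = _sig(x @ params["Wiz"] + params["biz"] + h @ params["Whz"] + params["bhz"])
    n = np.tanh(x @ params["Win"] + params["bin"] + r * (h @ params["Whn"] + params["bhn"]))
    return (1.0 - z) * n + z * h


def _switched(params, name, h, codes):
    W = params[f"Wh{name}"][codes]                      # (B, d, d)
    return np.einsum("bij,bj->bi", W, h) + params[f"bi{name}"][codes] \
        + params[f"bh{name}"][codes]


def switching_gru_step(params: dict, h: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """One switching-GRU update; weights selected by integer ``codes``."""
    K = params["Whr"].shape[0]
    if np.any((codes < 0) | (codes >= K)):
        raise SpecError(f"input code out of range [0, {K})")
    r = _sig(_switched(params, "r", h, codes))
    z = _sig(_switched(params, "z", h, codes))
    inner = np.einsum("bij,bj->bi", params["Whn"][codes], h) + params["bhn"][codes]
    n = np.tanh(params["bin"][codes] + r * inner)
    return (1.0 - z) * n + z * h


def slin_step(params: dict, h: np.ndarray, codes: np.ndarray,
              symmetric: bool = False) -> np.ndarray:
    W = params["W"]
    if symmetric and not np.allclose(W, np.swapaxes(W, 1, 2), atol=1e-10):
        raise SpecError("weight bank violates the symmetry constraint")
    return np.einsum("bij,bj->bi", W[codes], h) + params["b"][codes]


def step_hidden(spec: RNNSpec, params: dict, h: np.ndarray, xin) -> np.ndarray:
    if spec.architecture == "gru":
        return gru_step(params, h, xin)
    if spec.architecture == "switching_gru":
        return switching_gru_step(params, h, xin)
    return slin_step(params, h, xin, symmetric=spec.architecture == "slin_symmetric")


def readout_scores(spec: RNNSpec, params: dict, h: np.ndarray) -> np.ndarray:
    """Linear (bias-free) readout of action scores from the hidden state."""
    if spec.readout == "diagonal":
        return params["beta"] * h
    return h @ params["beta"]


# ---------------------------------------------------------------------------
# Exact vanilla -> switching transform


def to_switching(params: dict, spec: RNNSpec) -> tuple[dict, RNNSpec]:
    """Transform a vanilla GRU into the exactly equivalent switching GRU by
    folding the input projection of each discrete code into per-code biases
    (``b_i^(x) <- W_i x + b_i``; recurrent weights shared across codes)."""
    if spec.architecture != "gru":
        raise SpecError("transform applies to vanilla GRUs")
    sw_spec = dataclasses.replace(spec, architecture="switching_gru",
                                  encoding="selector")
    K = sw_spec.n_codes
    out: dict[str, np.ndarray] = {"beta": params["beta"].copy()}
    xs = np.stack([_code_to_vector(k, sw_spec) for k in range(K)])
    for g in _GATES:
        # vanilla stores recurrent weights for right-multiplication (h @ W);
        # the switching bank left-multiplies, hence the transpose
        out[f"Wh{g}"] = np.repeat(params[f"Wh{g}"].T[None], K, axis=0)
        out[f"bi{g}"] = xs @ params[f"Wi{g}"] + params[f"bi{g}"]
        out[f"bh{g}"] = np.repeat(params[f"bh{g}"][None], K, axis=0)
    return out, sw_spec


# ---------------------------------------------------------------------------
# Session-level forward passes


def _session_inputs(spec: RNNSpec, sessions: list[Session]):
    """Stack sessions into padded (T, B) input codes / (T, B, 3) vectors,
    plus action and mask arrays."""
    tmax = max(s.n_trials for s in sessions)
    B = len(sessions)
    actions = np.zeros((tmax, B), dtype=int)
    mask = np.zeros((tmax, B), dtype=bool)
    if spec.encoding == "selector":
        xin = np.zeros((tmax, B), dtype=int)
    else:
        xin = np.zeros((tmax, B, spec.input_dim))
    for i, sess in enumerate(sessions):
        T = sess.n_trials
        a = np.where(sess.mask, sess.action, 0)
        s = np.where(sess.mask, sess.state, 0)
        r = np.where(sess.mask, sess.reward, 0.0)
        actions[:T, i] = a
        mask[:T, i] = sess.mask
        if spec.encoding == "selector":
            xin[:T, i] = encode_selector(a, s, r, spec)
        else:
            xin[:T, i] = encode_vector(a, s, r, spec)
    return xin, actions, mask


class RNNModel:
    """A spec plus a parameter container, with the cognitive-model-style
    trace interface used by fitting and interpretation."""

    def __init__(self, spec: RNNSpec, params: dict[str, np.ndarray]):
        self.spec = spec
        self.params = params
        self.id = f"{spec.architecture}_d{spec.d}"
        self.n_actions = spec.n_actions
        self.d = spec.d
        self.two_stage_choice = False
        self.continuous_reward = spec.continuous_reward

    @classmethod
    def create(cls, spec: RNNSpec, seed: int = 0) -> "RNNModel":
        return cls(spec, init_params(spec, np.random.default_rng(seed)))

    def policy_traces(self, data: SessionData | list[Session]) -> PolicyTrace:
        sessions = data.sessions if isinstance(data, SessionData) else list(data)
        xin, _, mask = _session_inputs(self.spec, sessions)
        T, B = mask.shape
        h = np.zeros((B, self.spec.d))
        probs = np.empty((T, B, self.spec.n_actions))
        for t in range(T):
            probs[t] = softmax_policy(readout_scores(self.spec, self.params, h))
            h_new = step_hidden(self.spec, self.params, h, xin[t])
            h = np.where(mask[t][:, None], h_new, h)
        return PolicyTrace([probs[: s.n_trials, i, :] for i, s in enumerate(sessions)])

    def hidden_trajectory(self, session: Session) -> np.ndarray:
        """Hidden states h_t for one session, shape (T, d); h_1 = 0."""
        xin, _, mask = _session_inputs(self.spec, [session])
        h = np.zeros((1, self.spec.d))
        out = np.empty((session.n_trials, self.spec.d))
        for t in range(session.n_trials):
            out[t] = h[0]
            if mask[t, 0]:
                h = step_hidden(self.spec, self.params, h, xin[t])
        return out

    def step(self, h: np.ndarray, action, state, reward) -> np.ndarray:
        """Advance hidden state(s) by one observed trial."""
        h = np.atleast_2d(h)
        B = h.shape[0]
        a = np.broadcast_to(np.asarray(action, dtype=int), (B,))
        s = np.broadcast_to(np.asarray(state, dtype=int), (B,))
        r = np.broadcast_to(np.asarray(reward, dtype=float), (B,))
        if self.spec.encoding == "selector":
            xin = encode_selector(a, s, r, self.spec)
        else:
            xin = encode_vector(a, s, r, self.spec)
        return step_hidden(self.spec, self.params, h, xin)

    def copy(self) -> "RNNModel":
        return RNNModel(self.spec, {k: v.copy() for k, v in self.params.items()})


class RNNAgent:
    """Adapter so an RNN model can act as a simulation agent."""

    def __init__(self, model: RNNModel):
        self.model = model
        self.reset()

    def reset(self) -> None:
        self.h = np.zeros((1, self.model.spec.d))

    def policy(self) -> np.ndarray:
        return softmax_policy(readout_scores(self.model.spec, self.model.params, self.h))[0]

    def update(self, action, state, reward, action2=None) -> None:
        self.h = self.model.step(self.h, action, state, reward)


# ---------------------------------------------------------------------------
# Autodiff forward (training path)


def _onehot_codes(codes: np.ndarray, K: int) -> np.ndarray:
    out = np.zeros(codes.shape + (K,))
    np.put_along_axis(out, codes[..., None], 1.0, axis=-1)
    return out


def forward_log_policies(spec: RNNSpec, params: dict[str, Tensor], xin,
                         mask: np.ndarray):
    """Autodiff forward pass over padded inputs.

    Returns a (T, B, A) Tensor of log action probabilities.  On padded
    trials the hidden state is frozen (their rows are excluded from losses
    by the caller's mask).
    """
    T, B = mask.shape
    h = Tensor(np.zeros((B, spec.d)))
    log_probs = []
    if spec.encoding == "selector":
        hot = _onehot_codes(xin, spec.n_codes)          # (T, B, K)
    for t in range(T):
        if spec.readout == "diagonal":
            scores = h * params["beta"].reshape(1, spec.d)
        else:
            scores = h @ params["beta"]
        log_probs.append(ad.log_softmax(scores))
        if spec.architecture == "gru":
            x = Tensor(xin[t])
            r = ad.sigmoid(x @ params["Wir"] + params["bir"]
                           + h @ params["Whr"] + params["bhr"])
            z = ad.sigmoid(x @ params["Wiz"] + params["biz"]
                           + h @ params["Whz"] + params["bhz"])
            inner = h @ params["Whn"] + params["bhn"]
            n = ad.tanh(x @ params["Win"] + params["bin"] + r * inner)
            h_new = (1.0 - z) * n + z * h
        elif spec.architecture == "switching_gru":
            oh = hot[t]
            r = ad.sigmoid(ad.switched_linear(h, oh, params["Whr"], params["bhr"])
                           + Tensor(oh) @ params["bir"])
            z = ad.sigmoid(ad.switched_linear(h, oh, params["Whz"], params["bhz"])
                           + Tensor(oh) @ params["biz"])
            inner = ad.switched_linear(h, oh, params["Whn"], params["bhn"])
            n = ad.tanh(Tensor(oh) @ params["bin"] + r * inner)
            h_new = (1.0 - z) * n + z * h
        else:
            oh = hot[t]
            h_new = ad.switched_linear(h, oh, params["W"], params["b"])
        m = mask[t][:, None].astype(float)
        h = h_new * m + h * (1.0 - m)
    return ad.stack(log_probs, axis=0)


# ---------------------------------------------------------------------------
# Checkpoints (flat key-value text container)


def save_checkpoint(model: RNNModel, path) -> None:
    payload = {
        "spec": dataclasses.asdict(model.spec),
        "params": {k: v.tolist() for k, v in model.params.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_checkpoint(path) -> RNNModel:
    with open(path) as fh:
        payload = json.load(fh)
    spec = RNNSpec(**payload["spec"])
    params = {k: np.asarray(v, dtype=float) for k, v in payload["params"].items()}
    return RNNModel(spec, params)
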