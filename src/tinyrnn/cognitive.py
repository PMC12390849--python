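"""Classical cognitive models as per-trial state-update + policy rules.

Every model is a discrete dynamical system: a small vector of dynamical
variables (action values ``Q``, state values ``V``, beliefs, perseveration
traces, transition estimates) is carried across trials, updated from the
previous trial's (action, second-stage state, reward), and mapped to a
softmax policy over actions.

Conventions shared by the whole catalogue:

* values and perseveration traces start at 0; beliefs and transition
  estimates start at 0.5;
* continuous rewards (0-100 point scales) are rescaled to [0, 1] before
  entering update rules, so learning-rate semantics are uniform (the scale
  is absorbed by the inverse temperature / reward sensitivity);
* masked-out trials neither update the state nor contribute to policies
  used for fitting;
* all updates are vectorized over a batch of sessions (leading axis).

Models are registered by string id in :data:`MODEL_REGISTRY` and created
with :func:`make_model`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .task_data import Session, SessionData

__all__ = [
    "softmax_policy",
    "CognitiveModel",
    "PolicyTrace",
    "policy_traces",
    "CognitiveAgent",
    "MODEL_REGISTRY",
    "make_model",
    "model_ids",
]


def softmax_policy(scores: np.ndarray, beta: float = 1.0) -> np.ndarray:
    """Numerically stable softmax of ``beta * scores`` along the last axis."""
    z = beta * np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(z)):
        raise FloatingPointError("non-finite score passed to softmax")
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# parameter kinds understood by the fitting reparameterization:
#   unit       -> [0, 1]        (logistic)
#   unit_half  -> (0.5, 1]      (emission probabilities)
#   pos        -> [0, inf)      (inverse temperatures; softplus)
#   real       -> unconstrained (utilities, biases, reference points)


class CognitiveModel:
    """Base class; subclasses define PARAMS, d, and the update/policy rules."""

    id: str = ""
    n_actions: int = 2
    d: int = 0
    PARAMS: dict[str, str] = {}
    DEFAULTS: dict[str, float] = {}
    two_stage_choice = False        # True for the original two-stage family
    continuous_reward = False       # True for the drifting-bandit family

    def init_state(self, params: dict, batch: int) -> dict:
        raise NotImplementedError

    def step(self, st: dict, params: dict, a, s, r, a2=None) -> dict:
        """Return the updated state given the previous trial's observations.

        ``a``, ``s`` are int arrays (batch,), ``r`` float (batch,).  Must not
        mutate ``st``.
        """
        raise NotImplementedError

    def scores(self, st: dict, params: dict) -> np.ndarray:
        """Pre-softmax action scores, inverse temperature included."""
        raise NotImplementedError

    def policy(self, st: dict, params: dict) -> np.ndarray:
        return softmax_policy(self.scores(st, params))

    # -- helpers -----------------------------------------------------------
    @staticmethod
    def _onehot(idx: np.ndarray, n: int) -> np.ndarray:
        out = np.zeros((len(idx), n))
        out[np.arange(len(idx)), idx] = 1.0
        return out


def _sign(idx: np.ndarray) -> np.ndarray:
    """+1 for code 0 (A1/S1), -1 for code 1 (A2/S2)."""
    return 1.0 - 2.0 * idx


# ---------------------------------------------------------------------------
# Bayesian inference (reversal learning / two-stage; d = 1)


class BayesModel(CognitiveModel):
    """Latent-state inference: belief that state S1 currently carries the
    high reward probability, updated by Bayes' rule with emission
    probability ``p_emit`` and per-trial switch probability ``p_r``."""

    id = "bayes"
    d = 1
    PARAMS = {"p_r": "unit", "p_emit": "unit_half", "beta": "pos"}
    DEFAULTS = {"p_r": 0.05, "p_emit": 0.7, "beta": 5.0}

    def init_state(self, params, batch):
        return {"pr1": np.full(batch, 0.5)}

    def step(self, st, params, a, s, r, a2=None):
        pe, pr = params["p_emit"], params["p_r"]
        p1 = st["pr1"]
        # Pr(r | h=i, s): emission pe when the visited state matches h
        match1 = (s == 0).astype(float)
        p_match = np.where(r > 0.5, pe, 1.0 - pe)
        p_miss = np.where(r > 0.5, 1.0 - pe, pe)
        like1 = np.where(match1 > 0.5, p_match, p_miss)
        like2 = np.where(match1 > 0.5, p_miss, p_match)
        denom = like1 * p1 + like2 * (1.0 - p1)
        if np.any(denom <= 0):
            raise FloatingPointError("zero normalizer in Bayesian update")
        post = like1 * p1 / denom
        return {"pr1": (1.0 - pr) * post + pr * (1.0 - post)}

    def scores(self, st, params):
        p1 = st["pr1"]
        return params["beta"] * np.stack([p1, 1.0 - p1], axis=-1)


# ---------------------------------------------------------------------------
# Model-free family, reversal learning / two-stage first stage


class MF1(CognitiveModel):
    """Anticorrelated action values, Q(A1) = -Q(A2); one variable."""

    id = "mf1"
    d = 1
    PARAMS = {"alpha": "unit", "beta": "pos"}
    DEFAULTS = {"alpha": 0.5, "beta": 3.0}

    def init_state(self, params, batch):
        return {"q1": np.zeros(batch)}

    def step(self, st, params, a, s, r, a2=None):
        c = _sign(a)
        q1 = st["q1"]
        return {"q1": q1 + params["alpha"] * (c * r - q1)}

    def scores(self, st, params):
        q1 = st["q1"]
        return params["beta"] * np.stack([q1, -q1], axis=-1)


class MFN(CognitiveModel):
    """Independent action values; chosen value moves toward the reward.

    ``forgetting``: 'none' (unchosen unchanged), 'to_zero' (D*Q) or
    'to_mean' (D*Q + (1-D)/2).
    """

    d = None  # set in __init__
    PARAMS = {"alpha": "unit", "beta": "pos"}
    DEFAULTS = {"alpha": 0.4, "beta": 3.0, "forget": 0.9}

    def __init__(self, n_actions: int = 2, forgetting: str = "none"):
        if forgetting not in ("none", "to_zero", "to_mean"):
            raise ValueError(f"unknown forgetting mode {forgetting!r}")
        self.n_actions = n_actions
        self.forgetting = forgetting
        self.d = n_actions
        suffix = {"none": "", "to_zero": "_forget", "to_mean": "_forget_mean"}[forgetting]
        self.id = f"mf{n_actions}{suffix}" if n_actions == 2 else f"mf_n{suffix}"
        self.PARAMS = dict(self.PARAMS)
        if forgetting != "none":
            self.PARAMS["forget"] = "unit"

    def init_state(self, params, batch):
        return {"q": np.zeros((batch, self.n_actions))}

    def step(self, st, params, a, s, r, a2=None):
        alpha = params["alpha"]
        q = st["q"]
        hot = self._onehot(a, self.n_actions)
        chosen = q + alpha * (r[:, None] - q)
        if self.forgetting == "none":
            other = q
        elif self.forgetting == "to_zero":
            other = params["forget"] * q
        else:
            other = params["forget"] * q + (1.0 - params["forget"]) * 0.5
        return {"q": hot * chosen + (1.0 - hot) * other}

    def scores(self, st, params):
        return params["beta"] * st["q"]


class MF2Drift(CognitiveModel):
    """Drift-to-the-other rule (discovered from two-unit network dynamics).

    Rewarded: chosen <- D1*Q + 1, unchosen <- Q - b.  Unrewarded: chosen
    drifts toward the other value by alpha0; unchosen unchanged.
    """

    id = "mf2_drift"
    n_actions = 2
    d = 2
    PARAMS = {"alpha0": "unit", "D1": "unit", "b": "unit", "beta": "pos"}
    DEFAULTS = {"alpha0": 0.3, "D1": 0.7, "b": 0.05, "beta": 3.0}

    def init_state(self, params, batch):
        return {"q": np.zeros((batch, 2))}

    def step(self, st, params, a, s, r, a2=None):
        q = st["q"]
        hot = self._onehot(a, 2)
        other = (q * (1.0 - hot)).sum(axis=1)
        rewarded = (r > 0.5)[:, None]
        chosen_rew = params["D1"] * q + 1.0
        unchosen_rew = q - params["b"]
        chosen_unrew = q + params["alpha0"] * (other[:, None] - q)
        new = np.where(
            rewarded,
            hot * chosen_rew + (1 - hot) * unchosen_rew,
            hot * chosen_unrew + (1 - hot) * q,
        )
        return {"q": new}

    def scores(self, st, params):
        return params["beta"] * st["q"]


class MFInertia(CognitiveModel):
    """Model-free values plus an anticorrelated perseveration trace.

    ``values``: 'anticorrelated' (d = 2 overall) or 'independent' (d = 3).
    """

    PARAMS = {"alpha": "unit", "alpha_pers": "unit", "k_pers": "real", "beta": "pos"}
    DEFAULTS = {"alpha": 0.4, "alpha_pers": 0.3, "k_pers": 0.5, "beta": 3.0}
    n_actions = 2

    def __init__(self, values: str = "anticorrelated"):
        self.values = values
        self.d = 2 if values == "anticorrelated" else 3
        self.id = "mf1_inertia" if values == "anticorrelated" else "mf2_inertia"

    def init_state(self, params, batch):
        st = {"x1": np.zeros(batch)}
        if self.values == "anticorrelated":
            st["q1"] = np.zeros(batch)
        else:
            st["q"] = np.zeros((batch, 2))
        return st

    def step(self, st, params, a, s, r, a2=None):
        c = _sign(a)
        ap, k = params["alpha_pers"], params["k_pers"]
        x1 = st["x1"] + ap * (c * k - st["x1"])
        if self.values == "anticorrelated":
            q1 = st["q1"] + params["alpha"] * (c * r - st["q1"])
            return {"q1": q1, "x1": x1}
        hot = self._onehot(a, 2)
        q = st["q"] + hot * params["alpha"] * (r[:, None] - st["q"])
        return {"q": q, "x1": x1}

    def scores(self, st, params):
        x = np.stack([st["x1"], -st["x1"]], axis=-1)
        if self.values == "anticorrelated":
            q = np.stack([st["q1"], -st["q1"]], axis=-1)
        else:
            q = st["q"]
        return params["beta"] * (q + x)


class RewardAsCue(CognitiveModel):
    """Values over four augmented states (previous state x previous reward)
    and two actions; only the slot of the previous augmented state and the
    chosen action updates each trial (d = 8)."""

    id = "rac8"
    n_actions = 2
    d = 8
    PARAMS = {"alpha": "unit", "beta": "pos"}
    DEFAULTS = {"alpha": 0.4, "beta": 3.0}

    def init_state(self, params, batch):
        # augmented state index 2*s + r; starts at (S1, r=0) -> 0
        return {"q": np.zeros((batch, 4, 2)), "aug": np.zeros(batch, dtype=int)}

    def step(self, st, params, a, s, r, a2=None):
        q = st["q"].copy()
        b = np.arange(len(a))
        slot = q[b, st["aug"], a]
        q[b, st["aug"], a] = slot + params["alpha"] * (r - slot)
        return {"q": q, "aug": (2 * s + (r > 0.5)).astype(int)}

    def scores(self, st, params):
        b = np.arange(len(st["aug"]))
        return params["beta"] * st["q"][b, st["aug"], :]


# ---------------------------------------------------------------------------
# Model-free Q(0) for the two-stage task (d = 4)


class MFQ0(CognitiveModel):
    """First-stage action values learn from second-stage state values, which
    in turn learn from reward (one-step backup; d = 4)."""

    id = "mfq0"
    n_actions = 2
    d = 4
    PARAMS = {"alpha": "unit", "beta": "pos"}
    DEFAULTS = {"alpha": 0.4, "beta": 3.0}

    def init_state(self, params, batch):
        return {"q": np.zeros((batch, 2)), "v": np.zeros((batch, 2))}

    def step(self, st, params, a, s, r, a2=None):
        alpha = params["alpha"]
        b = np.arange(len(a))
        q = st["q"].copy()
        v = st["v"].copy()
        q[b, a] += alpha * (v[b, s] - q[b, a])   # uses V_{t-1}
        v[b, s] += alpha * (r - v[b, s])
        return {"q": q, "v": v}

    def scores(self, st, params):
        return params["beta"] * st["q"]


# ---------------------------------------------------------------------------
# Model-based family for the two-stage task


class MB1(CognitiveModel):
    """Anticorrelated second-stage state values; first-stage action values
    computed through the known transition table (d = 1)."""

    id = "mb1"
    n_actions = 2
    d = 1
    PARAMS = {"alpha": "unit", "beta": "pos"}
    DEFAULTS = {"alpha": 0.5, "beta": 3.0}

    def __init__(self, p_common: float = 0.8):
        self.p_common = p_common

    def init_state(self, params, batch):
        return {"v1": np.zeros(batch)}

    def step(self, st, params, a, s, r, a2=None):
        c = _sign(s)
        v1 = st["v1"]
        return {"v1": v1 + params["alpha"] * (c * r - v1)}

    def scores(self, st, params):
        qmb1 = (2.0 * self.p_common - 1.0) * st["v1"]
        return params["beta"] * np.stack([qmb1, -qmb1], axis=-1)


class MB2(CognitiveModel):
    """Independent second-stage state values, optional forgetting of the
    unvisited state; model-based first-stage values (d = 2)."""

    PARAMS = {"alpha": "unit", "beta": "pos"}
    DEFAULTS = {"alpha": 0.4, "beta": 3.0, "forget": 0.9}
    n_actions = 2
    d = 2

    def __init__(self, p_common: float = 0.8, forgetting: bool = False):
        self.p_common = p_common
        self.forgetting = forgetting
        self.id = "mb2_forget" if forgetting else "mb2"
        self.PARAMS = dict(self.PARAMS)
        if forgetting:
            self.PARAMS["forget"] = "unit"

    def _trans(self):
        p = self.p_common
        return np.array([[p, 1 - p], [1 - p, p]])

    def init_state(self, params, batch):
        return {"v": np.zeros((batch, 2))}

    def step(self, st, params, a, s, r, a2=None):
        hot = self._onehot(s, 2)
        visited = st["v"] + params["alpha"] * (r[:, None] - st["v"])
        other = params["forget"] * st["v"] if self.forgetting else st["v"]
        return {"v": hot * visited + (1 - hot) * other}

    def scores(self, st, params):
        qmb = st["v"] @ self._trans().T
        return params["beta"] * qmb


class MBMix(CognitiveModel):
    """Mixture of the anticorrelated model-free and model-based strategies;
    net values (1-w)*Qmf + w*Qmb (d = 2)."""

    id = "mb_mix"
    n_actions = 2
    d = 2
    PARAMS = {"alpha": "unit", "alpha_mb": "unit", "w": "unit", "beta": "pos"}
    DEFAULTS = {"alpha": 0.4, "alpha_mb": 0.4, "w": 0.5, "beta": 3.0}

    def __init__(self, p_common: float = 0.8):
        self.p_common = p_common

    def init_state(self, params, batch):
        return {"q1": np.zeros(batch), "v1": np.zeros(batch)}

    def step(self, st, params, a, s, r, a2=None):
        ca, cs = _sign(a), _sign(s)
        q1 = st["q1"] + params["alpha"] * (ca * r - st["q1"])
        v1 = st["v1"] + params["alpha_mb"] * (cs * r - st["v1"])
        return {"q1": q1, "v1": v1}

    def scores(self, st, params):
        w = params["w"]
        qmb1 = (2.0 * self.p_common - 1.0) * st["v1"]
        net1 = (1 - w) * st["q1"] + w * qmb1
        return params["beta"] * np.stack([net1, -net1], axis=-1)


# ---------------------------------------------------------------------------
# Component models for the transition-reversal two-stage task


class AkamComposite(CognitiveModel):
    """Compositional model: second-stage state values plus any of
    model-free action values (with eligibility trace), a learned transition
    model, motor-level action values, choice and motor-level perseveration
    traces, and bias terms, combined into net action values.

    ``components`` is a subset of {"mf", "mb", "motor"}; ``forget_q``
    enables forgetting of state, action and motor-level values (shared rate
    ``f_Q``), ``forget_t`` of the learned transition probabilities
    (``f_T``); ``multi_pers``/``motor_pers`` select the perseveration
    traces (with ``multi_pers`` False, the single-trial perseveration term
    is still present through its weight ``P_c``).
    """

    n_actions = 2

    def __init__(self, components=("mf",), forget_q=False, forget_t=False,
                 multi_pers=False, motor_pers=False, ident: str | None = None):
        self.components = frozenset(components)
        self.forget_q = forget_q
        self.forget_t = forget_t
        self.multi_pers = multi_pers
        self.motor_pers = motor_pers
        self.d = 2  # state values
        params: dict[str, str] = {"alpha_Q": "unit"}
        if forget_q:
            params["f_Q"] = "unit"
        if "mf" in self.components or "motor" in self.components:
            params["alpha"] = "unit"
            params["lam"] = "unit"
        if "mf" in self.components:
            params["G_mf"] = "pos"
            self.d += 2
        if "mb" in self.components:
            params["alpha_T"] = "unit"
            params["G_mb"] = "pos"
            if forget_t:
                params["f_T"] = "unit"
            self.d += 2
        if "motor" in self.components:
            params["G_mo"] = "pos"
            self.d += 4
        params["B_c"] = "real"
        params["B_r"] = "real"
        params["P_c"] = "real"
        if multi_pers:
            params["alpha_c"] = "unit"
            self.d += 1
        if motor_pers:
            params["alpha_m"] = "unit"
            params["P_m"] = "real"
            self.d += 2
        self.PARAMS = params
        self.DEFAULTS = {
            "alpha_Q": 0.4, "f_Q": 0.1, "alpha": 0.4, "lam": 0.5, "G_mf": 3.0,
            "alpha_T": 0.3, "G_mb": 3.0, "f_T": 0.1, "G_mo": 1.0,
            "B_c": 0.0, "B_r": 0.0, "P_c": 1.0, "alpha_c": 0.5,
            "alpha_m": 0.5, "P_m": 1.0,
        }
        self.id = ident or "akam_" + "_".join(sorted(self.components))

    def init_state(self, params, batch):
        # s_last holds the most recent second-stage state; during a step for
        # trial t-1 it still contains s_{t-2}, which is exactly what the
        # motor-level components index by.
        st = {"v": np.zeros((batch, 2)), "xcp": np.zeros(batch),
              "s_last": np.zeros(batch, dtype=int),
              "xs": np.zeros(batch)}
        if "mf" in self.components:
            st["qmf"] = np.zeros((batch, 2))
        if "mb" in self.components:
            st["p1"] = np.full((batch, 2), 0.5)   # P(S1 | A_i)
        if "motor" in self.components:
            st["qmo"] = np.zeros((batch, 4))      # index a + 2*s_{t-2}
        if self.motor_pers:
            st["xmocp"] = np.zeros((batch, 2))    # indexed by s_{t-2}
        return st

    def step(self, st, params, a, s, r, a2=None):
        b = np.arange(len(a))
        new = {k: v.copy() for k, v in st.items()}
        aQ = params["alpha_Q"]
        fQ = params.get("f_Q", 0.0)
        s_before = st["s_last"]                   # s_{t-2}
        hot_s = self._onehot(s, 2)
        v_prev = st["v"]
        visited = v_prev + aQ * (r[:, None] - v_prev)
        unvisited = (1.0 - fQ) * v_prev if self.forget_q else v_prev
        new["v"] = hot_s * visited + (1 - hot_s) * unvisited

        if "mf" in self.components:
            al, lam = params["alpha"], params["lam"]
            hot_a = self._onehot(a, 2)
            target = lam * r + (1 - lam) * v_prev[b, s]
            chosen = st["qmf"] + al * (target[:, None] - st["qmf"])
            unchosen = (1.0 - fQ) * st["qmf"] if self.forget_q else st["qmf"]
            new["qmf"] = hot_a * chosen + (1 - hot_a) * unchosen
        if "mb" in self.components:
            aT = params["alpha_T"]
            p1 = st["p1"].copy()
            p1[b, a] = (1 - aT) * p1[b, a] + aT * (s == 0)
            if self.forget_t:
                fT = params["f_T"]
                ub = 1 - a
                p1[b, ub] = p1[b, ub] + fT * (0.5 - p1[b, ub])
            new["p1"] = p1
        if "motor" in self.components:
            al, lam = params["alpha"], params["lam"]
            mo = (a + 2 * s_before).astype(int)
            qmo = st["qmo"].copy()
            target = lam * r + (1 - lam) * v_prev[b, s_before]
            qmo_new = qmo[b, mo] + al * (target - qmo[b, mo])
            if self.forget_q:
                qmo = (1.0 - fQ) * qmo
            qmo[b, mo] = qmo_new
            new["qmo"] = qmo

        xtilde = -0.5 + a.astype(float)   # -0.5 for A1, +0.5 for A2
        ac = params["alpha_c"] if self.multi_pers else 1.0
        new["xcp"] = st["xcp"] + ac * (xtilde - st["xcp"])
        if self.motor_pers:
            am = params["alpha_m"]
            xm = st["xmocp"].copy()
            xm[b, s_before] += am * (xtilde - xm[b, s_before])
            new["xmocp"] = xm

        new["s_last"] = s.astype(int)
        new["xs"] = -0.5 + s.astype(float)
        return new

    def scores(self, st, params):
        batch = len(st["xcp"])
        b = np.arange(batch)
        qnet = np.zeros((batch, 2))
        if "mf" in self.components:
            qnet += params["G_mf"] * st["qmf"]
        if "mb" in self.components:
            v1, v2 = st["v"][:, 0], st["v"][:, 1]
            qmb = st["p1"] * v1[:, None] + (1 - st["p1"]) * v2[:, None]
            qnet += params["G_mb"] * qmb
        if "motor" in self.components:
            idx = np.stack([0 + 2 * st["s_last"], 1 + 2 * st["s_last"]], axis=-1)
            qnet += params["G_mo"] * st["qmo"][b[:, None], idx]
        x2 = params["B_c"] + params["B_r"] * st["xs"] + params["P_c"] * st["xcp"]
        if self.motor_pers:
            x2 = x2 + params["P_m"] * st["xmocp"][b, st["s_last"]]
        qnet[:, 1] += x2
        return qnet


# ---------------------------------------------------------------------------
# n-armed model-free family (three-armed reversal, four-armed bandit)


class MFNForgetPers(CognitiveModel):
    """Value forgetting plus decaying action perseveration (d = 2n)."""

    PARAMS = {"alpha": "unit", "forget": "unit", "D_pers": "unit",
              "k_pers": "real", "beta": "pos"}
    DEFAULTS = {"alpha": 0.4, "forget": 0.9, "D_pers": 0.7, "k_pers": 0.3,
                "beta": 3.0}

    def __init__(self, n_actions: int, continuous_reward: bool = False):
        self.n_actions = n_actions
        self.d = 2 * n_actions
        self.continuous_reward = continuous_reward
        self.id = "mf_n_forget_pers"

    def init_state(self, params, batch):
        return {"q": np.zeros((batch, self.n_actions)),
                "x": np.zeros((batch, self.n_actions))}

    def step(self, st, params, a, s, r, a2=None):
        hot = self._onehot(a, self.n_actions)
        chosen = st["q"] + params["alpha"] * (r[:, None] - st["q"])
        q = hot * chosen + (1 - hot) * params["forget"] * st["q"]
        x = params["D_pers"] * st["x"] + hot * params["k_pers"]
        return {"q": q, "x": x}

    def scores(self, st, params):
        return params["beta"] * (st["q"] + st["x"])


class MFNUtility(CognitiveModel):
    """Unchosen-value updating with case-specific reward utilities
    (three-armed reversal; constructed from the network's strategy)."""

    id = "mf_n_utility"
    PARAMS = {"alpha_c": "unit", "alpha_u": "unit", "U_c0": "real",
              "U_c1": "real", "U_u0": "real", "U_u1": "real", "beta": "pos"}
    DEFAULTS = {"alpha_c": 0.5, "alpha_u": 0.2, "U_c0": -0.5, "U_c1": 1.0,
                "U_u0": 0.0, "U_u1": -0.5, "beta": 3.0}

    def __init__(self, n_actions: int = 3):
        self.n_actions = n_actions
        self.d = n_actions

    def init_state(self, params, batch):
        return {"q": np.zeros((batch, self.n_actions))}

    def step(self, st, params, a, s, r, a2=None):
        hot = self._onehot(a, self.n_actions)
        rew = (r > 0.5)
        uc = np.where(rew, params["U_c1"], params["U_c0"])[:, None]
        uu = np.where(rew, params["U_u1"], params["U_u0"])[:, None]
        chosen = st["q"] + params["alpha_c"] * (uc - st["q"])
        unchosen = st["q"] + params["alpha_u"] * (uu - st["q"])
        return {"q": hot * chosen + (1 - hot) * unchosen}

    def scores(self, st, params):
        return params["beta"] * st["q"]


class MFNRefPoint(CognitiveModel):
    """Decay-plus-increment rule with reward reference points (four-armed
    drifting bandit).  ``reduced`` ties the sensitivities to the decay
    rates (beta_c = alpha_c, beta_u = alpha_u)."""

    PARAMS = {"alpha_c": "unit", "alpha_u": "unit", "beta_c": "real",
              "beta_u": "real", "R_c": "real", "R_u": "real", "beta": "pos"}
    DEFAULTS = {"alpha_c": 0.4, "alpha_u": 0.1, "beta_c": 0.4, "beta_u": 0.1,
                "R_c": 0.5, "R_u": 0.5, "beta": 3.0}
    continuous_reward = True

    def __init__(self, n_actions: int = 4, reduced: bool = False):
        self.n_actions = n_actions
        self.d = n_actions
        self.reduced = reduced
        self.id = "mf_n_refpoint_reduced" if reduced else "mf_n_refpoint"
        if reduced:
            self.PARAMS = {k: v for k, v in self.PARAMS.items()
                           if k not in ("beta_c", "beta_u")}

    def init_state(self, params, batch):
        return {"q": np.zeros((batch, self.n_actions))}

    def step(self, st, params, a, s, r, a2=None):
        bc = params["alpha_c"] if self.reduced else params["beta_c"]
        bu = params["alpha_u"] if self.reduced else params["beta_u"]
        hot = self._onehot(a, self.n_actions)
        uc = (bc * (r - params["R_c"]))[:, None]
        uu = (bu * (r - params["R_u"]))[:, None]
        chosen = (1 - params["alpha_c"]) * st["q"] + uc
        unchosen = (1 - params["alpha_u"]) * st["q"] + uu
        return {"q": hot * chosen + (1 - hot) * unchosen}

    def scores(self, st, params):
        return params["beta"] * st["q"]


# ---------------------------------------------------------------------------
# Original two-stage task (two choice stages per trial)


class OriginalTwoStage(CognitiveModel):
    """Model family for the task with a second choice stage.

    ``variant`` in {mf3, mb2, mix3, mf6, mb4, mix6, utility3}.  The
    anticorrelated variants (mf3/mb2/mix3/utility3) track one value per
    choice state; the independent variants (mf6/mb4/mix6) track both.
    """

    two_stage_choice = True
    n_actions = 2

    _DIMS = {"mf3": 3, "mb2": 2, "mix3": 3, "mf6": 6, "mb4": 4, "mix6": 6,
             "utility3": 3}

    def __init__(self, variant: str = "mf3", p_common: float = 0.7):
        if variant not in self._DIMS:
            raise ValueError(f"unknown variant {variant!r}")
        self.variant = variant
        self.p_common = p_common
        self.d = self._DIMS[variant]
        self.id = f"ots_{variant}"
        self.anticorr = variant in ("mf3", "mb2", "mix3", "utility3")
        self.has_mf = variant in ("mf3", "mix3", "mf6", "mix6", "utility3")
        self.has_mb = variant in ("mb2", "mix3", "mb4", "mix6")
        params: dict[str, str] = {"alpha2": "unit", "beta1": "pos", "beta2": "pos"}
        if self.has_mf:
            params["alpha1"] = "unit"
        if variant in ("mf3", "mix3", "mf6", "mix6"):
            params["lam"] = "unit"
        if variant in ("mix3", "mix6"):
            params["w"] = "unit"
        if variant == "utility3":
            params.update({"U_other": "real", "U_1st_zero": "real",
                           "U_2nd_zero": "real"})
        self.PARAMS = params
        self.DEFAULTS = {"alpha1": 0.4, "alpha2": 0.4, "lam": 0.5, "w": 0.5,
                         "beta1": 3.0, "beta2": 3.0, "U_other": 0.3,
                         "U_1st_zero": -0.3, "U_2nd_zero": -0.5}

    def init_state(self, params, batch):
        if self.anticorr:
            return {"q0": np.zeros(batch), "q1": np.zeros(batch),
                    "q2": np.zeros(batch)}
        return {"q0": np.zeros((batch, 2)), "q1": np.zeros((batch, 2)),
                "q2": np.zeros((batch, 2))}

    # second-stage values per state, shape (batch, 2 states, 2 options)
    def _stage2_values(self, st):
        if self.anticorr:
            q1 = np.stack([st["q1"], -st["q1"]], axis=-1)
            q2 = np.stack([st["q2"], -st["q2"]], axis=-1)
        else:
            q1, q2 = st["q1"], st["q2"]
        return np.stack([q1, q2], axis=1)

    def step(self, st, params, a, s, r, a2=None):
        if a2 is None:
            raise ValueError("original two-stage models require second-stage actions")
        b = np.arange(len(a))
        a2 = np.asarray(a2)
        new = {k: v.copy() for k, v in st.items()}
        if self.variant == "utility3":
            return self._step_utility(st, new, params, b, a, s, r, a2)
        al2 = params["alpha2"]
        if self.anticorr:
            c2 = _sign(a2)
            for state, key in ((0, "q1"), (1, "q2")):
                m = s == state
                q = st[key]
                new[key] = np.where(m, q + al2 * (c2 * r - q), q)
            q2_chosen_new = np.where(s == 0, _sign(a2) * new["q1"],
                                     _sign(a2) * new["q2"])
        else:
            for state, key in ((0, "q1"), (1, "q2")):
                m = s == state
                q = st[key].copy()
                upd = q[b, a2] + al2 * (r - q[b, a2])
                q[b, a2] = np.where(m, upd, q[b, a2])
                new[key] = q
            q2_chosen_new = np.where(s == 0, new["q1"][b, a2], new["q2"][b, a2])
        if self.has_mf:
            al1, lam = params["alpha1"], params["lam"]
            target = lam * r + (1 - lam) * q2_chosen_new
            if self.anticorr:
                c0 = _sign(a)
                new["q0"] = st["q0"] + al1 * (c0 * target - st["q0"])
            else:
                q0 = st["q0"].copy()
                q0[b, a] += al1 * (target - q0[b, a])
                new["q0"] = q0
        return new

    def _step_utility(self, st, new, params, b, a, s, r, a2):
        al1, al2 = params["alpha1"], params["alpha2"]
        rew = r > 0.5
        u0 = np.where(rew, 1.0, params["U_1st_zero"])
        u_chosen = np.where(rew, 1.0, params["U_2nd_zero"])
        u_other = np.where(rew, params["U_other"], -params["U_other"])
        c0, c2 = _sign(a), _sign(a2)
        # chosen second-stage state: toward u_chosen; motor twin at the
        # other state: toward u_other (same option index, hence same sign)
        for state, key in ((0, "q1"), (1, "q2")):
            q = st[key]
            target = np.where(s == state, u_chosen, u_other)
            new[key] = q + al2 * (c2 * target - q)
        new["q0"] = st["q0"] + al1 * (c0 * u0 - st["q0"])
        return new

    def scores(self, st, params):
        """First-stage scores; see :meth:`scores2` for the second stage."""
        b1 = params["beta1"]
        if self.variant == "utility3" or (self.has_mf and not self.has_mb):
            if self.anticorr:
                qmf = np.stack([st["q0"], -st["q0"]], axis=-1)
            else:
                qmf = st["q0"]
            return b1 * qmf
        v2 = self._stage2_values(st)          # (batch, state, option)
        best = v2.max(axis=-1)                # (batch, state)
        p = self.p_common
        trans = np.array([[p, 1 - p], [1 - p, p]])
        qmb = best @ trans.T
        if self.has_mb and not self.has_mf:
            return b1 * qmb
        w = params["w"]
        if self.anticorr:
            qmf = np.stack([st["q0"], -st["q0"]], axis=-1)
        else:
            qmf = st["q0"]
        return b1 * ((1 - w) * qmf + w * qmb)

    def scores2(self, st, params, s: np.ndarray) -> np.ndarray:
        b = np.arange(len(s))
        v2 = self._stage2_values(st)
        return params["beta2"] * v2[b, s, :]

    def policy2(self, st, params, s):
        return softmax_policy(self.scores2(st, params, s))


# ---------------------------------------------------------------------------
# Registry


def _akam_catalogue() -> dict:
    """The compositional model catalogue for the transition-reversal task:
    three composite model-free strategies and twelve model-based ones (the
    richest, ``akam_mb_full``, has 13 dynamical variables)."""
    specs = {
        # model-free strategies (beyond mf1/mf2 reused from the two-stage task)
        "akam_mf": dict(components=("mf",)),
        "akam_mf_forget": dict(components=("mf",), forget_q=True),
        "akam_mf_motor": dict(components=("mf", "motor"), forget_q=True,
                              multi_pers=True, motor_pers=True),
        # model-based strategies
        "akam_mb": dict(components=("mb",)),
        "akam_mb_mf": dict(components=("mf", "mb")),
        "akam_mbf": dict(components=("mb",), forget_t=True),
        "akam_mbf_mff": dict(components=("mf", "mb"), forget_q=True,
                             forget_t=True),
        "akam_mb_mff": dict(components=("mf", "mb"), forget_q=True),
        "akam_mb_mf_pers": dict(components=("mf", "mb"), multi_pers=True),
        "akam_mbf_mff_pers": dict(components=("mf", "mb"), forget_q=True,
                                  forget_t=True, multi_pers=True),
        "akam_mb_mff_pers": dict(components=("mf", "mb"), forget_q=True,
                                 multi_pers=True),
        "akam_mbf_mff_mpers": dict(components=("mf", "mb"), forget_q=True,
                                   forget_t=True, motor_pers=True),
        "akam_mbf_pers_mpers": dict(components=("mb",), forget_t=True,
                                    multi_pers=True, motor_pers=True),
        "akam_mbf_mff_pers_mpers": dict(components=("mf", "mb"), forget_q=True,
                                        forget_t=True, multi_pers=True,
                                        motor_pers=True),
        "akam_mb_full": dict(components=("mf", "mb", "motor"), forget_q=True,
                             forget_t=True, multi_pers=True, motor_pers=True),
    }
    return {ident: (lambda kw=kw, ident=ident: AkamComposite(ident=ident, **kw))
            for ident, kw in specs.items()}


MODEL_REGISTRY: dict = {
    "bayes": BayesModel,
    "mf1": MF1,
    "mf2": lambda: MFN(2, "none"),
    "mf2_forget": lambda: MFN(2, "to_zero"),
    "mf2_forget_mean": lambda: MFN(2, "to_mean"),
    "mf2_drift": MF2Drift,
    "mf1_inertia": lambda: MFInertia("anticorrelated"),
    "mf2_inertia": lambda: MFInertia("independent"),
    "rac8": RewardAsCue,
    "mfq0": MFQ0,
    "mb1": MB1,
    "mb2": lambda: MB2(forgetting=False),
    "mb2_forget": lambda: MB2(forgetting=True),
    "mb_mix": MBMix,
    # n-armed families
    "mf3": lambda: MFN(3, "none"),
    "mf3_forget": lambda: MFN(3, "to_zero"),
    "mf3_forget_pers": lambda: MFNForgetPers(3),
    "mf3_utility": lambda: MFNUtility(3),
    "mf4": lambda: MFN(4, "none"),
    "mf4_forget": lambda: MFN(4, "to_zero"),
    "mf4_forget_pers": lambda: MFNForgetPers(4, continuous_reward=True),
    "mf4_refpoint": lambda: MFNRefPoint(4, reduced=False),
    "mf4_refpoint_reduced": lambda: MFNRefPoint(4, reduced=True),
    # original two-stage task
    "ots_mf3": lambda: OriginalTwoStage("mf3"),
    "ots_mb2": lambda: OriginalTwoStage("mb2"),
    "ots_mix3": lambda: OriginalTwoStage("mix3"),
    "ots_mf6": lambda: OriginalTwoStage("mf6"),
    "ots_mb4": lambda: OriginalTwoStage("mb4"),
    "ots_mix6": lambda: OriginalTwoStage("mix6"),
    "ots_utility3": lambda: OriginalTwoStage("utility3"),
}
MODEL_REGISTRY.update(_akam_catalogue())

# mark continuous-reward variants of the shared n-armed classes
_CONTINUOUS_IDS = {"mf4", "mf4_forget", "mf4_forget_pers", "mf4_refpoint",
                   "mf4_refpoint_reduced"}


def make_model(model_id: str) -> CognitiveModel:
    if model_id not in MODEL_REGISTRY:
        raise KeyError(f"unknown model id {model_id!r}; see model_ids()")
    model = MODEL_REGISTRY[model_id]()
    model.id = model_id
    if model_id in _CONTINUOUS_IDS:
        model.continuous_reward = True
    return model


def model_ids() -> list[str]:
    return sorted(MODEL_REGISTRY)


# ---------------------------------------------------------------------------
# Running models over sessions


@dataclass
class PolicyTrace:
    """Per-trial action probabilities, one array of shape (T_i, n_actions)
    per session; ``stage2`` holds second-stage policies where the task has
    a second choice stage."""

    per_session: list[np.ndarray]
    stage2: list[np.ndarray] | None = None

    @property
    def n_trials(self) -> int:
        return sum(len(p) for p in self.per_session)


def _session_arrays(sessions: list[Session]):
    tmax = max(s.n_trials for s in sessions)
    B = len(sessions)
    a = np.zeros((tmax, B), dtype=int)
    s_ = np.zeros((tmax, B), dtype=int)
    r = np.zeros((tmax, B))
    m = np.zeros((tmax, B), dtype=bool)
    a2 = np.zeros((tmax, B), dtype=int)
    has_a2 = all(sess.action2 is not None for sess in sessions)
    for i, sess in enumerate(sessions):
        T = sess.n_trials
        valid = sess.mask
        a[:T, i] = np.where(valid, sess.action, 0)
        s_[:T, i] = np.where(valid, sess.state, 0)
        r[:T, i] = np.where(valid, sess.reward, 0.0)
        m[:T, i] = valid
        if has_a2:
            a2[:T, i] = np.where(valid, sess.action2, 0)
    return a, s_, r, m, (a2 if has_a2 else None)


def _masked_update(old: dict, new: dict, mask: np.ndarray) -> dict:
    out = {}
    for k in old:
        o, n = old[k], new[k]
        mk = mask if o.ndim == 1 else mask.reshape(mask.shape + (1,) * (o.ndim - 1))
        out[k] = np.where(mk, n, o)
    return out


def policy_traces(model: CognitiveModel, params: dict,
                  data: SessionData | list[Session]) -> PolicyTrace:
    """Run a model over sessions and return its per-trial policies.

    On masked-out trials the state is carried through unchanged; the policy
    rows for those trials are still emitted (they are excluded from losses
    downstream).
    """
    sessions = data.sessions if isinstance(data, SessionData) else list(data)
    a, s, r, m, a2 = _session_arrays(sessions)
    if model.continuous_reward:
        r = r / 100.0
    T, B = a.shape
    st = model.init_state(params, B)
    probs = np.empty((T, B, model.n_actions))
    probs2 = np.empty((T, B, 2)) if model.two_stage_choice else None
    for t in range(T):
        probs[t] = model.policy(st, params)
        if model.two_stage_choice:
            probs2[t] = model.policy2(st, params, s[t])
        new = model.step(st, params, a[t], s[t], r[t],
                         a2[t] if a2 is not None else None)
        st = _masked_update(st, new, m[t])
    per_session = [probs[: sess.n_trials, i, :] for i, sess in enumerate(sessions)]
    stage2 = None
    if probs2 is not None:
        stage2 = [probs2[: sess.n_trials, i, :] for i, sess in enumerate(sessions)]
    return PolicyTrace(per_session, stage2)


class CognitiveAgent:
    """Adapter so a cognitive model can act as a simulation agent."""

    def __init__(self, model: CognitiveModel, params: dict | None = None):
        self.model = model
        self.params = dict(model.DEFAULTS) if params is None else dict(params)
        missing = set(model.PARAMS) - set(self.params)
        if missing:
            raise ValueError(f"missing parameters {sorted(missing)}")
        self.reset()

    def reset(self) -> None:
        self.state = self.model.init_state(self.params, 1)

    def policy(self) -> np.ndarray:
        return self.model.policy(self.state, self.params)[0]

    def policy2(self, state: int) -> np.ndarray:
        return self.model.policy2(self.state, self.params, np.array([state]))[0]

    def update(self, action, state, reward, action2=None) -> None:
        if self.model.continuous_reward:
            reward = reward / 100.0
        self.state = self.model.step(
            self.state, self.params, np.array([action]), np.array([state]),
            np.array([float(reward)]),
            None if action2 is None else np.array([action2]),
        )
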