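"""Dynamical-systems interpretation of fitted choice models.

Any fitted model — cognitive or recurrent — defines a discrete dynamical
system: its dynamical variables are updated once per trial by the input
condition (previous action, second-stage state, reward).  For
one-dimensional models the state coordinate is the policy logit
``L = log(Pr(A1)/Pr(A2))``; a phase portrait plots the one-step change
``dL = L(t+1) - L(t)`` against ``L`` for each input condition.  Fixed
points ``L*`` satisfy ``g(L*) = 0`` where ``g`` is the per-condition logit
change; with ``f(L) = L + g(L)`` the fixed point is stable iff
``-2 < g'(L*) < 0``.  Preference setpoints are the normalized asymptotic
logits reached by repeating one input.  Dynamical regression linearizes
the per-condition one-step map, collecting the coefficients into an
input-dependent state-transition matrix ``A`` akin to a Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .cognitive import CognitiveModel
from .fitting import FittedCognitive
from .rnn import RNNModel, readout_scores
from .task_data import Session, SessionData

__all__ = [
    "Condition",
    "compute_logits",
    "OneStepSystem",
    "PortraitData",
    "phase_portrait",
    "find_fixed_points",
    "SetpointTable",
    "preference_setpoints",
    "effective_learning_rate",
    "vector_field_2d",
    "DynRegressionResult",
    "dynamical_regression",
    "score_trajectory",
    "task_conditions",
]

FP_TOL = 1e-8
GRID_POINTS = 512
ITER_CAP = 10_000


Condition = tuple[int, int, float]    # (action, second-stage state, reward)


def task_conditions(task_config) -> list[Condition]:
    """All discrete input conditions of a task.  For single-outcome tasks
    the state mirrors the action."""
    conds = []
    states_informative = task_config.transition_types is not None
    for a in range(task_config.n_actions):
        states = range(task_config.n_states) if states_informative else [a]
        for s in states:
            for r in (0.0, 1.0):
                conds.append((a, s, r))
    return conds


def compute_logits(probs: np.ndarray, action_pair: tuple[int, int] = (0, 1)
                   ) -> np.ndarray:
    """Per-trial log odds of ``action_pair[0]`` over ``action_pair[1]``."""
    p = np.asarray(probs, dtype=float)
    i, j = action_pair
    p = np.clip(p, 1e-12, None)
    return np.log(p[..., i]) - np.log(p[..., j])


# ---------------------------------------------------------------------------
# Uniform one-step interface over fitted models


def _as_model(model):
    """Normalize accepted model forms to (model-like, kind)."""
    if isinstance(model, RNNModel):
        return model, "rnn"
    if isinstance(model, FittedCognitive):
        return model, "cog"
    if isinstance(model, tuple) and isinstance(model[0], CognitiveModel):
        return FittedCognitive(model[0], model[1]), "cog"
    raise TypeError(f"unsupported model object {type(model)!r}")


class OneStepSystem:
    """Scalar (d = 1) view of a fitted model: maps between the internal
    dynamical variable and the logit, and applies one-input steps."""

    def __init__(self, model):
        self.model, self.kind = _as_model(model)
        if self.kind == "cog":
            st = self.model.model.init_state(self.model.params, 1)
            if sum(np.asarray(v).size for v in st.values()) != 1:
                raise ValueError("one-dimensional analysis requires a d=1 model")
            self._key = next(k for k, v in st.items() if np.asarray(v).size == 1)
        elif self.model.spec.d != 1:
            raise ValueError("one-dimensional analysis requires d=1")

    # scalar <-> model state -------------------------------------------------
    def _state(self, x: np.ndarray):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if self.kind == "cog":
            st = self.model.model.init_state(self.model.params, len(x))
            st[self._key] = x.copy()
            return st
        return x[:, None]

    def _scalar(self, st) -> np.ndarray:
        return st[self._key] if self.kind == "cog" else st[:, 0]

    def logit_of(self, x: np.ndarray) -> np.ndarray:
        """Logit as a function of the scalar dynamical variable."""
        st = self._state(x)
        if self.kind == "cog":
            scores = self.model.model.scores(st, self.model.params)
        else:
            scores = readout_scores(self.model.spec, self.model.params, st)
        return scores[:, 0] - scores[:, 1]

    def step(self, x: np.ndarray, cond: Condition) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        a = np.full(len(x), cond[0], dtype=int)
        s = np.full(len(x), cond[1], dtype=int)
        r = np.full(len(x), float(cond[2]))
        if self.kind == "cog":
            new = self.model.model.step(self._state(x), self.model.params, a, s, r)
        else:
            new = self.model.step(self._state(x), a, s, r)
        return self._scalar(new)

    def observed_scalars(self, data: SessionData | list[Session]) -> np.ndarray:
        """Scalar state visited on each trial of the data."""
        sessions = data.sessions if isinstance(data, SessionData) else list(data)
        out = []
        for sess in sessions:
            if self.kind == "rnn":
                out.append(self.model.hidden_trajectory(sess)[:, 0])
                continue
            xs = np.empty(sess.n_trials)
            st = self.model.model.init_state(self.model.params, 1)
            for t in range(sess.n_trials):
                xs[t] = self._scalar(st)[0]
                if sess.mask[t]:
                    st = self.model.model.step(
                        st, self.model.params,
                        sess.action[t:t + 1], sess.state[t:t + 1],
                        np.asarray([float(sess.reward[t])]))
            out.append(xs)
        return np.concatenate(out)


# ---------------------------------------------------------------------------
# Phase portraits


@dataclass
class PortraitData:
    """Per input condition: a swept (L, dL) curve, observed (L, dL)
    samples, and the curve's fixed points with stability labels."""

    conditions: list[Condition]
    curves: dict = field(default_factory=dict)        # cond -> (L, dL)
    samples: dict = field(default_factory=dict)       # cond -> (L, dL)
    fixed_points: dict = field(default_factory=dict)  # cond -> [(L*, stable)]


def phase_portrait(model, task_config=None, data: SessionData | None = None,
                   conditions: list[Condition] | None = None,
                   grid: np.ndarray | None = None,
                   n_grid: int = GRID_POINTS) -> PortraitData:
    """Phase portrait of a one-dimensional model.

    The scalar state is swept over the 0.5-99.5 percentile range of the
    states visited in ``data`` (or a symmetric default range) and mapped to
    the logit through the model's readout; observed per-trial (L, dL)
    samples are collected when data is given.
    """
    sys = OneStepSystem(model)
    if conditions is None:
        if task_config is None:
            raise ValueError("provide conditions or a task configuration")
        conditions = task_conditions(task_config)
    if grid is None:
        if data is not None:
            xs = sys.observed_scalars(data)
            lo, hi = np.percentile(xs, [0.5, 99.5])
            if hi - lo < 1e-6:
                lo, hi = lo - 1.0, hi + 1.0
        else:
            lo, hi = -1.0, 1.0
        grid = np.linspace(lo, hi, n_grid)
    portrait = PortraitData(list(conditions))
    for cond in conditions:
        L = sys.logit_of(grid)
        L_next = sys.logit_of(sys.step(grid, cond))
        dL = L_next - L
        order = np.argsort(L)
        L, dL = L[order], dL[order]
        portrait.curves[cond] = (L, dL)
        portrait.fixed_points[cond] = find_fixed_points(L, dL)
    if data is not None:
        sessions = data.sessions if isinstance(data, SessionData) else list(data)
        per_cond: dict = {c: ([], []) for c in conditions}
        for sess in sessions:
            xs = np.empty(sess.n_trials)
            x = np.zeros(1)
            for t in range(sess.n_trials):
                xs[t] = x[0]
                if sess.mask[t]:
                    x = sys.step(x, (int(sess.action[t]), int(sess.state[t]),
                                     float(sess.reward[t])))
            Ls = sys.logit_of(xs)
            for t in range(sess.n_trials - 1):
                if not (sess.mask[t] and sess.mask[t + 1]):
                    continue
                c = (int(sess.action[t]), int(sess.state[t]), float(sess.reward[t]))
                if c in per_cond:
                    per_cond[c][0].append(Ls[t])
                    per_cond[c][1].append(Ls[t + 1] - Ls[t])
        portrait.samples = {c: (np.asarray(v[0]), np.asarray(v[1]))
                            for c, v in per_cond.items()}
    return portrait


def find_fixed_points(L: np.ndarray, dL: np.ndarray,
                      tol: float = FP_TOL) -> list[tuple[float, bool]]:
    """Locate zeros of a logit-change curve by sign-change bracketing and
    bisection; label stability by the central-difference slope criterion
    ``-2 < g'(L*) < 0``.  An empty list means no crossing in range."""
    L = np.asarray(L, dtype=float)
    dL = np.asarray(dL, dtype=float)
    def g(x):
        return np.interp(x, L, dL)
    out = []
    sign = np.sign(dL)
    eps = max(1e-6 * (L[-1] - L[0]), 1e-9)
    for i in np.flatnonzero(np.diff(sign) != 0):
        if sign[i] == 0:  # exact zero on the grid
            root = float(L[i])
        else:
            a, b = float(L[i]), float(L[i + 1])
            for _ in range(200):
                m = 0.5 * (a + b)
                if abs(g(m)) < tol or (b - a) < 1e-15:
                    break
                if np.sign(g(m)) == np.sign(g(a)):
                    a = m
                else:
                    b = m
            root = 0.5 * (a + b)
        slope = (g(root + eps) - g(root - eps)) / (2 * eps)
        out.append((root, bool(-2.0 < slope < 0.0)))
    dedup: list[tuple[float, bool]] = []
    for root, stable in out:
        if not dedup or abs(root - dedup[-1][0]) > 10 * eps:
            dedup.append((root, stable))
    return dedup


# ---------------------------------------------------------------------------
# Preference setpoints


@dataclass
class SetpointTable:
    """Normalized long-run action preference per input condition."""

    u: dict                      # cond -> u_I in [-1, 1] (nan if diverged)
    fixed_logits: dict           # cond -> L*_I
    normalizer: float            # max_I |L*_I|
    diverged: dict = field(default_factory=dict)  # cond -> drift sign


def preference_setpoints(model, conditions: list[Condition],
                         data: SessionData | None = None,
                         start: float | None = None,
                         iteration_cap: int = ITER_CAP,
                         tol: float = FP_TOL) -> SetpointTable:
    """Iterate each one-input map to convergence and normalize the
    asymptotic logits by the largest magnitude.

    The iteration starts from the median observed scalar state (or
    ``start``); non-convergent conditions are flagged with their drift
    sign and get a NaN setpoint.
    """
    sys = OneStepSystem(model)
    if start is None:
        start = float(np.median(sys.observed_scalars(data))) if data is not None else 0.0
    fixed, diverged = {}, {}
    L_start = sys.logit_of(np.array([start]))[0]
    for cond in conditions:
        x = np.array([start], dtype=float)
        L = L_start
        converged = False
        for _ in range(iteration_cap):
            x = sys.step(x, cond)
            L_new = sys.logit_of(x)[0]
            if abs(L_new - L) < tol:
                converged, L = True, L_new
                break
            L = L_new
        if converged:
            fixed[cond] = float(L)
        else:
            diverged[cond] = float(np.sign(L - L_start))
            fixed[cond] = np.nan
    mags = [abs(v) for v in fixed.values() if np.isfinite(v)]
    norm = max(mags) if mags else 0.0
    if norm > 0:
        u = {c: (v / norm if np.isfinite(v) else np.nan) for c, v in fixed.items()}
    else:
        u = {c: (0.0 if np.isfinite(v) else np.nan) for c, v in fixed.items()}
    return SetpointTable(u, fixed, norm, diverged)


# ---------------------------------------------------------------------------
# Effective learning rate


def effective_learning_rate(g, L_star: float, L: np.ndarray,
                            eps: float = 1e-6) -> np.ndarray:
    """Effective learning rate ``alpha(L) = -g(L) / (L - L*)`` relative to
    a stable fixed point (the secant slope toward the fixed point), with
    the derivative limit ``-g'(L*)`` at the fixed point itself.

    ``g`` is a callable or an (L, dL) curve pair.
    """
    if not callable(g):
        Lc, dLc = g
        gfun = lambda x: np.interp(x, Lc, dLc)
    else:
        gfun = g
    L = np.atleast_1d(np.asarray(L, dtype=float))
    out = np.empty_like(L)
    near = np.abs(L - L_star) < eps
    out[near] = -(gfun(L_star + eps) - gfun(L_star - eps)) / (2 * eps)
    far = ~near
    out[far] = -np.asarray(gfun(L[far])) / (L[far] - L_star)
    return out


# ---------------------------------------------------------------------------
# Two-dimensional vector fields


class TwoDSystem:
    """Vector view of a model with two dynamical variables (d = 2 network
    with diagonal readout, or a cognitive model with one 2-vector slot)."""

    def __init__(self, model):
        self.model, self.kind = _as_model(model)
        if self.kind == "rnn":
            if self.model.spec.d != 2 or self.model.spec.readout != "diagonal":
                raise ValueError("2-D analysis requires d=2 with diagonal readout")
        else:
            st = self.model.model.init_state(self.model.params, 1)
            vec = [k for k, v in st.items()
                   if np.asarray(v).ndim == 2 and np.asarray(v).shape[-1] == 2]
            if len(vec) != 1 or sum(np.asarray(v).size for v in st.values()) != 2:
                raise ValueError("2-D analysis requires a single 2-vector state")
            self._key = vec[0]

    def step(self, pts: np.ndarray, cond: Condition) -> np.ndarray:
        pts = np.atleast_2d(pts)
        n = len(pts)
        a = np.full(n, cond[0], dtype=int)
        s = np.full(n, cond[1], dtype=int)
        r = np.full(n, float(cond[2]))
        if self.kind == "rnn":
            return self.model.step(pts, a, s, r)
        st = self.model.model.init_state(self.model.params, n)
        st[self._key] = pts.copy()
        new = self.model.model.step(st, self.model.params, a, s, r)
        return new[self._key]


def vector_field_2d(model, conditions: list[Condition],
                    grid: tuple[np.ndarray, np.ndarray],
                    iteration_cap: int = 500, tol: float = 1e-6) -> dict:
    """One-step state changes on a 2-D grid per input condition, plus the
    attractor set found by iterated convergence from every node.

    Returns ``{cond: {"points", "deltas", "speed", "attractors"}}``.
    """
    sys = TwoDSystem(model)
    g1, g2 = np.meshgrid(grid[0], grid[1], indexing="ij")
    pts = np.stack([g1.ravel(), g2.ravel()], axis=-1)
    out = {}
    for cond in conditions:
        nxt = sys.step(pts, cond)
        deltas = nxt - pts
        x = pts.copy()
        for _ in range(iteration_cap):
            x_new = sys.step(x, cond)
            if np.max(np.abs(x_new - x)) < tol:
                x = x_new
                break
            x = x_new
        finite = np.all(np.isfinite(x), axis=1)
        attractors = (np.unique(np.round(x[finite], 4), axis=0)
                      if finite.any() else np.empty((0, 2)))
        out[cond] = {"points": pts, "deltas": deltas,
                     "speed": np.linalg.norm(deltas, axis=1),
                     "attractors": attractors}
    return out


# ---------------------------------------------------------------------------
# Dynamical regression


def score_trajectory(model, session: Session) -> np.ndarray:
    """Per-trial pre-softmax action scores (the preference coordinates
    P_i(t); for d = 1 models the logit is their difference)."""
    m, kind = _as_model(model)
    if kind == "rnn":
        H = m.hidden_trajectory(session)
        return readout_scores(m.spec, m.params, H)
    model_, params = m.model, m.params
    st = model_.init_state(params, 1)
    out = np.empty((session.n_trials, model_.n_actions))
    r_scale = 100.0 if model_.continuous_reward else 1.0
    for t in range(session.n_trials):
        out[t] = model_.scores(st, params)[0]
        if session.mask[t]:
            st = model_.step(st, params, session.action[t:t + 1],
                             session.state[t:t + 1],
                             np.asarray([float(session.reward[t]) / r_scale]))
    return out


@dataclass
class DynRegressionResult:
    """Per-condition linearization of the one-step dynamics."""

    conditions: list
    beta0: dict                  # cond -> (d,) intercepts
    A: dict                      # cond -> (d, d) state-transition matrix
    beta_r: dict                 # cond -> (d,) reward coefficients (or None)
    resid_var: dict              # cond -> (d,) residual variances
    flagged: list = field(default_factory=list)   # rank-deficient conditions


def dynamical_regression(states: np.ndarray, inputs: list,
                         reward: np.ndarray | None = None) -> DynRegressionResult:
    """Ordinary least squares of the one-step state change on the current
    state, separately per input condition.

    ``states``: (T, d) per-trial coordinates (logits or preferences);
    ``inputs[t]`` is the hashable condition applied between t and t+1;
    ``reward`` optionally adds a continuous-reward regressor (length
    aligned with ``inputs``).  Conditions with fewer than d + 2 usable
    pairs or a rank-deficient design are flagged and get no estimate.
    """
    states = np.asarray(states, dtype=float)
    T, d = states.shape
    dstates = states[1:] - states[:-1]
    conds = list(inputs)[: T - 1]
    uniq = sorted(set(conds), key=repr)
    res = DynRegressionResult(uniq, {}, {}, {}, {})
    conds_arr = np.array([uniq.index(c) for c in conds])
    for ci, cond in enumerate(uniq):
        rows = np.flatnonzero(conds_arr == ci)
        X = states[rows]
        cols = [np.ones(len(rows)), *(X[:, j] for j in range(d))]
        if reward is not None:
            cols.insert(1, np.asarray(reward, float)[rows])
        design = np.column_stack(cols)
        if len(rows) < d + 2 or np.linalg.matrix_rank(design) < design.shape[1]:
            res.flagged.append(cond)
            continue
        Y = dstates[rows]
        beta0 = np.empty(d)
        betar = np.empty(d) if reward is not None else None
        A = np.empty((d, d))
        rv = np.empty(d)
        for i in range(d):
            fit = sm.OLS(Y[:, i], design).fit()
            coefs = fit.params
            beta0[i] = coefs[0]
            off = 2 if reward is not None else 1
            if reward is not None:
                betar[i] = coefs[1]
            A[i] = coefs[off:off + d]
            rv[i] = float(np.var(fit.resid))
        res.beta0[cond] = beta0
        res.A[cond] = A
        res.beta_r[cond] = betar
        res.resid_var[cond] = rv
    return res
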