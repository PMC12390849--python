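"""Maximum-likelihood fitting, nested cross-validation and dimensionality.

All models — classical cognitive models and the tiny recurrent networks —
are fitted by minimizing the trial-averaged negative log-likelihood (NLL,
cross-entropy) of next-action prediction; missing trials are excluded from
the loss.  Parameter bounds of cognitive models are enforced by smooth
reparameterization (logistic for rates/probabilities, softplus for inverse
temperatures), so every model family is optimized with the same gradient
machinery: scipy L-BFGS with random restarts for the few-parameter
cognitive models, Adam with early stopping for networks.

Model comparison uses nested cross-validation over ~150-trial blocks dealt
into folds: for each outer test fold, an inner loop over the remaining
folds trains one model per (validation fold, hyperparameter) pair, selects
the best by trial-weighted NLL on the held-in (train + validation) data,
and evaluates it once on the unseen test fold.  For the single-block human
tasks an interspersed split samples disjoint train/validation/test trial
index sets while models always see the whole sequence as input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from . import rnn as rnn_mod
from .autodiff import Adam, Tensor
from .cognitive import CognitiveModel, PolicyTrace, policy_traces
from .rnn import RNNModel, RNNSpec, forward_log_policies, init_params
from .task_data import BlockPartition, Session, SessionData

__all__ = [
    "FitConfig",
    "CVReport",
    "FoldResult",
    "FittedCognitive",
    "negative_log_likelihood",
    "fit_sequence_model",
    "train_model",
    "fit_cognitive",
    "train_rnn",
    "nested_cv",
    "interspersed_split",
    "fit_interspersed",
    "estimate_dimensionality",
]

PROB_FLOOR = 1e-12


class LeakageError(AssertionError):
    pass


@dataclass
class FitConfig:
    """Optimization and cross-validation settings."""

    learning_rate: float = 0.005
    l1_grid: tuple[float, ...] = (1e-5, 1e-4, 1e-3, 1e-2, 1e-1)
    patience: int = 200            # early-stop patience, in epochs
    max_epochs: int = 1000
    seeds: tuple[int, ...] = (0, 1, 2)
    n_folds: int = 10
    protocol: str = "nested_cv"    # 'nested_cv' | 'interspersed' | 'cross_subject'
    n_restarts: int = 3            # cognitive-model restarts
    val_every: int = 1             # epochs between validation evaluations

    def __post_init__(self) -> None:
        if not self.l1_grid:
            raise ValueError("hyperparameter grid must be nonempty")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


# ---------------------------------------------------------------------------
# Likelihood


def negative_log_likelihood(trace: PolicyTrace, sessions: list[Session] | SessionData,
                            loss_masks: list[np.ndarray] | None = None
                            ) -> tuple[float, int]:
    """Total NLL of the observed actions under ``trace`` plus the trial
    count entering the loss.

    ``loss_masks`` optionally restricts which trials are scored (on top of
    the validity mask); the model still saw the whole sequence when the
    trace was produced.  Zero probabilities are floored at 1e-12 with a
    warning.  For tasks with a second choice stage, both stages contribute.
    """
    if isinstance(sessions, SessionData):
        sessions = sessions.sessions
    total = 0.0
    count = 0
    floored = False
    for i, sess in enumerate(sessions):
        m = sess.mask.copy()
        if loss_masks is not None:
            m &= loss_masks[i]
        if not m.any():
            continue
        p = trace.per_session[i][m, sess.action[m]]
        if np.any(p < PROB_FLOOR):
            floored = True
            p = np.maximum(p, PROB_FLOOR)
        total += float(-np.log(p).sum())
        count += int(m.sum())
        if trace.stage2 is not None:
            p2 = trace.stage2[i][m, sess.action2[m]]
            if np.any(p2 < PROB_FLOOR):
                floored = True
                p2 = np.maximum(p2, PROB_FLOOR)
            total += float(-np.log(p2).sum())
    if floored:
        warnings.warn("policy probability floored at 1e-12 in NLL", RuntimeWarning)
    return total, count


def _nll_per_trial(model, sessions, loss_masks=None) -> float:
    total, count = negative_log_likelihood(model.policy_traces(sessions),
                                           sessions, loss_masks)
    return total / max(count, 1)


# ---------------------------------------------------------------------------
# Cognitive-model fitting (smooth reparameterization + L-BFGS restarts)


def _to_natural(u: np.ndarray, kinds: list[str]) -> np.ndarray:
    out = np.empty_like(u)
    for i, kind in enumerate(kinds):
        if kind == "unit":
            out[i] = special.expit(u[i])
        elif kind == "unit_half":
            out[i] = 0.5 + 0.5 * special.expit(u[i])
        elif kind == "pos":
            out[i] = np.logaddexp(0.0, u[i])      # softplus
        else:
            out[i] = u[i]
    return out


def _from_natural(x: np.ndarray, kinds: list[str]) -> np.ndarray:
    out = np.empty_like(x)
    for i, kind in enumerate(kinds):
        if kind == "unit":
            out[i] = special.logit(np.clip(x[i], 1e-9, 1 - 1e-9))
        elif kind == "unit_half":
            out[i] = special.logit(np.clip(2 * (x[i] - 0.5), 1e-9, 1 - 1e-9))
        elif kind == "pos":
            out[i] = np.log(np.expm1(max(x[i], 1e-9)))
        else:
            out[i] = x[i]
    return out


class FittedCognitive:
    """A cognitive model bound to fitted parameters, exposing the same
    trace interface as :class:`~tinyrnn.rnn.RNNModel`."""

    def __init__(self, model: CognitiveModel, params: dict[str, float]):
        self.model = model
        self.params = dict(params)
        self.id = model.id
        self.n_actions = model.n_actions
        self.d = model.d

    def policy_traces(self, data) -> PolicyTrace:
        return policy_traces(self.model, self.params, data)


def fit_cognitive(model: CognitiveModel, train_sessions: list[Session],
                  config: FitConfig | None = None, seed: int = 0,
                  loss_masks: list[np.ndarray] | None = None
                  ) -> tuple[FittedCognitive, dict]:
    """Maximum-likelihood fit with ``config.n_restarts`` random restarts."""
    config = config or FitConfig()
    names = list(model.PARAMS)
    kinds = [model.PARAMS[k] for k in names]
    rng = np.random.default_rng(seed)

    def objective(u: np.ndarray) -> float:
        x = _to_natural(u, kinds)
        params = dict(zip(names, x))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                trace = policy_traces(model, params, train_sessions)
                total, count = negative_log_likelihood(trace, train_sessions,
                                                       loss_masks)
        except FloatingPointError:
            # degenerate parameter corner (e.g. an emission probability
            # saturating at 1 meeting a contradictory observation)
            return 1e6
        return total / max(count, 1)

    best_u, best_val = None, np.inf
    for _ in range(config.n_restarts):
        u0 = rng.normal(0.0, 1.0, size=len(names))
        res = optimize.minimize(objective, u0, method="L-BFGS-B")
        if res.fun < best_val:
            best_val, best_u = res.fun, res.x
    params = dict(zip(names, _to_natural(best_u, kinds)))
    fitted = FittedCognitive(model, params)
    return fitted, {"train_nll": best_val, "n_restarts": config.n_restarts}


# ---------------------------------------------------------------------------
# RNN training (Adam, L1 on recurrent weights, early stopping)


def fit_sequence_model(spec: RNNSpec, xin, mask: np.ndarray,
                       targets: np.ndarray, val_fn, config: FitConfig,
                       seed: int = 0, l1: float = 0.0) -> tuple[RNNModel, dict]:
    """Shared trainer for recurrent models.

    ``targets`` is a (T, B, A) array of target probabilities already
    multiplied by the loss mask — a one-hot array for maximum likelihood,
    the teacher's policies for distillation (the loss is the cross-entropy
    between target and model policies).  ``val_fn(model)`` returns the
    validation loss (or None to disable early stopping).  Deterministic
    given ``seed``.
    """
    n_loss = float(targets.sum())
    if n_loss == 0:
        raise ValueError("no trials enter the training loss")
    params = {k: Tensor(v, requires_grad=True)
              for k, v in init_params(spec, np.random.default_rng(seed)).items()}
    opt = Adam(params, lr=config.learning_rate)

    def eval_model() -> RNNModel:
        return RNNModel(spec, {k: t.data for k, t in params.items()})

    best = {k: t.data.copy() for k, t in params.items()}
    best_val, best_epoch, since = np.inf, 0, 0
    train_curve, val_curve = [], []
    for epoch in range(config.max_epochs):
        opt.zero_grad()
        logp = forward_log_policies(spec, params, xin, mask)
        loss = -(logp * targets).sum() / n_loss
        if l1 > 0:
            for key in rnn_mod.RECURRENT_KEYS:
                if key in params:
                    loss = loss + l1 * params[key].abs().sum()
        if not np.isfinite(loss.data):
            raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
        loss.backward()
        opt.step()
        if spec.architecture == "slin_symmetric":
            W = params["W"].data
            params["W"].data = (W + np.swapaxes(W, 1, 2)) / 2.0
        train_curve.append(float(loss.data))
        if val_fn is not None and epoch % config.val_every == 0:
            val_nll = val_fn(eval_model())
            val_curve.append(val_nll)
            if val_nll < best_val - 1e-12:
                best_val, best_epoch, since = val_nll, epoch, 0
                best = {k: t.data.copy() for k, t in params.items()}
            else:
                since += config.val_every
                if since >= config.patience:
                    break
    if val_fn is None:
        best = {k: t.data.copy() for k, t in params.items()}
        best_epoch = len(train_curve) - 1
    model = RNNModel(spec, best)
    log = {"train_curve": train_curve, "val_curve": val_curve,
           "best_epoch": best_epoch, "best_val": best_val, "l1": l1, "seed": seed}
    return model, log


def train_rnn(spec: RNNSpec, train_sessions: list[Session],
              val_sessions: list[Session] | None = None,
              config: FitConfig | None = None, seed: int = 0, l1: float = 0.0,
              train_loss_masks: list[np.ndarray] | None = None,
              val_loss_masks: list[np.ndarray] | None = None
              ) -> tuple[RNNModel, dict]:
    """Train a recurrent choice model by full-batch Adam.

    The loss is the trial-averaged NLL over the masked-in training trials
    plus ``l1`` times the L1 norm of the recurrent weights.  If validation
    sessions are given, training stops once the validation NLL has not
    improved for ``config.patience`` epochs and the best-validation
    checkpoint is returned; otherwise the final parameters are returned.
    """
    config = config or FitConfig()
    xin, actions, mask = rnn_mod._session_inputs(spec, train_sessions)
    loss_mask = mask.copy()
    if train_loss_masks is not None:
        for i, lm in enumerate(train_loss_masks):
            loss_mask[: len(lm), i] &= lm
    hot = np.zeros(actions.shape + (spec.n_actions,))
    np.put_along_axis(hot, actions[..., None], 1.0, axis=-1)
    hot *= loss_mask[..., None]
    val_fn = None
    if val_sessions is not None:
        def val_fn(model):
            return _nll_per_trial(model, val_sessions, val_loss_masks)
    return fit_sequence_model(spec, xin, mask, hot, val_fn, config, seed, l1)


def train_model(model_or_spec, train_sessions, val_sessions=None,
                config: FitConfig | None = None, seed: int = 0, **kw):
    """Dispatch to the RNN or cognitive fitting path."""
    if isinstance(model_or_spec, RNNSpec):
        return train_rnn(model_or_spec, train_sessions, val_sessions,
                         config, seed, **kw)
    if isinstance(model_or_spec, RNNModel):
        return train_rnn(model_or_spec.spec, train_sessions, val_sessions,
                         config, seed, **kw)
    if isinstance(model_or_spec, CognitiveModel):
        return fit_cognitive(model_or_spec, train_sessions, config, seed, **kw)
    raise TypeError(f"cannot train {type(model_or_spec)!r}")


# ---------------------------------------------------------------------------
# Nested cross-validation


@dataclass
class FoldResult:
    fold: int
    n_test_trials: int
    test_nll: float                 # trial-averaged
    hyper: dict = field(default_factory=dict)


@dataclass
class CVReport:
    """Per-outer-fold results; the aggregate is the trial-weighted mean."""

    folds: list[FoldResult]
    model_id: str = ""

    @property
    def aggregate(self) -> float:
        w = np.array([f.n_test_trials for f in self.folds], dtype=float)
        v = np.array([f.test_nll for f in self.folds])
        return float((w * v).sum() / w.sum())

    @property
    def fold_nlls(self) -> np.ndarray:
        return np.array([f.test_nll for f in sorted(self.folds, key=lambda f: f.fold)])


def _hyper_grid(model_or_spec, config: FitConfig):
    if isinstance(model_or_spec, (RNNSpec, RNNModel)):
        return [{"l1": l1, "seed": s} for l1 in config.l1_grid for s in config.seeds]
    return [{"seed": s} for s in config.seeds]


def nested_cv(model_or_spec, data: SessionData, partition: BlockPartition,
              config: FitConfig | None = None) -> CVReport:
    """Nested cross-validated predictive NLL for one model family.

    Outer loop: each fold once as the unseen test set.  Inner loop: every
    remaining fold serves once as validation (the rest train); the model
    with the best trial-weighted NLL on the held-in (train + validation)
    trials is selected and scored on the test fold.
    """
    config = config or FitConfig()
    n_folds = partition.n_folds
    is_rnn = isinstance(model_or_spec, (RNNSpec, RNNModel))
    spec = model_or_spec.spec if isinstance(model_or_spec, RNNModel) else model_or_spec
    results = []
    for test_fold in range(n_folds):
        test_sessions = partition.extract(data, partition.fold_blocks(test_fold))
        inner_folds = [f for f in range(n_folds) if f != test_fold]
        best_model, best_score, best_hyper = None, np.inf, None
        for val_fold in inner_folds:
            train_blocks = [b for b in partition.blocks
                            if b.fold not in (test_fold, val_fold)]
            train_sessions = partition.extract(data, train_blocks)
            val_sessions = partition.extract(data, partition.fold_blocks(val_fold))
            heldin = train_sessions + val_sessions
            for hyper in _hyper_grid(spec, config):
                if is_rnn:
                    fitted, _ = train_rnn(spec, train_sessions, val_sessions,
                                          config, seed=hyper["seed"], l1=hyper["l1"])
                else:
                    fitted, _ = fit_cognitive(spec, train_sessions, config,
                                              seed=hyper["seed"])
                score = _nll_per_trial(fitted, heldin)
                if score < best_score:
                    best_model, best_score = fitted, score
                    best_hyper = dict(hyper, val_fold=val_fold)
        test_nll = _nll_per_trial(best_model, test_sessions)
        n_test = int(sum(s.mask.sum() for s in test_sessions))
        results.append(FoldResult(test_fold, n_test, test_nll, best_hyper))
    model_id = getattr(model_or_spec, "id", None) or getattr(
        model_or_spec, "architecture", "model")
    return CVReport(results, model_id=str(model_id))


# ---------------------------------------------------------------------------
# Interspersed split protocol (single-block human tasks)


def interspersed_split(n_trials: int, counts: tuple[int, int, int], seed: int
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample disjoint train/validation/test trial index sets of exactly
    the requested sizes, without replacement."""
    n_train, n_val, n_test = counts
    if n_train + n_val + n_test > n_trials:
        raise ValueError(f"split counts {counts} exceed {n_trials} trials")
    perm = np.random.default_rng(seed).permutation(n_trials)
    train = np.sort(perm[:n_train])
    val = np.sort(perm[n_train:n_train + n_val])
    test = np.sort(perm[n_train + n_val:n_train + n_val + n_test])
    return train, val, test


def _index_mask(n: int, idx: np.ndarray) -> np.ndarray:
    m = np.zeros(n, dtype=bool)
    m[idx] = True
    return m


def fit_interspersed(model_or_spec, session: Session,
                     counts: tuple[int, int, int], config: FitConfig | None = None,
                     seed: int = 0, **train_kw) -> tuple[object, dict]:
    """Fit on a single block under the interspersed protocol.

    The whole sequence is always fed as input; the train/validation/test
    losses are computed on the sampled index sets.  Returns the fitted
    model and a report with the three per-trial NLLs.
    """
    config = config or FitConfig()
    tr, va, te = interspersed_split(session.n_trials, counts, seed)
    masks = {k: [_index_mask(session.n_trials, idx)] for k, idx in
             (("train", tr), ("val", va), ("test", te))}
    sessions = [session]
    if isinstance(model_or_spec, (RNNSpec, RNNModel)):
        spec = model_or_spec.spec if isinstance(model_or_spec, RNNModel) else model_or_spec
        fitted, log = train_rnn(spec, sessions, sessions, config, seed=seed,
                                train_loss_masks=masks["train"],
                                val_loss_masks=masks["val"], **train_kw)
    else:
        fitted, log = fit_cognitive(model_or_spec, sessions, config, seed=seed,
                                    loss_masks=masks["train"])
    report = {k: _nll_per_trial(fitted, sessions, m) for k, m in masks.items()}
    report["indices"] = {"train": tr, "val": va, "test": te}
    return fitted, {**log, **report}


# ---------------------------------------------------------------------------
# Behavioural dimensionality


def estimate_dimensionality(cv_reports: dict[int, CVReport | np.ndarray],
                            significance: float = 0.05) -> int:
    """Estimate d*, the number of dynamical variables needed.

    A candidate d significantly outperforms *all* models with fewer
    variables (paired one-sided t-tests of per-fold NLLs, no correction);
    d* is the largest candidate — equivalently the smallest d that beats
    all smaller models while no larger model does so as well.  If no model
    improves on the simplest one, d* is the smallest d examined.
    """
    ds = sorted(cv_reports)
    nlls = {}
    for d in ds:
        rep = cv_reports[d]
        nlls[d] = rep.fold_nlls if isinstance(rep, CVReport) else np.asarray(rep, float)
    n_folds = {len(v) for v in nlls.values()}
    if len(n_folds) != 1 or n_folds.pop() < 2:
        raise ValueError("need aligned per-fold NLLs for >= 2 folds")

    def beats(a: int, b: int) -> bool:
        diff = nlls[a] - nlls[b]
        if np.allclose(diff, 0.0):
            return False
        p = stats.ttest_rel(nlls[a], nlls[b], alternative="less").pvalue
        return bool(p < significance)

    candidates = [d for d in ds[1:] if all(beats(d, smaller)
                                           for smaller in ds if smaller < d)]
    return max(candidates) if candidates else ds[0]
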