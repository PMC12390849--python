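"""Teacher-student knowledge distillation for individual-subject models.

A *teacher* network — a 20-unit GRU that receives, besides the usual trial
input, a learned subject-embedding vector (a linear projection of the
subject's one-hot code) — is trained on pooled multi-subject data to
predict choices.  A tiny *student* network is then trained on one
subject's data to match the teacher's output probabilities (cross-entropy
between teacher and student policies), transferring group-level structure
into an interpretable per-subject model.

The student's training set is augmented by the task's symmetry: flipping
the action codes and/or the second-stage state codes yields four copies of
every block.  The teacher itself is trained on the raw data only, so real
asymmetries (such as a side bias) remain visible to it and can be passed
on to students.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import rnn as rnn_mod
from .autodiff import Adam, Tensor, concat, log_softmax
from .cognitive import PolicyTrace, softmax_policy
from .fitting import FitConfig, LeakageError, fit_sequence_model, \
    negative_log_likelihood
from .rnn import RNNModel, RNNSpec, gru_step
from .task_data import Session, SessionData

__all__ = [
    "TeacherSpec",
    "TeacherModel",
    "train_teacher",
    "teacher_forward",
    "distillation_loss",
    "augment_by_symmetry",
    "train_student",
    "distill_pipeline",
    "cross_subject_folds",
    "distill_cross_subject",
]


class UnsupportedTaskError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Teacher network


@dataclass
class TeacherSpec:
    subjects: list[str]
    d: int = 20
    embed_width: int = 2
    n_actions: int = 2
    input_dim: int = 3
    continuous_reward: bool = False

    def __post_init__(self) -> None:
        self.index = {s: i for i, s in enumerate(self.subjects)}
        if len(self.index) != len(self.subjects):
            raise ValueError("duplicate subject ids")


def _teacher_init(spec: TeacherSpec, rng: np.random.Generator) -> dict:
    scale = 1.0 / np.sqrt(spec.d)
    n_in = spec.input_dim + spec.embed_width
    def u(*shape):
        return rng.uniform(-scale, scale, size=shape)
    p = {}
    for g in ("r", "z", "n"):
        p[f"Wi{g}"] = u(n_in, spec.d)
        p[f"Wh{g}"] = u(spec.d, spec.d)
        p[f"bi{g}"] = u(spec.d)
        p[f"bh{g}"] = u(spec.d)
    p["E"] = u(len(spec.subjects), spec.embed_width)
    p["beta"] = u(spec.d, spec.n_actions)
    return p


class TeacherModel:
    """Subject-embedding GRU bound to trained parameters."""

    def __init__(self, spec: TeacherSpec, params: dict[str, np.ndarray]):
        self.spec = spec
        self.params = params

    def _inputs(self, sessions: list[Session], subject_ids: list[str]):
        base = RNNSpec(architecture="gru", d=self.spec.d, encoding="vector",
                       n_actions=self.spec.n_actions,
                       continuous_reward=self.spec.continuous_reward)
        xin, actions, mask = rnn_mod._session_inputs(base, sessions)
        try:
            idx = np.array([self.spec.index[s] for s in subject_ids])
        except KeyError as exc:
            raise KeyError(f"unknown subject id {exc.args[0]!r}") from exc
        return xin, actions, mask, idx

    def policy_traces(self, sessions: list[Session],
                      subject_ids: list[str]) -> PolicyTrace:
        xin, _, mask, idx = self._inputs(sessions, subject_ids)
        T, B = mask.shape
        e = self.params["E"][idx]                       # (B, embed)
        h = np.zeros((B, self.spec.d))
        probs = np.empty((T, B, self.spec.n_actions))
        for t in range(T):
            probs[t] = softmax_policy(h @ self.params["beta"])
            x_full = np.concatenate([xin[t], e], axis=-1)
            h_new = gru_step(self.params, h, x_full)
            h = np.where(mask[t][:, None], h_new, h)
        return PolicyTrace([probs[: s.n_trials, i, :]
                            for i, s in enumerate(sessions)])


def teacher_forward(data: list[SessionData], model: TeacherModel
                    ) -> dict[str, PolicyTrace]:
    """Teacher policies for every subject in ``data``."""
    out = {}
    for subject in data:
        out[subject.subject_id] = model.policy_traces(
            subject.sessions, [subject.subject_id] * len(subject.sessions))
    return out


def _teacher_loss_forward(spec: TeacherSpec, params: dict[str, Tensor],
                          xin, mask, idx) -> Tensor:
    T, B = mask.shape
    e = params["E"][idx]                                # gathers rows, trainable
    h = Tensor(np.zeros((B, spec.d)))
    logps = []
    import tinyrnn.autodiff as ad
    for t in range(T):
        logps.append(log_softmax(h @ params["beta"]))
        x = concat([Tensor(xin[t]), e], axis=-1)
        r = ad.sigmoid(x @ params["Wir"] + params["bir"]
                       + h @ params["Whr"] + params["bhr"])
        z = ad.sigmoid(x @ params["Wiz"] + params["biz"]
                       + h @ params["Whz"] + params["bhz"])
        n = ad.tanh(x @ params["Win"] + params["bin"]
                    + r * (h @ params["Whn"] + params["bhn"]))
        h_new = (1.0 - z) * n + z * h
        m = mask[t][:, None].astype(float)
        h = h_new * m + h * (1.0 - m)
    return ad.stack(logps, axis=0)


def train_teacher(train_blocks: list[tuple[str, Session]],
                  val_blocks: list[tuple[str, Session]],
                  spec: TeacherSpec, config: FitConfig | None = None,
                  seed: int = 0, l1: float = 0.0) -> tuple[TeacherModel, dict]:
    """Train the teacher on (subject id, block) pairs with early stopping
    on the validation blocks."""
    config = config or FitConfig()
    subjects_tr = [s for s, _ in train_blocks]
    sessions_tr = [b for _, b in train_blocks]
    model0 = TeacherModel(spec, _teacher_init(spec, np.random.default_rng(seed)))
    xin, actions, mask, idx = model0._inputs(sessions_tr, subjects_tr)
    hot = np.zeros(actions.shape + (spec.n_actions,))
    np.put_along_axis(hot, actions[..., None], 1.0, axis=-1)
    hot *= mask[..., None]
    n_loss = float(mask.sum())

    params = {k: Tensor(v, requires_grad=True) for k, v in model0.params.items()}
    opt = Adam(params, lr=config.learning_rate)
    val_sessions = [b for _, b in val_blocks]
    val_subjects = [s for s, _ in val_blocks]

    def val_nll(np_params) -> float:
        m = TeacherModel(spec, np_params)
        trace = m.policy_traces(val_sessions, val_subjects)
        tot, cnt = negative_log_likelihood(trace, val_sessions)
        return tot / max(cnt, 1)

    best = {k: t.data.copy() for k, t in params.items()}
    best_val, since = np.inf, 0
    curve = []
    for epoch in range(config.max_epochs):
        opt.zero_grad()
        logp = _teacher_loss_forward(spec, params, xin, mask, idx)
        loss = -(logp * hot).sum() / n_loss
        if l1 > 0:
            for key in ("Whr", "Whz", "Whn"):
                loss = loss + l1 * params[key].abs().sum()
        if not np.isfinite(loss.data):
            raise FloatingPointError("non-finite teacher loss")
        loss.backward()
        opt.step()
        curve.append(float(loss.data))
        if epoch % config.val_every == 0:
            v = val_nll({k: t.data for k, t in params.items()})
            if v < best_val - 1e-12:
                best_val, since = v, 0
                best = {k: t.data.copy() for k, t in params.items()}
            else:
                since += config.val_every
                if since >= config.patience:
                    break
    return TeacherModel(spec, best), {"best_val": best_val, "train_curve": curve}


# ---------------------------------------------------------------------------
# Distillation loss


def distillation_loss(teacher: PolicyTrace, student: PolicyTrace,
                      sessions: list[Session] | None = None) -> float:
    """Cross-entropy between teacher and student policies, summed over
    masked-in trials: ``-sum_t sum_a pT(a) log pS(a)``."""
    if len(teacher.per_session) != len(student.per_session):
        raise ValueError("teacher and student traces have different session counts")
    total = 0.0
    for i, (pt, ps) in enumerate(zip(teacher.per_session, student.per_session)):
        if pt.shape != ps.shape:
            raise ValueError(f"misaligned traces in session {i}: "
                             f"{pt.shape} vs {ps.shape}")
        m = sessions[i].mask if sessions is not None else np.ones(len(pt), bool)
        total += float(-(pt[m] * np.log(np.maximum(ps[m], 1e-12))).sum())
    return total


# ---------------------------------------------------------------------------
# Symmetry augmentation


def _flip_session(sess: Session, flip_action: bool, flip_state: bool,
                  tag: str) -> Session:
    return Session(
        f"{sess.session_id}{tag}",
        (1 - sess.action) if flip_action else sess.action.copy(),
        (1 - sess.state) if flip_state else sess.state.copy(),
        sess.reward.copy(),
        sess.mask.copy(),
        None if sess.action2 is None else sess.action2.copy(),
        None if sess.block is None else sess.block.copy(),
    )


def augment_by_symmetry(data: SessionData, task_config) -> SessionData:
    """Original plus action-flipped, state-flipped and both-flipped copies
    of every block (4x the data); rewards and block structure unchanged.

    Requires a two-action, two-state task whose second-stage state is an
    independent outcome dimension (two-stage family); tasks without this
    symmetry are rejected.
    """
    if task_config.n_actions != 2 or task_config.n_states != 2 \
            or task_config.transition_types is None:
        raise UnsupportedTaskError(
            "symmetry augmentation requires a two-action, two-state task "
            "with probabilistic transitions")
    flips = [(False, False, ""), (True, False, "_fa"),
             (False, True, "_fs"), (True, True, "_fas")]
    sessions = [_flip_session(s, fa, fs, tag)
                for fa, fs, tag in flips for s in data.sessions]
    return SessionData(data.subject_id, sessions)


# ---------------------------------------------------------------------------
# Student training


def train_student(spec: RNNSpec, train_sessions: list[Session],
                  teacher_train: PolicyTrace,
                  val_sessions: list[Session] | None = None,
                  teacher_val: PolicyTrace | None = None,
                  config: FitConfig | None = None, seed: int = 0,
                  l1: float = 0.0) -> tuple[RNNModel, dict]:
    """Train a tiny student against teacher probability targets; early
    stopping uses the distillation loss on the validation sessions."""
    config = config or FitConfig()
    xin, _, mask = rnn_mod._session_inputs(spec, train_sessions)
    T, B = mask.shape
    targets = np.zeros((T, B, spec.n_actions))
    for i, pt in enumerate(teacher_train.per_session):
        targets[: len(pt), i, :] = pt
    targets *= mask[..., None]
    val_fn = None
    if val_sessions is not None:
        n_val = sum(s.mask.sum() for s in val_sessions)
        def val_fn(model):
            return distillation_loss(teacher_val, model.policy_traces(val_sessions),
                                     val_sessions) / max(n_val, 1)
    return fit_sequence_model(spec, xin, mask, targets, val_fn, config, seed, l1)


# ---------------------------------------------------------------------------
# Full pipelines


def _chunk_session(sess: Session, chunk: int) -> list[Session]:
    bounds = list(range(0, sess.n_trials, chunk)) + [sess.n_trials]
    if len(bounds) > 2 and bounds[-1] - bounds[-2] < chunk / 2:
        bounds.pop(-2)
    return [sess.slice(a, b) for a, b in zip(bounds[:-1], bounds[1:])]


def _split_blocks(blocks: list, fractions: tuple[float, ...], seed: int):
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(blocks))
    cuts = np.cumsum(np.round(np.array(fractions) * len(blocks)).astype(int))[:-1]
    groups = np.split(order, cuts)
    return [[blocks[i] for i in g] for g in groups]


@dataclass
class DistillReport:
    student_test_nll: float
    teacher_test_nll: float
    embed_width: int
    n_m_train: int
    logs: dict = field(default_factory=dict)


def distill_pipeline(group: list[SessionData], target_subject: str,
                     task_config, student_spec: RNNSpec | None = None,
                     teacher_d: int = 20, embed_grid: tuple[int, ...] = (1, 2),
                     config: FitConfig | None = None, seed: int = 0,
                     m_train_trials: int | None = None, chunk: int = 100,
                     l1: float = 1e-4) -> tuple[RNNModel, DistillReport]:
    """Distil group knowledge into one subject's tiny model.

    The target subject's trials are chunked into blocks; 25% are held out
    as the M-test set and the rest split 90/10 into M-training/M-validation
    (optionally subsampled to ``m_train_trials``).  Every other subject's
    blocks are split 90/10 (O-training/O-validation).  The teacher (hidden
    size ``teacher_d``; embedding width selected on M-validation) trains on
    M+O-training with early stopping on M+O-validation.  The student trains
    on symmetry-augmented M-training blocks against teacher policies, is
    selected on M-validation, and is evaluated on M-test against actual
    choices.
    """
    config = config or FitConfig()
    subjects = [d.subject_id for d in group]
    if target_subject not in subjects:
        raise KeyError(f"unknown target subject {target_subject!r}")
    m_data = next(d for d in group if d.subject_id == target_subject)
    m_blocks = [c for s in m_data.sessions for c in _chunk_session(s, chunk)]
    m_test, m_rest = _split_blocks(m_blocks, (0.25, 0.75), seed)
    if m_train_trials is not None:
        rng = np.random.default_rng(seed + 1)
        order = rng.permutation(len(m_rest))
        kept, total = [], 0
        for i in order:
            if total >= m_train_trials:
                break
            kept.append(m_rest[i])
            total += m_rest[i].n_trials
        m_rest = kept
    m_val, m_train = _split_blocks(m_rest, (0.1, 0.9), seed + 2)
    if not m_train:
        raise ValueError("no M-training trials available")

    o_train, o_val = [], []
    for d in group:
        if d.subject_id == target_subject:
            continue
        blocks = [c for s in d.sessions for c in _chunk_session(s, chunk)]
        ov, otr = _split_blocks(blocks, (0.1, 0.9), seed + 3)
        o_train += [(d.subject_id, b) for b in otr]
        o_val += [(d.subject_id, b) for b in ov]

    teacher_train_blocks = [(target_subject, b) for b in m_train] + o_train
    test_ids = {id(b) for b in m_test}
    if any(id(b) in test_ids for _, b in teacher_train_blocks):
        raise LeakageError("teacher training saw an M-test block")
    teacher_val_blocks = [(target_subject, b) for b in m_val] + o_val

    best_teacher, best_width, best_mval = None, None, np.inf
    tlogs = {}
    for width in embed_grid:
        tspec = TeacherSpec(subjects=subjects, d=teacher_d, embed_width=width,
                            n_actions=task_config.n_actions)
        teacher, tlog = train_teacher(teacher_train_blocks, teacher_val_blocks,
                                      tspec, config, seed=seed, l1=l1)
        trace = teacher.policy_traces(m_val, [target_subject] * len(m_val))
        tot, cnt = negative_log_likelihood(trace, m_val)
        mval = tot / max(cnt, 1)
        tlogs[width] = {"m_val_nll": mval, **{k: v for k, v in tlog.items()
                                              if k == "best_val"}}
        if mval < best_mval:
            best_teacher, best_width, best_mval = teacher, width, mval

    aug = augment_by_symmetry(SessionData(target_subject, m_train), task_config)
    t_targets_train = best_teacher.policy_traces(
        aug.sessions, [target_subject] * len(aug.sessions))
    t_targets_val = best_teacher.policy_traces(
        m_val, [target_subject] * len(m_val))

    student_spec = student_spec or rnn_mod.default_spec(
        1, states_informative=task_config.transition_types is not None,
        n_actions=task_config.n_actions)
    student, slog = train_student(student_spec, aug.sessions, t_targets_train,
                                  m_val, t_targets_val, config, seed=seed, l1=l1)

    s_tot, s_cnt = negative_log_likelihood(student.policy_traces(m_test), m_test)
    t_trace = best_teacher.policy_traces(m_test, [target_subject] * len(m_test))
    t_tot, t_cnt = negative_log_likelihood(t_trace, m_test)
    report = DistillReport(
        student_test_nll=s_tot / max(s_cnt, 1),
        teacher_test_nll=t_tot / max(t_cnt, 1),
        embed_width=best_width,
        n_m_train=sum(b.n_trials for b in m_train),
        logs={"teacher": tlogs, "student": {"best_epoch": slog["best_epoch"]},
              "m_splits": {"train": len(m_train), "val": len(m_val),
                           "test": len(m_test)}},
    )
    report.logs["m_sets"] = {"train": m_train, "val": m_val, "test": m_test}
    report.logs["teacher_model"] = best_teacher
    report.logs["teacher_targets"] = {"train": t_targets_train,
                                      "val": t_targets_val,
                                      "aug_sessions": aug.sessions}
    return student, report


def cross_subject_folds(subject_ids: list[str], n_folds: int = 6,
                        seed: int = 0) -> list[list[str]]:
    """Deal subjects into folds for the cross-subject (zero-shot) protocol:
    the teacher trains on all but one fold of subjects and students for
    held-out subjects are fitted purely against teacher policies."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subject_ids))
    folds: list[list[str]] = [[] for _ in range(n_folds)]
    for i, j in enumerate(order):
        folds[i % n_folds].append(subject_ids[j])
    return folds


def distill_cross_subject(group: list[SessionData], test_fold: int,
                          task_config, student_spec: RNNSpec | None = None,
                          teacher_d: int = 20, embed_width: int = 2,
                          n_folds: int = 6, config: FitConfig | None = None,
                          seed: int = 0, l1: float = 1e-4,
                          chunk: int = 100) -> dict:
    """Zero-shot distillation: train the teacher on all subjects outside
    ``test_fold`` (90/10 train/validation within each subject's blocks);
    for every held-out subject, train a student on their action-augmented
    blocks to predict the teacher's policies, validate it against the
    teacher on the original block, and test it against the subject's
    actual choices.

    Held-out subjects get a zero embedding (their one-hot rows were never
    trained), so the teacher acts as a group-average policy for them.
    Returns ``{subject_id: {"student", "test_nll", "teacher_test_nll"}}``.
    """
    config = config or FitConfig()
    subjects = [d.subject_id for d in group]
    folds = cross_subject_folds(subjects, n_folds, seed)
    if not (0 <= test_fold < n_folds):
        raise ValueError(f"test_fold must lie in [0, {n_folds})")
    held_out = set(folds[test_fold])
    train_blocks, val_blocks = [], []
    for d in group:
        if d.subject_id in held_out:
            continue
        blocks = [c for s in d.sessions for c in _chunk_session(s, chunk)]
        ov, otr = _split_blocks(blocks, (0.1, 0.9), seed + 1)
        if not ov:               # single-block subject: reuse it for both
            ov = otr[:1]
        train_blocks += [(d.subject_id, b) for b in otr]
        val_blocks += [(d.subject_id, b) for b in ov]
    tspec = TeacherSpec(subjects=subjects, d=teacher_d,
                        embed_width=embed_width,
                        n_actions=task_config.n_actions)
    teacher, _ = train_teacher(train_blocks, val_blocks, tspec, config,
                               seed=seed, l1=l1)
    teacher.params["E"][[tspec.index[s] for s in held_out]] = 0.0

    student_spec = student_spec or rnn_mod.default_spec(
        1, states_informative=task_config.transition_types is not None,
        n_actions=task_config.n_actions)
    out = {}
    for d in group:
        sid = d.subject_id
        if sid not in held_out:
            continue
        aug = augment_by_symmetry(d, task_config)
        targets = teacher.policy_traces(aug.sessions,
                                        [sid] * len(aug.sessions))
        val_targets = teacher.policy_traces(d.sessions,
                                            [sid] * len(d.sessions))
        student, _ = train_student(student_spec, aug.sessions, targets,
                                   list(d.sessions), val_targets, config,
                                   seed=seed, l1=l1)
        tot, cnt = negative_log_likelihood(
            student.policy_traces(d.sessions), list(d.sessions))
        t_tot, t_cnt = negative_log_likelihood(
            teacher.policy_traces(d.sessions, [sid] * len(d.sessions)),
            list(d.sessions))
        out[sid] = {"student": student, "test_nll": tot / max(cnt, 1),
                    "teacher_test_nll": t_tot / max(t_cnt, 1)}
    return out
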