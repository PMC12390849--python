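"""Canonical behavioural data model shared by every other module.

A *session* is an ordered run of trials from one subject: on each trial the
subject emits an action, (in two-stage tasks) arrives at a second-stage
state, and receives a reward.  Missing trials are kept in place with
``mask=False`` and placeholder codes so that trial indices stay aligned; they
are excluded from every likelihood.

The on-disk format is a plain columnar text file (CSV with header), one row
per trial, with columns ``subject, session, trial, action, state, reward,
mask`` plus optional ``action2`` (second-stage action in the original
two-stage task) and ``block`` (block label emitted by the simulators).
Action and state codes are 0-based integers; code 0 plays the role of the
first action/state (A1/S1) throughout the documentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Session",
    "SessionData",
    "Block",
    "BlockPartition",
    "read_sessions",
    "read_all_subjects",
    "write_sessions",
    "segment_blocks",
]

PLACEHOLDER = -1  # code stored on masked-out trials


class DataError(ValueError):
    """Malformed or out-of-range behavioural data."""


@dataclass
class Session:
    """One session of consecutive trials.

    ``block`` holds an integer block label per trial when the data came from
    a simulator (or was annotated); ``None`` otherwise.
    """

    session_id: str
    action: np.ndarray          # int, shape (T,)
    state: np.ndarray           # int, shape (T,)
    reward: np.ndarray          # float, shape (T,)
    mask: np.ndarray            # bool, shape (T,)
    action2: np.ndarray | None = None   # second-stage action, original two-stage task
    block: np.ndarray | None = None     # block label per trial (simulator output)
    extras: dict | None = None          # simulator ground truth (not serialized)

    def __post_init__(self) -> None:
        self.action = np.asarray(self.action, dtype=int)
        self.state = np.asarray(self.state, dtype=int)
        self.reward = np.asarray(self.reward, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.action2 is not None:
            self.action2 = np.asarray(self.action2, dtype=int)
        if self.block is not None:
            self.block = np.asarray(self.block, dtype=int)
        n = len(self.action)
        for name in ("state", "reward", "mask"):
            if len(getattr(self, name)) != n:
                raise DataError(f"column '{name}' length mismatch in session {self.session_id}")

    @property
    def n_trials(self) -> int:
        return len(self.action)

    def slice(self, start: int, stop: int) -> "Session":
        return Session(
            self.session_id,
            self.action[start:stop],
            self.state[start:stop],
            self.reward[start:stop],
            self.mask[start:stop],
            None if self.action2 is None else self.action2[start:stop],
            None if self.block is None else self.block[start:stop],
            None if self.extras is None else
            {k: v[start:stop] for k, v in self.extras.items()},
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Session):
            return NotImplemented
        same_opt = (
            (self.action2 is None) == (other.action2 is None)
            and (self.action2 is None or np.array_equal(self.action2, other.action2))
            and (self.block is None) == (other.block is None)
            and (self.block is None or np.array_equal(self.block, other.block))
        )
        return (
            self.session_id == other.session_id
            and np.array_equal(self.action, other.action)
            and np.array_equal(self.state, other.state)
            and np.allclose(self.reward, other.reward, atol=1e-9)
            and np.array_equal(self.mask, other.mask)
            and same_opt
        )


@dataclass
class SessionData:
    """Per-subject collection of sessions; the universal input."""

    subject_id: str
    sessions: list[Session] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return sum(s.n_trials for s in self.sessions)

    @property
    def n_masked_in(self) -> int:
        return int(sum(s.mask.sum() for s in self.sessions))

    def validate(self, task_config) -> "SessionData":
        """Check codes against a task configuration (duck-typed: needs
        ``n_actions``, ``n_states`` and ``reward_range`` attributes).

        Masked-out trials may carry placeholder codes and are not checked.
        """
        lo, hi = task_config.reward_range
        for s in self.sessions:
            m = s.mask
            if np.any((s.action[m] < 0) | (s.action[m] >= task_config.n_actions)):
                bad = int(np.flatnonzero((s.action < 0) | (s.action >= task_config.n_actions))[0])
                raise DataError(
                    f"action code {s.action[bad]} out of range for "
                    f"{task_config.n_actions}-action task (session {s.session_id}, trial {bad})"
                )
            if np.any((s.state[m] < 0) | (s.state[m] >= task_config.n_states)):
                raise DataError(f"state code out of range in session {s.session_id}")
            if np.any((s.reward[m] < lo - 1e-9) | (s.reward[m] > hi + 1e-9)):
                raise DataError(f"reward outside [{lo}, {hi}] in session {s.session_id}")
        return self

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SessionData):
            return NotImplemented
        return self.subject_id == other.subject_id and self.sessions == other.sessions


# ---------------------------------------------------------------------------
# Readers / writers


def _to_frame(data: SessionData) -> pd.DataFrame:
    rows = []
    for s in data.sessions:
        df = pd.DataFrame(
            {
                "subject": data.subject_id,
                "session": s.session_id,
                "trial": np.arange(s.n_trials),
                "action": s.action,
                "state": s.state,
                "reward": s.reward,
                "mask": s.mask.astype(int),
            }
        )
        if s.action2 is not None:
            df["action2"] = s.action2
        if s.block is not None:
            df["block"] = s.block
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def write_sessions(data: SessionData | Sequence[SessionData], path) -> None:
    """Write one or several subjects to a session CSV."""
    if isinstance(data, SessionData):
        data = [data]
    pd.concat([_to_frame(d) for d in data], ignore_index=True).to_csv(path, index=False)


_REQUIRED = ["subject", "session", "trial", "action", "state", "reward", "mask"]


def _frame_to_subject(sub: str, df: pd.DataFrame) -> SessionData:
    sessions = []
    for sid, g in df.groupby("session", sort=False):
        g = g.sort_values("trial")
        trials = g["trial"].to_numpy()
        if not np.array_equal(trials, np.arange(len(trials))):
            raise DataError(f"non-contiguous trial indices in session {sid} of subject {sub}")
        sessions.append(
            Session(
                str(sid),
                g["action"].to_numpy(),
                g["state"].to_numpy(),
                g["reward"].to_numpy(),
                g["mask"].to_numpy().astype(bool),
                g["action2"].to_numpy() if "action2" in g else None,
                g["block"].to_numpy() if "block" in g else None,
            )
        )
    return SessionData(str(sub), sessions)


def read_all_subjects(path, task_config=None) -> list[SessionData]:
    """Read every subject in a session CSV, in file order."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DataError(f"cannot parse session file {path}: {exc}") from exc
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise DataError(f"session file {path} lacks columns {missing}")
    for col in ("trial", "action", "state"):
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            row = int(bad[0]) if len(bad) else 0
            raise DataError(f"malformed value in column '{col}' at row {row} of {path}")
    out = [_frame_to_subject(sub, g) for sub, g in df.groupby("subject", sort=False)]
    if task_config is not None:
        for d in out:
            d.validate(task_config)
    return out


def read_sessions(path, task_config=None) -> SessionData:
    """Read a single-subject session CSV (validated against ``task_config``)."""
    subjects = read_all_subjects(path, task_config)
    if len(subjects) != 1:
        raise DataError(f"expected one subject in {path}, found {len(subjects)}")
    return subjects[0]


# ---------------------------------------------------------------------------
# Block segmentation and fold assignment


@dataclass(frozen=True)
class Block:
    session_index: int
    start: int          # inclusive trial index within the session
    end: int            # exclusive
    fold: int

    @property
    def n_trials(self) -> int:
        return self.end - self.start


@dataclass
class BlockPartition:
    """Disjoint consecutive-trial blocks covering all trials, dealt to folds."""

    blocks: list[Block]
    target_len: int
    n_folds: int

    def fold_blocks(self, fold: int) -> list[Block]:
        return [b for b in self.blocks if b.fold == fold]

    def extract(self, data: SessionData, blocks: Iterable[Block]) -> list[Session]:
        return [data.sessions[b.session_index].slice(b.start, b.end) for b in blocks]


class ConfigurationError(ValueError):
    pass


def _session_cuts(n: int, target_len: int) -> list[tuple[int, int]]:
    """Cut one session into consecutive blocks of roughly ``target_len``.

    A trailing fragment shorter than half the target is merged into the
    preceding block of the same session (a lone short session stays whole).
    """
    bounds = list(range(0, n, target_len)) + [n]
    cuts = [(a, b) for a, b in zip(bounds[:-1], bounds[1:])]
    if len(cuts) > 1 and (cuts[-1][1] - cuts[-1][0]) < target_len / 2:
        last = cuts.pop()
        prev = cuts.pop()
        cuts.append((prev[0], last[1]))
    return cuts


def segment_blocks(
    data: SessionData, target_len: int = 150, n_folds: int = 10, seed: int = 0
) -> BlockPartition:
    """Divide sessions into non-overlapping blocks of ~``target_len`` trials
    and deal them into ``n_folds`` folds.

    Blocks never span session boundaries.  Fold assignment shuffles the
    blocks once with ``seed`` and deals them round-robin, balancing temporal
    structure across folds.
    """
    if target_len < 2:
        raise ConfigurationError("target_len must be >= 2")
    if n_folds < 2:
        raise ConfigurationError("n_folds must be >= 2")
    if not data.sessions or data.n_trials == 0:
        raise ConfigurationError("empty SessionData")
    spans = [
        (si, a, b)
        for si, s in enumerate(data.sessions)
        for a, b in _session_cuts(s.n_trials, target_len)
    ]
    if len(spans) < n_folds:
        raise ConfigurationError(
            f"only {len(spans)} blocks for {n_folds} folds; lower n_folds or target_len"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(spans))
    blocks = [
        Block(spans[j][0], spans[j][1], spans[j][2], fold=i % n_folds)
        for i, j in enumerate(order)
    ]
    blocks.sort(key=lambda b: (b.session_index, b.start))
    return BlockPartition(blocks, target_len, n_folds)
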