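import numpy as np
import pytest
from scipy import optimize

from tinyrnn.cognitive import CognitiveAgent, PolicyTrace, make_model
from tinyrnn.distillation import (TeacherModel, TeacherSpec,
                                  UnsupportedTaskError, augment_by_symmetry,
                                  cross_subject_folds, distillation_loss,
                                  teacher_forward, train_teacher)
from tinyrnn.fitting import FitConfig, negative_log_likelihood
from tinyrnn.task_data import Session, SessionData
from tinyrnn.task_envs import (reversal_bartolo, simulate_task,
                               three_armed_reversal, two_stage_miller)


@pytest.fixture(scope="module")
def two_stage_block():
    agent = CognitiveAgent(make_model("mf1"), {"alpha": 0.5, "beta": 3.0})
    return simulate_task(two_stage_miller(), agent, 200, seed=41)


class TestDistillationLoss:
    def _trace(self, probs):
        return PolicyTrace([np.asarray(probs)])

    def test_self_distillation_equals_entropy(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(2), size=50)
        loss = distillation_loss(self._trace(p), self._trace(p))
        entropy = -(p * np.log(p)).sum()
        assert loss == pytest.approx(entropy)

    def test_one_hot_teacher_reduces_to_nll(self):
        rng = np.random.default_rng(1)
        acts = rng.integers(0, 2, size=30)
        hot = np.eye(2)[acts]
        ps = rng.dirichlet(np.ones(2), size=30)
        loss = distillation_loss(self._trace(hot), self._trace(ps))
        sess = [Session("s", acts, acts, np.zeros(30), np.ones(30, bool))]
        nll, _ = negative_log_likelihood(self._trace(ps), sess)
        assert loss == pytest.approx(nll)

    def test_gibbs_minimum_at_teacher(self):
        """Minimizing the distillation loss over an unconstrained student
        recovers the teacher's probabilities exactly (3-trial toy)."""
        teacher = np.array([[0.7, 0.3], [0.2, 0.8], [0.5, 0.5]])

        def loss_of(logits):
            z = logits.reshape(3, 2)
            z = z - z.max(axis=1, keepdims=True)
            p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
            return distillation_loss(self._trace(teacher), self._trace(p))

        res = optimize.minimize(loss_of, np.zeros(6), method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-14,
                                         "maxiter": 5000})
        z = res.x.reshape(3, 2)
        p = np.exp(z - z.max(1, keepdims=True))
        p /= p.sum(1, keepdims=True)
        assert np.abs(p - teacher).max() < 1e-4
        entropy = -(teacher * np.log(teacher)).sum()
        assert res.fun == pytest.approx(entropy, abs=1e-8)

    def test_loss_bounded_below_by_entropy_random_traces(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            pt = rng.dirichlet(np.ones(2), size=40)
            ps = rng.dirichlet(np.ones(2), size=40)
            loss = distillation_loss(PolicyTrace([pt]), PolicyTrace([ps]))
            entropy = -(pt * np.log(pt)).sum()
            assert loss >= entropy - 1e-12

    def test_misaligned_traces_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            distillation_loss(self._trace(np.ones((5, 2)) / 2),
                              self._trace(np.ones((6, 2)) / 2))


class TestAugmentation:
    def test_four_copies_with_flipped_codes(self, two_stage_block):
        aug = augment_by_symmetry(two_stage_block, two_stage_miller())
        assert len(aug.sessions) == 4 * len(two_stage_block.sessions)
        orig = two_stage_block.sessions[0]
        fa = aug.sessions[1]           # action-flipped copy
        assert np.array_equal(fa.action, 1 - orig.action)
        assert np.array_equal(fa.state, orig.state)
        assert np.array_equal(fa.reward, orig.reward)
        fs = aug.sessions[2]           # state-flipped copy
        assert np.array_equal(fs.state, 1 - orig.state)
        assert np.array_equal(fs.action, orig.action)

    def test_group_closure(self, two_stage_block):
        """Augmenting twice then deduplicating yields the same 4 variants."""
        cfg = two_stage_miller()
        once = augment_by_symmetry(two_stage_block, cfg)
        twice = augment_by_symmetry(once, cfg)

        def key(s):
            return (tuple(s.action), tuple(s.state), tuple(s.reward))

        assert {key(s) for s in twice.sessions} == {key(s)
                                                    for s in once.sessions}
        assert len({key(s) for s in once.sessions}) == 4

    def test_unsupported_tasks_rejected(self):
        agent = CognitiveAgent(make_model("mf3"))
        data = simulate_task(three_armed_reversal(), agent, 50, seed=1)
        with pytest.raises(UnsupportedTaskError):
            augment_by_symmetry(data, three_armed_reversal())
        rev = simulate_task(reversal_bartolo(),
                            CognitiveAgent(make_model("mf1")), 50, seed=1)
        with pytest.raises(UnsupportedTaskError):
            augment_by_symmetry(rev, reversal_bartolo())

    def test_symmetric_model_invariant_nll(self, two_stage_block):
        """An action/state-symmetric model assigns every augmented copy the
        same likelihood."""
        aug = augment_by_symmetry(two_stage_block, two_stage_miller())
        model = make_model("mf1")
        params = {"alpha": 0.4, "beta": 2.0}
        from tinyrnn.cognitive import policy_traces
        nlls = []
        for sess in aug.sessions:
            trace = policy_traces(model, params, [sess])
            tot, cnt = negative_log_likelihood(trace, [sess])
            nlls.append(tot / cnt)
        assert np.ptp(nlls) < 1e-12


class TestTeacher:
    def _spec(self, subjects, width=2, d=6):
        return TeacherSpec(subjects=subjects, d=d, embed_width=width)

    def test_identical_subjects_identical_traces(self, two_stage_block):
        spec = self._spec(["a", "b"])
        model = TeacherModel(spec, _random_teacher_params(spec, seed=0))
        model.params["E"][1] = model.params["E"][0]
        sessions = two_stage_block.sessions
        ta = model.policy_traces(sessions, ["a"] * len(sessions))
        tb = model.policy_traces(sessions, ["b"] * len(sessions))
        assert np.array_equal(ta.per_session[0], tb.per_session[0])

    def test_zero_embedding_ignores_identity(self, two_stage_block):
        spec = self._spec(["a", "b"])
        model = TeacherModel(spec, _random_teacher_params(spec, seed=1))
        model.params["E"][:] = 0.0
        sessions = two_stage_block.sessions
        ta = model.policy_traces(sessions, ["a"] * len(sessions))
        tb = model.policy_traces(sessions, ["b"] * len(sessions))
        assert np.array_equal(ta.per_session[0], tb.per_session[0])

    def test_unknown_subject_rejected(self, two_stage_block):
        spec = self._spec(["a"])
        model = TeacherModel(spec, _random_teacher_params(spec, seed=0))
        with pytest.raises(KeyError, match="unknown subject"):
            model.policy_traces(two_stage_block.sessions, ["nope"])

    def test_raw_teacher_breaks_action_symmetry_augmented_does_not(self):
        """Trained on symmetry-augmented data, the teacher's policy is an
        action-symmetric function (mirrored inputs give mirrored outputs),
        so a side bias can only be expressed when the teacher sees the raw,
        asymmetric data — the reason teachers are trained on raw data."""
        from tinyrnn.distillation import _flip_session
        cfg = two_stage_miller()
        rng = np.random.default_rng(3)
        n = 300
        actions = (rng.random(n) < 0.1).astype(int)     # 90% A1
        states = np.where(rng.random(n) < 0.8, actions, 1 - actions)
        rewards = rng.integers(0, 2, size=n).astype(float)
        sess = Session("s0", actions, states, rewards, np.ones(n, bool))
        data = SessionData("biased", [sess])
        spec = TeacherSpec(subjects=["biased"], d=4, embed_width=1)
        config = FitConfig(max_epochs=150, patience=150, learning_rate=0.02)
        raw_teacher, _ = train_teacher([("biased", sess)], [("biased", sess)],
                                       spec, config, seed=0)
        aug = augment_by_symmetry(data, cfg)
        aug_blocks = [("biased", s) for s in aug.sessions]
        aug_teacher, _ = train_teacher(aug_blocks, aug_blocks, spec, config,
                                       seed=0)
        flip = _flip_session(sess, True, True, "_f")

        def mirror_asymmetry(teacher):
            p = teacher.policy_traces([sess], ["biased"]).per_session[0]
            pf = teacher.policy_traces([flip], ["biased"]).per_session[0]
            return np.abs(p[:, 0] - pf[:, 1]).mean()

        raw_p = raw_teacher.policy_traces([sess], ["biased"]).per_session[0]
        assert raw_p[:, 0].mean() > 0.75            # bias learned from raw data
        assert mirror_asymmetry(aug_teacher) < 0.05
        assert mirror_asymmetry(raw_teacher) > 0.3

    def test_teacher_forward_per_subject(self, two_stage_block):
        spec = self._spec(["x"])
        model = TeacherModel(spec, _random_teacher_params(spec, seed=2))
        out = teacher_forward([SessionData("x", two_stage_block.sessions)],
                              model)
        assert set(out) == {"x"}
        assert out["x"].per_session[0].shape[1] == 2


def _random_teacher_params(spec, seed):
    from tinyrnn.distillation import _teacher_init
    return _teacher_init(spec, np.random.default_rng(seed))


def test_cross_subject_folds_partition():
    subs = [f"s{i}" for i in range(20)]
    folds = cross_subject_folds(subs, n_folds=6, seed=0)
    assert len(folds) == 6
    flat = [s for f in folds for s in f]
    assert sorted(flat) == sorted(subs)
    assert max(len(f) for f in folds) - min(len(f) for f in folds) <= 1


def test_cross_subject_pipeline_zero_shot():
    """Held-out subjects get finite student NLLs from a teacher that never
    saw their choices (zero-shot protocol)."""
    from tinyrnn.distillation import distill_cross_subject
    cfg = two_stage_miller()
    rng = np.random.default_rng(0)
    group = []
    for i in range(6):
        agent = CognitiveAgent(make_model("mf1"),
                               {"alpha": float(rng.uniform(0.3, 0.7)),
                                "beta": 3.0})
        group.append(simulate_task(cfg, agent, 200, seed=50 + i,
                                   subject_id=f"s{i}"))
    out = distill_cross_subject(group, 0, cfg, teacher_d=6, embed_width=1,
                                n_folds=3,
                                config=FitConfig(max_epochs=60, patience=30),
                                seed=0)
    assert len(out) == 2
    for rep in out.values():
        assert np.isfinite(rep["test_nll"])
        assert rep["test_nll"] < np.log(2) + 0.5   # sane scale


def test_pipeline_rejects_empty_training_set():
    from tinyrnn.distillation import distill_pipeline
    cfg = two_stage_miller()
    group = [simulate_task(cfg, CognitiveAgent(make_model("mf1")), 200,
                           seed=i, subject_id=f"s{i}") for i in range(3)]
    with pytest.raises(ValueError, match="M-training"):
        distill_pipeline(group, "s0", cfg, m_train_trials=0, chunk=50,
                         config=FitConfig(max_epochs=5, patience=5))
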