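import numpy as np
import pytest

from tinyrnn.cognitive import CognitiveAgent, CognitiveModel, make_model
from tinyrnn.fitting import FittedCognitive
from tinyrnn.interpretation import (OneStepSystem, compute_logits,
                                    dynamical_regression,
                                    effective_learning_rate,
                                    find_fixed_points, phase_portrait,
                                    preference_setpoints, score_trajectory,
                                    task_conditions, vector_field_2d)
from tinyrnn.task_envs import reversal_bartolo, simulate_task, two_stage_miller


def _fitted(model_id, params):
    return FittedCognitive(make_model(model_id), params)


class TestComputeLogits:
    def test_indifference(self):
        assert compute_logits(np.array([[0.5, 0.5]]))[0] == pytest.approx(0.0)

    def test_closed_form(self):
        L = compute_logits(np.array([[0.75, 0.25]]))[0]
        assert L == pytest.approx(np.log(3))

    def test_matches_score_difference(self):
        m = _fitted("mf1", {"alpha": 0.3, "beta": 2.0})
        sys = OneStepSystem(m)
        xs = np.linspace(-1, 1, 7)
        probs = np.exp(sys.logit_of(xs))
        # logit of softmax equals beta * (o1 - o2) = 2*beta*q1
        assert np.allclose(sys.logit_of(xs), 2 * 2.0 * xs)


class TestPhasePortraitMF1:
    """Under input (A1, r=1) the anticorrelated model-free rule gives
    dL(L) = alpha * (2 beta - L): slope -alpha, fixed point at 2 beta."""

    @pytest.mark.parametrize("alpha,beta", [(0.3, 2.0), (0.7, 1.5)])
    def test_slope_and_fixed_point(self, alpha, beta):
        model = _fitted("mf1", {"alpha": alpha, "beta": beta})
        grid = np.linspace(-1.5, 1.5, 512)
        por = phase_portrait(model, conditions=[(0, 0, 1.0)], grid=grid)
        L, dL = por.curves[(0, 0, 1.0)]
        slope = np.polyfit(L, dL, 1)[0]
        assert slope == pytest.approx(-alpha, abs=1e-9)
        # fixed point is outside the swept grid unless it covers 2 beta
        grid = np.linspace(-3 * beta, 3 * beta, 512)
        por = phase_portrait(model, conditions=[(0, 0, 1.0)], grid=grid)
        fps = por.fixed_points[(0, 0, 1.0)]
        assert len(fps) == 1
        L_star, stable = fps[0]
        assert L_star == pytest.approx(2 * beta, abs=1e-6)
        assert stable == (alpha < 2)

    def test_frozen_model_flat(self):
        model = _fitted("mf1", {"alpha": 0.0, "beta": 2.0})
        por = phase_portrait(model, conditions=[(0, 0, 1.0), (1, 1, 0.0)],
                             grid=np.linspace(-1, 1, 64))
        for cond in por.conditions:
            assert np.allclose(por.curves[cond][1], 0.0)

    def test_bayes_fixed_points_symmetric_never_zero(self):
        model = _fitted("bayes", {"p_r": 0.05, "p_emit": 0.8, "beta": 4.0})
        sys = OneStepSystem(model)
        grid = np.linspace(0.01, 0.99, 1024)
        fps = {}
        for cond in [(0, 0, 1.0), (1, 1, 1.0)]:
            L = sys.logit_of(grid)
            dL = sys.logit_of(sys.step(grid, cond)) - L
            order = np.argsort(L)
            fps[cond] = find_fixed_points(L[order], dL[order])
        a = [fp for fp, _ in fps[(0, 0, 1.0)]]
        b = [fp for fp, _ in fps[(1, 1, 1.0)]]
        assert len(a) == 1 and len(b) == 1
        assert a[0] == pytest.approx(-b[0], abs=1e-6)
        assert abs(a[0]) > 0.1          # repeated rewards never converge to 0


class TestFindFixedPoints:
    def _curve(self, f, lo=-3, hi=3, n=512):
        L = np.linspace(lo, hi, n)
        return L, f(L)

    def test_linear_stable(self):
        L, dL = self._curve(lambda L: -0.5 * L)
        fps = find_fixed_points(L, dL)
        assert len(fps) == 1
        assert fps[0][0] == pytest.approx(0.0, abs=1e-8)
        assert fps[0][1] is True

    def test_steep_line_unstable(self):
        L, dL = self._curve(lambda L: -2.5 * (L - 1.0))
        fps = find_fixed_points(L, dL)
        assert fps[0][0] == pytest.approx(1.0, abs=1e-6)
        assert fps[0][1] is False        # slope -2.5 < -2

    def test_positive_slope_unstable(self):
        L, dL = self._curve(lambda L: 0.3 * L)
        fps = find_fixed_points(L, dL)
        assert fps[0][0] == pytest.approx(0.0, abs=1e-8)
        assert fps[0][1] is False

    def test_no_crossing_empty(self):
        L, dL = self._curve(lambda L: 1.0 + 0 * L)
        assert find_fixed_points(L, dL) == []

    def test_stability_agrees_with_simulation(self):
        """Stable labels predict convergence of the iterated map from
        perturbed starts; checked over random anticorrelated models."""
        rng = np.random.default_rng(0)
        for _ in range(25):
            alpha = rng.uniform(0.05, 0.95)
            beta = rng.uniform(0.5, 3.0)
            model = _fitted("mf1", {"alpha": alpha, "beta": beta})
            sys = OneStepSystem(model)
            cond = (0, 0, 1.0)
            L_star = 2 * beta
            x_star = 1.0                 # q1 fixed point for r=1
            for _ in range(40):
                x = x_star + rng.normal(0, 0.2)
                for _ in range(500):
                    x = sys.step(np.array([x]), cond)[0]
                assert abs(sys.logit_of(np.array([x]))[0] - L_star) < 1e-6


class _TargetModel(CognitiveModel):
    """Synthetic d=1 model with one setpoint per action/reward condition
    (test helper for the normalization arithmetic)."""

    id = "targets"
    n_actions = 2
    d = 1
    PARAMS = {"rate": "unit"}
    DEFAULTS = {"rate": 0.5}
    TARGETS = {(0, 1.0): 2.0, (0, 0.0): 1.0, (1, 1.0): 0.0, (1, 0.0): -2.0}

    def init_state(self, params, batch):
        return {"x": np.zeros(batch)}

    def step(self, st, params, a, s, r, a2=None):
        target = np.array([self.TARGETS[(int(ai), float(ri))]
                           for ai, ri in zip(a, r)])
        return {"x": st["x"] + params["rate"] * (target - st["x"])}

    def scores(self, st, params):
        return np.stack([st["x"] / 2.0, -st["x"] / 2.0], axis=-1)


class TestPreferenceSetpoints:
    def test_mf1_saturating_preferences(self):
        model = _fitted("mf1", {"alpha": 0.5, "beta": 1.0})
        conds = [(0, 0, 1.0), (1, 1, 1.0)]
        table = preference_setpoints(model, conds, start=0.0)
        assert table.u[(0, 0, 1.0)] == pytest.approx(1.0)
        assert table.u[(1, 1, 1.0)] == pytest.approx(-1.0)
        assert table.normalizer == pytest.approx(2.0)   # 2 beta

    def test_constructed_normalization(self):
        model = FittedCognitive(_TargetModel(), {"rate": 0.5})
        conds = [(0, 0, 1.0), (0, 0, 0.0), (1, 1, 1.0), (1, 1, 0.0)]
        table = preference_setpoints(model, conds, start=0.0)
        u = [table.u[c] for c in conds]
        assert np.allclose(u, [1.0, 0.5, 0.0, -1.0], atol=1e-6)
        assert max(abs(x) for x in u) == pytest.approx(1.0)

    def test_all_zero_fixed_points(self):
        model = _fitted("mf1", {"alpha": 0.5, "beta": 1.0})
        table = preference_setpoints(model, [(0, 0, 0.0), (1, 1, 0.0)],
                                     start=0.0)
        # unrewarded conditions drive the logit to 0 in this model
        assert all(v == 0.0 for v in table.u.values())


class TestEffectiveLearningRate:
    def test_linear_dynamics_constant_rate(self):
        alpha, L_star = 0.4, 1.3
        g = lambda L: alpha * (L_star - L)
        L = np.linspace(-2, 2, 101)
        rates = effective_learning_rate(g, L_star, L)
        assert np.allclose(rates, alpha, atol=1e-6)

    def test_identity_with_tangent_slope(self):
        """alpha(L) = -g'(L) - alpha'(L) (L - L*) holds numerically for a
        curved logit-change function."""
        L_star = 1.0
        g = lambda L: -0.3 * (L - L_star) - 0.05 * (L - L_star) ** 2
        L = np.linspace(-1.0, 2.8, 400)
        L = L[np.abs(L - L_star) > 0.05]
        a = effective_learning_rate(g, L_star, L)
        h = 1e-5
        a_prime = (effective_learning_rate(g, L_star, L + h)
                   - effective_learning_rate(g, L_star, L - h)) / (2 * h)
        g_prime = (g(L + h) - g(L - h)) / (2 * h)
        resid = a - (-g_prime - a_prime * (L - L_star))
        assert np.abs(resid).max() < 1e-6

    def test_value_at_fixed_point_is_negative_slope(self):
        g = lambda L: -0.25 * (L - 0.7) + 0.1 * (L - 0.7) ** 2
        val = effective_learning_rate(g, 0.7, np.array([0.7]))[0]
        assert val == pytest.approx(0.25, abs=1e-5)


class TestVectorField2D:
    def test_mf2_arrows_axis_aligned(self):
        model = _fitted("mf2", {"alpha": 0.4, "beta": 1.0})
        grid = (np.linspace(-1, 1, 5), np.linspace(-1, 1, 5))
        field = vector_field_2d(model, [(0, 0, 1.0), (1, 1, 0.0)], grid)
        # choosing A1 only moves the first coordinate
        assert np.allclose(field[(0, 0, 1.0)]["deltas"][:, 1], 0.0)
        assert np.allclose(field[(1, 1, 0.0)]["deltas"][:, 0], 0.0)

    def test_drift_to_other_attracts_to_diagonal(self):
        model = _fitted("mf2_drift",
                        {"alpha0": 0.3, "D1": 0.7, "b": 0.05, "beta": 1.0})
        grid = (np.linspace(-0.5, 0.5, 4), np.linspace(-0.5, 0.5, 4))
        field = vector_field_2d(model, [(0, 0, 0.0)], grid)
        att = field[(0, 0, 0.0)]["attractors"]
        assert len(att) > 0
        assert np.abs(att[:, 0] - att[:, 1]).max() < 1e-3

    def test_zero_dynamics_zero_arrows(self):
        model = _fitted("mf2", {"alpha": 0.0, "beta": 1.0})
        grid = (np.linspace(-1, 1, 4), np.linspace(-1, 1, 4))
        field = vector_field_2d(model, [(0, 0, 1.0)], grid)
        assert np.allclose(field[(0, 0, 1.0)]["deltas"], 0.0)


class TestDynamicalRegression:
    def _trajectory(self, model_id, params, n=800, seed=5):
        cfg = reversal_bartolo()
        model = make_model(model_id)
        data = simulate_task(cfg, CognitiveAgent(model, params), n, seed=seed)
        sess = data.sessions[0]
        scores = score_trajectory(FittedCognitive(model, params), sess)
        inputs = [(int(sess.action[t]), float(sess.reward[t]))
                  for t in range(sess.n_trials - 1)]
        return scores, inputs

    def test_mf2_exact_coefficients(self):
        alpha, beta = 0.3, 1.0
        scores, inputs = self._trajectory("mf2", {"alpha": alpha,
                                                  "beta": beta})
        res = dynamical_regression(scores, inputs)
        A = res.A[(0, 1.0)]            # chose A1, rewarded
        assert A[0, 0] == pytest.approx(-alpha, abs=1e-6)
        assert A[0, 1] == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(A[1], 0.0, atol=1e-9)        # unchosen frozen
        assert res.beta0[(0, 1.0)][0] == pytest.approx(alpha * beta, abs=1e-6)
        assert np.abs(np.concatenate(
            [v for v in res.resid_var.values()])).max() < 1e-12

    def test_mf1_logit_regression(self):
        alpha, beta = 0.45, 2.0
        model = make_model("mf1")
        params = {"alpha": alpha, "beta": beta}
        cfg = reversal_bartolo()
        data = simulate_task(cfg, CognitiveAgent(model, params), 800, seed=6)
        sess = data.sessions[0]
        scores = score_trajectory(FittedCognitive(model, params), sess)
        L = (scores[:, 0] - scores[:, 1])[:, None]
        inputs = [(int(sess.action[t]), float(sess.reward[t]))
                  for t in range(sess.n_trials - 1)]
        res = dynamical_regression(L, inputs)
        assert res.beta0[(0, 1.0)][0] == pytest.approx(2 * alpha * beta,
                                                       abs=1e-6)
        assert res.A[(0, 1.0)][0, 0] == pytest.approx(-alpha, abs=1e-6)

    def test_constant_change_gives_pure_intercept(self):
        T = 60
        states = np.concatenate([[0.0],
                                 np.cumsum(np.full(T - 1, 0.37))])[:, None]
        inputs = ["only"] * (T - 1)
        res = dynamical_regression(states, inputs)
        assert res.beta0["only"][0] == pytest.approx(0.37, abs=1e-9)
        assert abs(res.A["only"][0, 0]) < 1e-9

    def test_rank_deficient_flagged(self):
        states = np.zeros((40, 2))      # constant states: no spread
        inputs = ["c"] * 39
        res = dynamical_regression(states, inputs)
        assert res.flagged == ["c"]

    def test_reward_regressor_recovered(self):
        rng = np.random.default_rng(1)
        T = 300
        states = np.zeros((T, 1))
        rewards = rng.uniform(0, 1, size=T - 1)
        for t in range(T - 1):
            states[t + 1, 0] = 0.7 * states[t, 0] + 0.5 * rewards[t]
        res = dynamical_regression(states, ["c"] * (T - 1), reward=rewards)
        assert res.beta_r["c"][0] == pytest.approx(0.5, abs=1e-8)
        assert res.A["c"][0, 0] == pytest.approx(-0.3, abs=1e-8)


class TestTaskConditions:
    def test_reversal_conditions(self):
        conds = task_conditions(reversal_bartolo())
        assert len(conds) == 4
        assert all(c[0] == c[1] for c in conds)

    def test_two_stage_conditions(self):
        assert len(task_conditions(two_stage_miller())) == 8
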