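"""Model heads, likelihood loss, survival curves, and training."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nnsurv as ns
from nnsurv.model import brown_loss_gradient, loss_gradient


def interval_loglik_oracle(time, event, surv_pred, grid):
    """Log likelihood computed directly from interval indices.

    For an event in interval j: ln h_j + sum_{i<j} ln(1 - h_i).  For a
    censored time: credit ln(1 - h_i) for every interval whose midpoint
    was reached.  Independent of the vector encoding path.
    """
    p = np.asarray(surv_pred, dtype=float)
    if event == 1:
        j = min(int(grid.interval_index(time)), grid.n - 1)
        return float(np.log(1 - p[j]) + np.log(p[:j]).sum())
    k = int(np.sum(np.asarray(grid.midpoints) <= time))
    return float(np.log(p[:k]).sum())


class TestHeads:
    def test_flexible_head_zero_inputs_give_half(self):
        out = ns.flexible_head(np.zeros(3), np.zeros((3, 4)), np.zeros(4))
        assert np.allclose(out, 0.5)

    def test_flexible_head_saturates_with_large_bias(self):
        out = ns.flexible_head(np.zeros(1), np.zeros((1, 2)), np.array([40.0, -40.0]))
        assert out[0] > 1 - 1e-9 and out[1] < 1e-9

    def test_flexible_head_log_odds(self):
        out = ns.flexible_head(np.array([1.0]), np.array([[np.log(3)]]), np.array([0.0]))
        assert np.allclose(out, 0.75)

    def test_flexible_head_shape_mismatch(self):
        with pytest.raises(ValueError):
            ns.flexible_head(np.zeros(2), np.zeros((3, 4)), np.zeros(4))

    def test_ph_head_identity_at_zero_predictor(self):
        logits = np.array([0.4, -1.2, 2.0])
        assert np.allclose(ns.ph_head(0.0, logits), 1 / (1 + np.exp(-logits)))

    def test_ph_head_power_rule(self):
        # baseline survival 0.5, xbeta = ln 2 -> 0.5^2 = 0.25
        assert np.allclose(ns.ph_head(np.log(2), np.zeros(3)), 0.25)

    def test_ph_head_protective_limit(self):
        out = ns.ph_head(-200.0, np.array([-3.0, 0.0, 3.0]))
        assert np.all(out > 1 - 1e-6)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(a=st.floats(-1.5, 1.5), b=st.floats(-1.5, 1.5))
    def test_ph_head_proportional_hazards_property(self, a, b):
        """log survival ratio is constant over intervals = exp(a - b).

        Predictor range kept where the [EPS, 1-EPS] output clip is
        inactive; the clip flattens the identity at extreme predictors.
        """
        logits = np.array([1.5, 0.2, -0.8, -2.0])
        ratio = np.log(ns.ph_head(a, logits)) / np.log(ns.ph_head(b, logits))
        assert np.allclose(ratio, np.exp(a - b), rtol=1e-6)


class TestLosses:
    def test_nll_single_failure(self):
        loss = ns.negative_log_likelihood([[0.0]], [[1.0]], [[0.5]])
        assert np.isclose(loss, -np.log(0.5))

    def test_nll_censored_past_two_intervals(self):
        loss = ns.negative_log_likelihood([[1, 1]], [[0, 0]], [[0.8, 0.9]])
        assert np.isclose(loss, -(np.log(0.8) + np.log(0.9)))

    def test_nll_all_zero_encoding_contributes_nothing(self):
        assert ns.negative_log_likelihood([[0, 0]], [[0, 0]], [[0.3, 0.9]]) == 0.0

    def test_nll_shape_mismatch(self):
        with pytest.raises(ValueError):
            ns.negative_log_likelihood([[1, 0]], [[0]], [[0.5, 0.5]])

    def test_brown_failure_interval_contributions(self):
        # perfect hazard prediction h=1 -> 0; h=0.5 -> 1/2 (1-0.5)^2
        assert ns.brown_loss([[0.0]], [[1.0]], [[0.0]]) == 0.0
        assert np.isclose(ns.brown_loss([[0.0]], [[1.0]], [[0.5]]), 0.125)

    def test_brown_null_minimizer_is_life_table(self):
        """On a null model the quadratic loss is minimized by h = d/r,
        the same product-limit hazard the likelihood gives."""
        rng = np.random.default_rng(1)
        grid = ns.make_uniform_grid(25, 100)
        s, f = ns.encode_dataset(rng.uniform(0, 120, 300),
                                 rng.integers(0, 2, 300), grid)
        d, r, h_km = ns.life_table_from_encodings(s, f)
        hs = np.linspace(0.01, 0.99, 99)
        for j in range(grid.n):
            losses = [
                0.5 * (s[:, j] * (1 - p) ** 2 + f[:, j] * p**2).sum() for p in 1 - hs
            ]
            assert np.isclose(hs[np.argmin(losses)], h_km[j], atol=0.01)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(seed=st.integers(0, 10_000))
    def test_nll_matches_interval_oracle(self, seed):
        """Vectorized bilinear loss equals the per-individual interval
        log likelihood, to 1e-10."""
        rng = np.random.default_rng(seed)
        grid = ns.TimeGrid(np.cumsum(rng.uniform(1, 20, rng.integers(1, 7))))
        n = 20
        times = rng.uniform(0, grid.boundaries[-1] * 0.99, n)
        events = rng.integers(0, 2, n)
        p = rng.uniform(0.05, 0.95, (n, grid.n))
        s, f = ns.encode_dataset(times, events, grid)
        vec = -ns.negative_log_likelihood(s, f, p)
        oracle = sum(
            interval_loglik_oracle(t, e, p[i], grid)
            for i, (t, e) in enumerate(zip(times, events))
        )
        assert np.isclose(vec, oracle, atol=1e-10)

    @pytest.mark.parametrize("grad_fn,loss_fn", [
        (loss_gradient, ns.negative_log_likelihood),
        (brown_loss_gradient, ns.brown_loss),
    ])
    def test_gradients_match_central_differences(self, grad_fn, loss_fn):
        rng = np.random.default_rng(7)
        s = (rng.random((8, 5)) < 0.5).astype(float)
        f = np.zeros((8, 5))
        f[::2, 2] = 1.0
        s[f == 1] = 0.0
        p = rng.uniform(0.05, 0.95, (8, 5))
        g = grad_fn(s, f, p)
        eps = 1e-6
        fd = np.zeros_like(p)
        for i in range(p.shape[0]):
            for j in range(p.shape[1]):
                up, dn = p.copy(), p.copy()
                up[i, j] += eps
                dn[i, j] -= eps
                fd[i, j] = (loss_fn(s, f, up) - loss_fn(s, f, dn)) / (2 * eps)
        assert np.abs(g - fd).max() < 1e-5


class TestSurvivalCurves:
    def test_cumulative_product(self, grid3):
        curve = ns.survival_curve([0.9, 0.8, 1.0], grid3)
        assert np.allclose(curve.S, [0.9, 0.72, 0.72])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(p=st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3))
    def test_curve_monotone_non_increasing(self, p):
        grid = ns.TimeGrid(np.array([10.0, 20.0, 30.0]))
        assert np.all(np.diff(ns.survival_curve(p, grid).S) <= 0)

    def test_interpolation_knots_and_midpoint(self, grid3):
        curve = ns.survival_curve([0.8, 0.5, 0.9], grid3)
        assert ns.survival_at(0.0, curve) == 1.0
        for j, t in enumerate(grid3.boundaries):
            assert np.isclose(ns.survival_at(t, curve), curve.S[j])
        single = ns.StepSurvivalCurve(ns.TimeGrid(np.array([10.0])), np.array([0.8]))
        assert np.isclose(ns.survival_at(5.0, single), 0.9)

    def test_step_mode(self, grid3):
        curve = ns.survival_curve([0.8, 0.5, 0.9], grid3)
        assert ns.survival_at(5.0, curve, mode="step") == 1.0
        assert np.isclose(ns.survival_at(15.0, curve, mode="step"), 0.8)

    def test_no_extrapolation(self, grid3):
        curve = ns.survival_curve([0.8, 0.5, 0.9], grid3)
        with pytest.raises(ns.ExtrapolationError):
            ns.survival_at(31.0, curve)


class TestTraining:
    def _toy(self, n=300, seed=5):
        cohort = ns.simulate_two_group(n=n, seed=seed)
        grid = ns.make_uniform_grid(100, 900)
        s, f = ns.encode_dataset(cohort.times, cohort.events, grid)
        return cohort, grid, s, f

    def test_one_epoch_decreases_loss(self):
        cohort, grid, s, f = self._toy()
        model = ns.SurvivalNetwork(grid, 1, (), "flexible")
        model.initialize(np.random.default_rng(0))
        before = model.loss(cohort.covariates, s, f)
        model.fit(cohort.covariates, s, f,
                  ns.TrainingConfig(seed=0, epochs=1, batch_size=64))
        after = model.loss(cohort.covariates, s, f)
        assert after < before

    def test_training_reproducible_given_seed(self):
        cohort, grid, s, f = self._toy()
        params = []
        for _ in range(2):
            m = ns.SurvivalNetwork(grid, 1, (), "flexible")
            m.fit(cohort.covariates, s, f, ns.TrainingConfig(seed=9, epochs=20))
            params.append({k: v.copy() for k, v in m.params.items()})
        for k in params[0]:
            assert np.array_equal(params[0][k], params[1][k])

    def test_divergence_raises_naming_epoch(self):
        cohort, grid, s, f = self._toy()
        model = ns.SurvivalNetwork(grid, 1, (), "flexible")
        model.initialize(np.random.default_rng(0))
        model.params["bias"][0] = np.nan     # corrupted state must be detected
        with pytest.raises(ns.TrainingDivergedError, match="epoch 0"):
            model.fit(cohort.covariates, s, f, ns.TrainingConfig(seed=0, epochs=5))

    def test_null_model_recovers_life_table(self):
        """Intercept-only flexible model trained to convergence reproduces
        the life-table hazard d_j/r_j (the discrete-time MLE)."""
        _, grid, s, f = self._toy(n=400, seed=3)
        _, _, h_expected = ns.life_table_from_encodings(s, f)
        model = ns.SurvivalNetwork(grid, 0, (), "flexible")
        X = np.empty((s.shape[0], 0))
        for lr in (0.05, 0.005, 0.0005):   # staged refinement to the optimum
            model.fit(X, s, f, ns.TrainingConfig(seed=1, epochs=2000,
                                                 batch_size=len(s), learning_rate=lr))
        h_fitted = 1 - model.predict_conditional(np.empty((1, 0)))[0]
        assert np.abs(h_fitted - h_expected).max() < 1e-3

    def test_null_model_survival_matches_kaplan_meier(self):
        """On uncensored data the life-table product telescopes to the
        empirical survival, so the fitted null-model curve equals the
        Kaplan-Meier estimate at the interval ends."""
        cohort = ns.simulate_digit_cohort(n=400, seed=2)
        grid = ns.make_event_quantile_grid(cohort.times, cohort.events, 8)
        s, f = ns.encode_dataset(cohort.times, cohort.events, grid)
        model = ns.SurvivalNetwork(grid, 0, (), "flexible")
        X = np.empty((len(s), 0))
        for lr in (0.05, 0.005, 0.0005):
            model.fit(X, s, f, ns.TrainingConfig(seed=1, epochs=2000,
                                                 batch_size=len(s), learning_rate=lr))
        S_fit = model.predict_survival(np.empty((1, 0)))[0]
        km = ns.kaplan_meier(cohort.times, cohort.events)
        assert np.abs(S_fit - km.at(grid.boundaries)).max() < 5e-3

    def test_l2_cross_validation_prefers_moderate_penalty(self):
        cohort, grid, s, f = self._toy(n=200, seed=11)
        best, scores = ns.select_l2_cross_validated(
            cohort.covariates, s, f, grid, candidates=[0.0, 1000.0],
            k=3, config=ns.TrainingConfig(seed=4, epochs=100))
        assert best == 0.0           # a huge penalty must lose on held-out loglik
        assert scores[0.0] > scores[1000.0]

    def test_checkpoint_roundtrip(self, tmp_path):
        cohort, grid, s, f = self._toy(n=100, seed=6)
        model = ns.SurvivalNetwork(grid, 1, (4,), "ph")
        config = ns.TrainingConfig(seed=2, epochs=30)
        model.fit(cohort.covariates, s, f, config)
        path = tmp_path / "model.json"
        model.save(path, config=config, covariate_names=["x0"])
        loaded = ns.SurvivalNetwork.load(path)
        assert np.allclose(loaded.predict_survival(cohort.covariates),
                           model.predict_survival(cohort.covariates))
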