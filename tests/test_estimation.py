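"""Likelihood correctness (against brute-force density oracles), the
least-squares initialization, and constrained ML fitting."""

import numpy as np
import pytest
from scipy import stats

from sdngc import (
    JointARBEKKModel,
    TrialPanel,
    fit,
    fit_joint,
    init_params,
    log_likelihood,
    second_order_stable,
    simulate,
)
from sdngc.estimation import count_free_params, init_joint_params

from conftest import random_stable_scalar_models, scalar_model, scalar_pair_model


def brute_force_loglik(model, values):
    """Independent oracle: product of conditional normal densities, one
    time point at a time, straight from the model definition."""
    total = 0.0
    m = max(model.p, model.q)
    for trial in values:
        for t in range(m, trial.shape[0]):
            mean = sum(model.A[i - 1] @ trial[t - i] for i in range(1, model.p + 1))
            H = model.W.copy()
            for j in range(1, model.q + 1):
                v = model.B[j - 1] @ trial[t - j]
                H += np.outer(v, v)
            total += stats.multivariate_normal.logpdf(trial[t], mean=mean, cov=H)
    return total


class TestLogLikelihood:
    def test_standard_normal_point(self):
        # one scored point, h = 1, residual 0 -> log phi(0)
        model = scalar_model(0.0, 0.0, w=1.0)
        panel = TrialPanel(np.zeros((1, 2, 1)))
        assert log_likelihood(model, panel) == pytest.approx(
            -0.5 * np.log(2 * np.pi), rel=1e-12
        )

    def test_matches_brute_force_oracle(self, rng):
        """Vectorized likelihood equals the direct density product to 1e-10
        for 50 random stable scalar models on 20-point series."""
        for model in random_stable_scalar_models(rng, 50, q_zero_fraction=0.3):
            panel = simulate(model, T=20, n_trials=1, seed=rng)
            assert log_likelihood(model, panel) == pytest.approx(
                brute_force_loglik(model, panel.values), abs=1e-10
            )

    def test_multitrial_additivity(self, base_model, rng):
        panel = simulate(base_model, T=30, n_trials=4, seed=rng)
        total = log_likelihood(base_model, panel)
        parts = sum(
            log_likelihood(base_model, TrialPanel(panel.values[[i]]))
            for i in range(4)
        )
        assert total == pytest.approx(parts, rel=1e-12)

    def test_joint_blockdiag_likelihood_oracle(self, rng):
        """Joint likelihood equals the sum of the two blocks' conditional
        Gaussian densities computed by brute force."""
        jm = scalar_pair_model(a=0.5, b=0.4, a_xy=0.3, b_xy=0.2, w=1.2)
        panel = simulate(jm, T=15, n_trials=2, seed=rng)
        total = 0.0
        for trial in panel.values:
            for t in range(1, trial.shape[0]):
                mean = jm.A[0] @ trial[t - 1]
                hx = jm.Wx[0, 0] + (jm.Bx[0] @ trial[t - 1]).item() ** 2
                hy = jm.Wy[0, 0] + (jm.By[0] @ trial[t - 1]).item() ** 2
                total += stats.norm.logpdf(trial[t, 0], mean[0], np.sqrt(hx))
                total += stats.norm.logpdf(trial[t, 1], mean[1], np.sqrt(hy))
        assert log_likelihood(jm, panel) == pytest.approx(total, abs=1e-10)

    def test_dimension_mismatch(self, base_model):
        with pytest.raises(ValueError, match="dimension"):
            log_likelihood(base_model, TrialPanel(np.zeros((1, 10, 2))))


class TestInitParams:
    def test_recovers_var_coefficients(self, rng):
        model = scalar_model(0.6, 0.0, w=1.0)
        panel = simulate(model, T=1000, n_trials=1, seed=rng)
        init = init_params(panel, 1, 1)
        assert init.A[0][0, 0] == pytest.approx(0.6, abs=0.08)

    def test_volatility_init_nonnegative(self, base_model, rng):
        panel = simulate(base_model, T=500, n_trials=2, seed=rng)
        init = init_params(panel, 1, 1)
        assert np.all(np.diag(init.B[0]) >= 0)
        assert np.all(np.diag(init.W) >= 1e-6)

    def test_degenerate_panel_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            init_params(TrialPanel(np.zeros((2, 50, 1))), 1, 1)

    def test_initial_model_is_stable(self, rng):
        # even for near-unit-root data the start is projected into stability
        model = scalar_model(0.95, 0.0)
        panel = simulate(model, T=500, n_trials=1, seed=rng)
        init = init_params(panel, 1, 1)
        assert second_order_stable(init)[0]


class TestFit:
    def test_parameter_recovery_reference_model(self, base_panel):
        res = fit(base_panel, 1, 1)
        assert res.converged
        assert res.model.A[0][0, 0] == pytest.approx(0.5, abs=0.1)
        assert abs(res.model.B[0][0, 0]) == pytest.approx(0.5, abs=0.1)
        assert res.model.W[0, 0] == pytest.approx(1.0, abs=0.15)

    def test_ascent_over_initialization(self, base_panel):
        init = init_params(base_panel, 1, 1)
        res = fit(base_panel, 1, 1)
        assert res.loglik >= log_likelihood(init, base_panel) - 1e-6

    def test_fitted_model_is_stable(self, base_panel):
        res = fit(base_panel, 1, 1)
        ok, radius = second_order_stable(res.model)
        assert ok and radius < 1.0

    def test_var_oracle_agreement(self, rng):
        """With q=0 the constrained ML fit agrees with closed-form VAR least
        squares within optimizer tolerance."""
        model = scalar_model(0.6, 0.0, w=1.5)
        panel = simulate(model, T=1000, n_trials=2, seed=rng)
        res = fit(panel, p=1, q=0)
        x = panel.values[:, :, 0]
        num = (x[:, 1:] * x[:, :-1]).sum()
        den = (x[:, :-1] ** 2).sum()
        a_ols = num / den
        assert res.model.A[0][0, 0] == pytest.approx(a_ols, abs=1e-3)

    def test_local_optimality_of_fit(self, base_panel):
        res = fit(base_panel, 1, 1)
        theta = np.array([res.model.A[0][0, 0], res.model.B[0][0, 0],
                          res.model.W_chol[0, 0]])
        base = res.loglik
        for i in range(3):
            for sign in (-1, 1):
                pert = theta.copy()
                pert[i] += sign * 1e-2
                m = scalar_model(pert[0], pert[1], pert[2] ** 2)
                if not second_order_stable(m)[0]:
                    continue
                assert log_likelihood(m, base_panel) <= base + 1e-6


class TestFitJoint:
    def test_free_parameter_counts(self):
        full = scalar_pair_model()
        restricted = scalar_pair_model()
        restricted.restriction = "y_to_x_zero"
        assert count_free_params(full) == 10
        assert count_free_params(restricted) == 8

    def test_restricted_never_beats_full(self, rng):
        m = scalar_model()
        px = simulate(m, T=300, n_trials=2, seed=rng)
        py = simulate(m, T=300, n_trials=2, seed=rng)
        restr = fit_joint(px, py, restriction="y_to_x_zero")
        full = fit_joint(px, py, restriction="none",
                         start_models=[restr.model])
        assert full.loglik >= restr.loglik - 1e-6

    def test_restriction_zeroes_coefficients(self, rng):
        m = scalar_model()
        px = simulate(m, T=200, n_trials=2, seed=rng)
        py = simulate(m, T=200, n_trials=2, seed=rng)
        res = fit_joint(px, py, restriction="y_to_x_zero")
        assert res.model.A[0][0, 1] == 0.0
        assert res.model.Bx[0][0, 1] == 0.0

    def test_null_statistic_calibration(self, rng):
        """2*(full - restricted) loglik on independent series is small:
        median below the chi-squared(2) median across replicates."""
        m = scalar_model()
        stats_ = []
        for _ in range(24):
            px = simulate(m, T=300, n_trials=2, seed=rng)
            py = simulate(m, T=300, n_trials=2, seed=rng)
            restr = fit_joint(px, py, restriction="y_to_x_zero")
            full = fit_joint(px, py, restriction="none",
                             start_models=[restr.model])
            stats_.append(2 * (full.loglik - restr.loglik))
        # chi2(2) median is 1.386; allow generous binomial slack at n=24
        assert np.median(stats_) < 3.5

    def test_misaligned_panels_error(self, rng):
        m = scalar_model()
        px = simulate(m, T=100, n_trials=2, seed=rng)
        py = simulate(m, T=101, n_trials=2, seed=rng)
        with pytest.raises(ValueError, match="misaligned|aligned"):
            fit_joint(px, py)

    def test_joint_init_respects_restriction(self, rng):
        m = scalar_model()
        px = simulate(m, T=100, n_trials=2, seed=rng)
        stacked = px.stack(simulate(m, T=100, n_trials=2, seed=rng))
        init = init_joint_params(stacked, kx=1, restriction="y_to_x_zero")
        assert init.A[0][0, 1] == 0.0
        assert init.Bx[0][0, 1] == 0.0


def test_fit_result_serializes_to_json(base_panel):
    import json

    res = fit(base_panel, 1, 1)
    payload = json.loads(res.to_json())
    assert payload["n_params"] == 3
    assert payload["converged"] is True
    assert payload["model"]["kind"] == "marginal"
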