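"""Projection-based signal/noise estimation and the signal-dependent-noise
correlation diagnostic."""

import numpy as np
import pytest

from sdngc import (
    BasisSpec,
    TrialPanel,
    build_design,
    empirical_signal_noise,
    fit,
    model_concordance,
    sdn_correlation,
    simulate,
)

from conftest import scalar_model


class TestBasisSpec:
    @pytest.mark.parametrize(
        "family, n_lags, expected",
        [("linear", 2, 3), ("poly2", 1, 3), ("fourier6", 1, 13),
         ("linear", 9, 10), ("poly2", 6, 13), ("fourier6", 2, 25)],
    )
    def test_regressor_counts(self, family, n_lags, expected):
        assert BasisSpec(family, n_lags).n_regressors == expected

    def test_unknown_family(self):
        with pytest.raises(ValueError):
            BasisSpec("cubic", 1)


class TestBuildDesign:
    def test_linear_two_lags_columns(self, rng):
        panel = TrialPanel(rng.standard_normal((3, 20, 1)))
        X, y, trial_idx, time_idx = build_design(panel, BasisSpec("linear", 2))
        assert X.shape == (3 * 18, 3)  # intercept + 2 lags
        assert y.shape == (3 * 18,)
        assert np.all(time_idx >= 2)
        # first regressor after the intercept is lag-1
        row = np.flatnonzero((trial_idx == 1) & (time_idx == 5))[0]
        assert X[row, 1] == panel.values[1, 4, 0]
        assert X[row, 2] == panel.values[1, 3, 0]

    def test_poly2_single_lag_regressors(self, rng):
        panel = TrialPanel(rng.standard_normal((2, 10, 1)))
        X, _, _, _ = build_design(panel, BasisSpec("poly2", 1))
        assert np.allclose(X[:, 2], X[:, 1] ** 2)

    def test_fourier_range_normalization(self, rng):
        panel = TrialPanel(rng.standard_normal((2, 30, 1)))
        X, _, _, _ = build_design(panel, BasisSpec("fourier6", 1))
        assert X.shape[1] == 13
        assert np.all(np.abs(X[:, 1:]) <= 1 + 1e-12)

    def test_short_trial_errors(self, rng):
        panel = TrialPanel(rng.standard_normal((2, 3, 1)))
        with pytest.raises(ValueError, match="short"):
            build_design(panel, BasisSpec("linear", 2))


class TestEmpiricalSignalNoise:
    def test_noiseless_ar1_is_exactly_representable(self):
        x0 = np.linspace(1.0, 2.0, 12)
        T = 15
        vals = np.empty((12, T, 1))
        for i, s in enumerate(x0):
            x = s
            for t in range(T):
                vals[i, t, 0] = x
                x = 0.9 * x
        esn = empirical_signal_noise(TrialPanel(vals), BasisSpec("linear", 1))
        assert np.abs(esn.residual).max() < 1e-10
        assert esn.r2 == pytest.approx(1.0, abs=1e-10)

    def test_homoskedastic_null_rarely_flags(self, rng):
        model = scalar_model(0.6, 0.0)
        hits = 0
        for _ in range(20):
            panel = simulate(model, T=40, n_trials=40, seed=rng)
            esn = empirical_signal_noise(panel, BasisSpec("linear", 1))
            r, p = sdn_correlation(esn)
            hits += p < 0.05
        assert hits <= 4

    def test_arbekk_alternative_detected(self, rng):
        model = scalar_model(0.5, 0.6)
        hits = 0
        for _ in range(10):
            panel = simulate(model, T=40, n_trials=60, seed=rng, burn_in=0,
                             initial_state=np.array([4.0]))
            esn = empirical_signal_noise(panel, BasisSpec("linear", 1))
            r, p = sdn_correlation(esn)
            hits += (r > 0) and (p < 0.05)
        assert hits >= 9

    def test_requires_enough_trials(self, rng):
        panel = TrialPanel(rng.standard_normal((5, 30, 1)))
        with pytest.raises(ValueError, match="trials"):
            empirical_signal_noise(panel, BasisSpec("linear", 1))

    def test_collinear_columns_dropped_and_recorded(self, rng):
        # constant series make the lag column collinear with the intercept
        vals = np.ones((12, 20, 1)) * 2.0
        vals += 1e-9 * rng.standard_normal(vals.shape)
        esn = empirical_signal_noise(TrialPanel(vals), BasisSpec("poly2", 1))
        assert len(esn.dropped_columns[0]) >= 1

    def test_r2_monotone_in_lags(self, rng):
        """Nested projections: adding lags never decreases r2."""
        model = scalar_model(0.6, 0.4)
        panel = simulate(model, T=60, n_trials=30, seed=rng)
        for family in ("linear", "poly2", "fourier6"):
            # fixed conditioning window so the projections are nested on the
            # same rows
            r2s = [
                empirical_signal_noise(panel, BasisSpec(family, L),
                                       condition_on=3).r2
                for L in (1, 2, 3)
            ]
            assert r2s[0] <= r2s[1] + 1e-12 <= r2s[2] + 2e-12

    def test_verdict_consistent_across_bases(self, rng):
        """All three projection families agree on signal-dependent noise for
        AR-BEKK data."""
        model = scalar_model(0.5, 0.6)
        panel = simulate(model, T=50, n_trials=80, seed=rng, burn_in=0,
                         initial_state=np.array([4.0]))
        for family in ("linear", "poly2", "fourier6"):
            r, p = sdn_correlation(
                empirical_signal_noise(panel, BasisSpec(family, 1))
            )
            assert r > 0 and p < 0.05


class TestSdnCorrelation:
    def test_perfect_linearity(self, rng):
        esn = empirical_signal_noise(
            simulate(scalar_model(0.5, 0.5), T=30, n_trials=20, seed=rng),
            BasisSpec("linear", 1),
        )
        esn.noise_var = np.mean(esn.signal_hat**2, axis=0) * 3.0
        r, p = sdn_correlation(esn)
        assert r == pytest.approx(1.0)

    def test_too_few_points(self, rng):
        panel = simulate(scalar_model(), T=5, n_trials=15, seed=rng)
        esn = empirical_signal_noise(panel, BasisSpec("linear", 1))
        with pytest.raises(ValueError, match="time points"):
            sdn_correlation(esn)

    def test_spearman_option(self, rng):
        panel = simulate(scalar_model(0.5, 0.6), T=40, n_trials=40, seed=rng)
        esn = empirical_signal_noise(panel, BasisSpec("linear", 1))
        r, p = sdn_correlation(esn, method="spearman")
        assert -1 <= r <= 1 and 0 <= p <= 1


class TestModelConcordance:
    @pytest.fixture()
    def trial_locked_panel(self):
        # released from a common state, like stimulus-locked trials
        model = scalar_model(0.7, 0.5)
        return model, simulate(model, T=25, n_trials=100, seed=4, burn_in=0,
                               initial_state=np.array([5.0]))

    def test_self_consistency(self, trial_locked_panel):
        model, panel = trial_locked_panel
        fitres = fit(panel, 1, 1)
        esn = empirical_signal_noise(panel, BasisSpec("linear", 1))
        r_signal, r_variance = model_concordance(fitres, esn)
        assert r_signal > 0.7
        assert r_variance > 0.7

    def test_median_self_consistency_across_seeds(self):
        model = scalar_model(0.7, 0.5)
        rvs = []
        for seed in range(5):
            panel = simulate(model, T=25, n_trials=100, seed=seed, burn_in=0,
                             initial_state=np.array([5.0]))
            fitres = fit(panel, 1, 1)
            esn = empirical_signal_noise(panel, BasisSpec("linear", 1))
            rs, rv = model_concordance(fitres, esn)
            assert rs > 0.7
            rvs.append(rv)
        assert np.median(rvs) > 0.7

    def test_constant_variance_reported_as_nan(self, rng):
        model = scalar_model(0.6, 0.0)
        panel = simulate(model, T=30, n_trials=30, seed=rng)
        fitres = fit(panel, p=1, q=0)
        esn = empirical_signal_noise(panel, BasisSpec("linear", 1))
        r_signal, r_variance = model_concordance(fitres, esn)
        assert np.isnan(r_variance)
        assert r_signal > 0.5

    def test_trial_permutation_invariance(self, trial_locked_panel, rng):
        model, panel = trial_locked_panel
        fitres = fit(panel, 1, 1)
        esn = empirical_signal_noise(panel, BasisSpec("linear", 1))
        r1 = model_concordance(fitres, esn)
        perm = rng.permutation(panel.n_trials)
        shuffled = TrialPanel(panel.values[perm], dt=panel.dt,
                              channel_names=panel.channel_names)
        esn2 = empirical_signal_noise(shuffled, BasisSpec("linear", 1))
        r2 = model_concordance(fitres, esn2)
        assert r1[0] == pytest.approx(r2[0], rel=1e-9)
        assert r1[1] == pytest.approx(r2[1], rel=1e-9)
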