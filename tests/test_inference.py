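"""Causality tests: classical and SDN likelihood-ratio tests, the
difference-of-chi-squared distribution, and the all-pairs report."""

import numpy as np
import pytest
from scipy import integrate, stats

from sdngc import (
    classical_gc,
    difference_cdf,
    difference_test,
    pair_table,
    sdn_gc,
    simulate,
)
from sdngc.inference import _vg_pdf, difference_tail

from conftest import scalar_model, scalar_pair_model


def make_pair(rng, model=None, T=300, n_trials=2):
    model = model or scalar_model()
    px = simulate(model, T=T, n_trials=n_trials, seed=rng)
    py = simulate(model, T=T, n_trials=n_trials, seed=rng)
    return px, py


class TestClassicalGC:
    def test_geweke_f_nonnegative_and_consistent(self, rng):
        for _ in range(10):
            px, py = make_pair(rng, T=120)
            t = classical_gc(px, py, p=1)
            assert t.geweke_f >= -1e-12
            assert t.statistic == pytest.approx(
                t.full_fit.n_obs * t.geweke_f, rel=1e-10
            )

    def test_power_under_coupling(self, rng):
        """VAR(1) with cross-coefficient 0.5 is detected essentially always
        at T=1000."""
        jm = scalar_pair_model(a=0.5, b=0.0, a_xy=0.5)
        jm.Bx, jm.By = [], []  # pure VAR
        rejections = 0
        n_rep = 25
        for _ in range(n_rep):
            panel = simulate(jm, T=1000, n_trials=1, seed=rng)
            t = classical_gc(panel.channel(0), panel.channel(1), p=1)
            rejections += t.p_value < 0.05
        assert rejections >= n_rep - 1

    def test_type_i_error_near_nominal(self, rng):
        # independent white noise series
        pvals = []
        for _ in range(200):
            x = rng.standard_normal((1, 100, 1))
            y = rng.standard_normal((1, 100, 1))
            from sdngc import TrialPanel

            t = classical_gc(TrialPanel(x), TrialPanel(y), p=1)
            pvals.append(t.p_value)
        rate = np.mean(np.asarray(pvals) < 0.05)
        # binomial 95% interval around 0.05 at n=200
        half = 1.96 * np.sqrt(0.05 * 0.95 / 200)
        assert 0.05 - half - 0.02 <= rate <= 0.05 + half + 0.02

    def test_short_series_error(self, rng):
        px, py = make_pair(rng, T=2)
        with pytest.raises(ValueError, match="short"):
            classical_gc(px, py, p=1)


class TestSdnGC:
    def test_df_for_scalar_pair(self, rng):
        px, py = make_pair(rng)
        t = sdn_gc(px, py, p=1, q=1)
        assert t.df == 2
        assert t.statistic >= -1e-6
        assert 0.0 <= t.p_value <= 1.0

    def test_variance_only_coupling_detected(self, rng):
        """Volatility-only influence is caught by the SDN test while the
        classical test stays near its nominal rate."""
        jm = scalar_pair_model(a=0.5, b=0.35, b_xy=0.6)
        sdn_hits = cls_hits = 0
        n_rep = 12
        for _ in range(n_rep):
            panel = simulate(jm, T=1000, n_trials=2, seed=rng)
            px, py = panel.channel(0), panel.channel(1)
            sdn_hits += sdn_gc(px, py, 1, 1).p_value < 0.01
            cls_hits += classical_gc(px, py, 1).p_value < 0.01
        assert sdn_hits > n_rep // 2
        assert cls_hits <= n_rep // 2

    def test_reduces_to_classical_without_volatility(self, rng):
        jm = scalar_pair_model(a=0.5, b=0.0, a_xy=0.3)
        jm.Bx, jm.By = [], []
        panel = simulate(jm, T=400, n_trials=2, seed=rng)
        px, py = panel.channel(0), panel.channel(1)
        t_sdn = sdn_gc(px, py, p=1, q=0)
        t_cls = classical_gc(px, py, p=1)
        assert t_sdn.df == t_cls.df == 1
        assert t_sdn.statistic == pytest.approx(t_cls.statistic, abs=1e-3)


class TestDifferenceDistribution:
    @pytest.mark.parametrize("df", [1, 2, 4, 7])
    def test_cdf_at_zero_is_half(self, df):
        assert difference_cdf(0.0, df) == 0.5

    def test_df2_closed_form_laplace(self):
        """The difference of two chi-squared(2) variables is Laplace with
        scale 2: two-sided tail exp(-d/2)."""
        for d in (1.0, 2.5, 4.61, 9.0):
            two_sided = 2 * difference_tail(d, 2)
            assert two_sided == pytest.approx(np.exp(-d / 2), rel=1e-6)
        assert 2 * difference_tail(4.61, 2) == pytest.approx(0.0997, abs=1e-3)

    def test_density_normalizes(self):
        for df in (1, 2, 4):
            val, _ = integrate.quad(lambda u: _vg_pdf(u, df), -np.inf, np.inf,
                                    limit=400)
            assert val == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("df", [1, 2, 4])
    def test_matches_monte_carlo(self, df, rng):
        sim = rng.chisquare(df, 100_000) - rng.chisquare(df, 100_000)
        grid = np.quantile(sim, np.linspace(0.01, 0.99, 25))
        srt = np.sort(sim)
        for d in grid:
            emp = np.searchsorted(srt, d, side="right") / sim.size
            assert difference_cdf(d, df) == pytest.approx(emp, abs=0.01)

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            difference_cdf(1.0, 0)
        with pytest.raises(ValueError):
            difference_cdf(1.0, 2.5)


class TestDifferenceTest:
    def test_equal_statistics(self):
        dt = difference_test(3.0, 3.0, df=2)
        assert dt.delta == 0.0
        assert dt.p_value == 1.0
        assert dt.dominant is None

    def test_antisymmetry(self):
        a = difference_test(7.0, 2.0, df=2)
        b = difference_test(2.0, 7.0, df=2)
        assert a.delta == -b.delta
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)

    def test_p_decreases_in_delta(self):
        ps = [difference_test(d, 0.0, df=2).p_value for d in (1, 2, 4, 8)]
        assert all(p1 > p2 for p1, p2 in zip(ps, ps[1:]))

    def test_dominant_direction_labeling(self):
        dt = difference_test(12.0, 1.0, df=2, alpha=0.05,
                             direction_forward="a->b",
                             direction_backward="b->a")
        assert dt.dominant == "a->b"

    def test_mismatched_df_rejected(self):
        with pytest.raises(ValueError):
            difference_test(1.0, 2.0, df=-1)


class TestPairTable:
    @pytest.fixture()
    def four_region_panel(self, rng):
        model = scalar_model(0.5, 0.4)
        panels = {f"r{i}": simulate(model, T=120, n_trials=4, seed=rng)
                  for i in range(4)}
        return panels

    def test_counts_and_bonferroni_divisor(self, four_region_panel):
        table = pair_table(four_region_panel, method="classical", alpha=0.05)
        assert table.n_tests == 12
        assert table.bonferroni_divisor == 12
        assert table.statistic.notna().sum().sum() == 12

    def test_region_relabeling_permutes_consistently(self, four_region_panel):
        t1 = pair_table(four_region_panel, method="classical")
        order = ["r2", "r0", "r3", "r1"]
        permuted = {k: four_region_panel[k] for k in order}
        t2 = pair_table(permuted, method="classical")
        for s in order:
            for t in order:
                if s != t:
                    assert t1.statistic.loc[s, t] == pytest.approx(
                        t2.statistic.loc[s, t], rel=1e-10
                    )

    def test_difference_matrix_antisymmetric(self, four_region_panel):
        table = pair_table(four_region_panel, method="classical")
        D = table.difference.to_numpy()
        mask = ~np.isnan(D)
        assert np.allclose(D[mask], -D.T[mask])

    def test_single_region_rejected(self, rng):
        model = scalar_model()
        with pytest.raises(ValueError, match="two regions"):
            pair_table({"only": simulate(model, T=50, n_trials=2, seed=rng)})

    def test_planted_link_recovered(self, rng):
        jm = scalar_pair_model(a=0.5, b=0.35, a_xy=0.5, b_xy=0.5)
        panel = simulate(jm, T=800, n_trials=2, seed=rng)
        table = pair_table({"x": panel.channel(0), "y": panel.channel(1)},
                           method="sdn", alpha=0.05)
        assert bool(table.significant.loc["y", "x"])
        assert not bool(table.significant.loc["x", "y"])
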