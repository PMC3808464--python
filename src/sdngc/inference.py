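"""Causal inference: classical Granger causality, the signal-dependent-noise
likelihood-ratio test, and the difference-of-causalities test.

Classical Granger causality for a target block x and source block y fits, by
pooled least squares, a restricted VAR (x on its own past) and a full VAR
(x on the past of both), and computes Geweke's measure
``F = ln det(Sigma_restricted) / det(Sigma_full)`` together with the
equivalent likelihood-ratio statistic ``G = n * F``, asymptotically
chi-squared with ``p * kx * ky`` degrees of freedom.

The signal-dependent-noise test replaces the VAR by the joint AR-BEKK model:
the full joint model is compared with the joint model whose tested
cross-coefficients (mean block and volatility columns) are held at zero.
``G = 2 (lnL_full - lnL_restricted)`` with ``(p + q) * kx * ky`` degrees of
freedom — the count of zeroed coefficients (2 for a univariate pair at
p = q = 1).

Because the two directed statistics of a pair are each approximately
chi-squared, their difference follows the symmetric variance-gamma (Bessel)
distribution; :func:`difference_cdf` evaluates it by quadrature of the
modified-Bessel density, and :func:`difference_test` uses the two-sided tail
to call a dominant direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, special, stats

from .estimation import FitResult, fit_joint
from .panel import TrialPanel

__all__ = [
    "CausalityTest",
    "DifferenceTest",
    "classical_gc",
    "sdn_gc",
    "difference_cdf",
    "difference_tail",
    "difference_test",
    "pair_table",
    "PairTable",
]


@dataclass
class CausalityTest:
    """Directed causality test result (source -> target)."""

    direction: str
    statistic: float
    df: int
    p_value: float
    method: str
    full_fit: FitResult
    restricted_fit: FitResult
    converged: bool = True
    geweke_f: float | None = None


@dataclass
class DifferenceTest:
    """Two-sided test on the difference of two directed causality statistics."""

    delta: float
    df: int
    p_value: float
    dominant: str | None
    direction_forward: str = "forward"
    direction_backward: str = "backward"


# ---------------------------------------------------------------------------
# Classical Granger causality (pooled least squares)
# ---------------------------------------------------------------------------

def _ols_gaussian_ll(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """OLS fit returning coefficients, ML residual covariance and log-likelihood."""
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    E = Y - X @ coef
    n, k = Y.shape
    Sigma = E.T @ E / n
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular residual covariance")
    ll = -0.5 * n * (k * np.log(2 * np.pi) + logdet + k)
    return coef, Sigma, float(ll)


def _lag_design(V: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    n, T, k = V.shape
    Y = V[:, p:, :].reshape(-1, k)
    X = np.concatenate([V[:, p - i : T - i, :] for i in range(1, p + 1)], axis=2)
    return Y, X.reshape(-1, k * p)


def classical_gc(panel_x: TrialPanel, panel_y: TrialPanel, p: int = 1) -> CausalityTest:
    """Classical Granger causality from the source ``panel_y`` to the target
    ``panel_x`` via nested pooled least-squares VAR fits."""
    if panel_x.values.shape[:2] != panel_y.values.shape[:2]:
        raise ValueError("panels have misaligned trial structure")
    if panel_x.n_times < p + 2:
        raise ValueError(f"series of length {panel_x.n_times} too short for p={p}")
    kx, ky = panel_x.n_channels, panel_y.n_channels
    Vx = panel_x.values
    Vz = np.concatenate([panel_x.values, panel_y.values], axis=2)

    Yr, Xr = _lag_design(Vx, p)
    coef_r, Sigma_r, ll_r = _ols_gaussian_ll(Yr, Xr)
    Yf, Xf = _lag_design(Vz, p)
    Yf = Yf[:, :kx]
    coef_f, Sigma_f, ll_f = _ols_gaussian_ll(Yf, Xf)

    n_obs = Yr.shape[0]
    sr = np.linalg.slogdet(Sigma_r)[1]
    sf = np.linalg.slogdet(Sigma_f)[1]
    F = float(sr - sf)
    G = 2.0 * (ll_f - ll_r)  # equals n_obs * F for ML covariances
    df = p * kx * ky
    p_value = float(stats.chi2.sf(max(G, 0.0), df))
    name_x = "+".join(panel_x.channel_names)
    name_y = "+".join(panel_y.channel_names)
    mk = lambda coef, Sigma, ll, npar: FitResult(
        model={"coef": coef.tolist(), "sigma": Sigma.tolist()},
        loglik=ll, n_params=npar, n_obs=n_obs, converged=True,
        algorithm="ols",
    )
    return CausalityTest(
        direction=f"{name_y}->{name_x}",
        statistic=float(G),
        df=df,
        p_value=p_value,
        method="classical",
        full_fit=mk(coef_f, Sigma_f, ll_f, p * kx * (kx + ky) + kx * (kx + 1) // 2),
        restricted_fit=mk(coef_r, Sigma_r, ll_r, p * kx * kx + kx * (kx + 1) // 2),
        geweke_f=F,
    )


# ---------------------------------------------------------------------------
# Signal-dependent-noise likelihood-ratio test
# ---------------------------------------------------------------------------

def sdn_gc(
    panel_x: TrialPanel,
    panel_y: TrialPanel,
    p: int = 1,
    q: int = 1,
    opts: dict | None = None,
    full_fit: FitResult | None = None,
) -> CausalityTest:
    """Likelihood-ratio test of the influence ``panel_y -> panel_x`` under the
    joint AR-BEKK model.

    The restricted fit zeroes the y->x mean block and the y-columns of the
    x-block volatility matrices.  ``full_fit`` may be supplied to reuse a
    previously fitted unrestricted model (it is direction-independent).
    With ``q = 0`` the model class reduces to the Gaussian VAR and the test
    coincides with classical Granger causality.
    """
    restricted_fit = fit_joint(
        panel_x, panel_y, p=p, q=q, restriction="y_to_x_zero", opts=opts
    )
    if full_fit is None:
        # warm-start the full fit from the restricted optimum so the nested
        # likelihood inequality holds up to optimizer tolerance
        full_fit = fit_joint(panel_x, panel_y, p=p, q=q, restriction="none",
                             opts=opts, start_models=[restricted_fit.model])
    G = 2.0 * (full_fit.loglik - restricted_fit.loglik)
    df = full_fit.n_params - restricted_fit.n_params
    p_value = float(stats.chi2.sf(max(G, 0.0), df))
    name_x = "+".join(panel_x.channel_names)
    name_y = "+".join(panel_y.channel_names)
    return CausalityTest(
        direction=f"{name_y}->{name_x}",
        statistic=float(G),
        df=int(df),
        p_value=p_value,
        method="sdn",
        full_fit=full_fit,
        restricted_fit=restricted_fit,
        converged=bool(full_fit.converged and restricted_fit.converged),
    )


# ---------------------------------------------------------------------------
# Difference-of-causalities distribution (symmetric variance-gamma)
# ---------------------------------------------------------------------------

def _check_df(df) -> int:
    if not float(df).is_integer() or df < 1:
        raise ValueError(f"degrees of freedom must be a positive integer, got {df}")
    return int(df)


def _vg_logpdf(u: np.ndarray, df: int) -> np.ndarray:
    """Log-density of D = X - Y with X, Y independent chi-squared(df).

    D is symmetric variance-gamma: with alpha = df/2 and rate lam = 1/2,
    f(u) = lam^(2 alpha) / (sqrt(pi) Gamma(alpha))
           * (|u| / (2 lam))^(alpha - 1/2) * K_(alpha - 1/2)(lam |u|).
    """
    alpha = df / 2.0
    lam = 0.5
    au = np.abs(np.asarray(u, dtype=float))
    nu = alpha - 0.5
    with np.errstate(divide="ignore"):
        logk = np.log(special.kv(nu, lam * au))
        logpow = nu * (np.log(au) - np.log(2 * lam))
    return (
        2 * alpha * np.log(lam)
        - 0.5 * np.log(np.pi)
        - special.gammaln(alpha)
        + logpow
        + logk
    )


def _vg_pdf(u, df: int):
    return np.exp(_vg_logpdf(u, df))


def difference_tail(d: float, df: int) -> float:
    """Upper tail P(D > d) for d >= 0, by quadrature of the Bessel density."""
    df = _check_df(df)
    d = float(d)
    if d < 0:
        return 1.0 - difference_tail(-d, df)
    val, _ = integrate.quad(lambda u: _vg_pdf(u, df), d, np.inf, limit=200)
    return float(min(max(val, 0.0), 1.0))


def difference_cdf(d: float, df: int) -> float:
    """CDF of the difference of two independent chi-squared(df) variables.

    By symmetry ``difference_cdf(0, df) == 0.5`` exactly.
    """
    df = _check_df(df)
    d = float(d)
    if d == 0.0:
        return 0.5
    if d < 0:
        return 1.0 - difference_cdf(-d, df)
    val, _ = integrate.quad(lambda u: _vg_pdf(u, df), 0.0, d,
                            limit=200, points=[0.0] if d > 0 else None)
    return float(min(0.5 + val, 1.0))


def difference_test(
    g_forward: float,
    g_backward: float,
    df: int,
    alpha: float = 0.05,
    direction_forward: str = "forward",
    direction_backward: str = "backward",
) -> DifferenceTest:
    """Two-sided test on ``D = G_forward - G_backward``.

    Under the null that the two directed causality statistics are independent
    chi-squared with the same ``df``, D follows the Bessel-density law of
    :func:`difference_cdf`.  ``dominant`` names the direction with the larger
    statistic when the two-sided p-value falls below ``alpha``.
    """
    df = _check_df(df)
    delta = float(g_forward) - float(g_backward)
    if delta == 0.0:
        p = 1.0
    else:
        p = min(1.0, 2.0 * difference_tail(abs(delta), df))
    dominant = None
    if p < alpha:
        dominant = direction_forward if delta > 0 else direction_backward
    return DifferenceTest(
        delta=delta,
        df=df,
        p_value=p,
        dominant=dominant,
        direction_forward=direction_forward,
        direction_backward=direction_backward,
    )


# ---------------------------------------------------------------------------
# All-pairs report (Tables 1/3 layout: causality from row to column)
# ---------------------------------------------------------------------------

@dataclass
class PairTable:
    """Directed test matrix plus difference-of-causalities matrix.

    ``statistic``/``p_value``/``significant`` are source-row by target-column
    DataFrames; ``difference`` holds the signed difference G(row->col) -
    G(col->row) with ``difference_significant`` flagging dominant directions.
    """

    method: str
    alpha: float
    n_tests: int
    bonferroni_divisor: int
    statistic: pd.DataFrame
    p_value: pd.DataFrame
    significant: pd.DataFrame
    converged: pd.DataFrame
    difference: pd.DataFrame
    difference_p: pd.DataFrame
    difference_significant: pd.DataFrame
    failures: list = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "method": self.method,
            "alpha": self.alpha,
            "n_tests": self.n_tests,
            "bonferroni_divisor": self.bonferroni_divisor,
            "statistic": self.statistic.to_dict(),
            "p_value": self.p_value.to_dict(),
            "significant": self.significant.astype(bool).to_dict(),
            "converged": self.converged.astype(bool).to_dict(),
            "difference": self.difference.to_dict(),
            "difference_p": self.difference_p.to_dict(),
            "difference_significant": self.difference_significant.astype(bool).to_dict(),
            "failures": self.failures,
        }

    def write(self, out_dir, prefix: str = "pair_table") -> None:
        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.statistic.to_csv(out / f"{prefix}_statistic.csv")
        self.p_value.to_csv(out / f"{prefix}_pvalue.csv")
        self.difference.to_csv(out / f"{prefix}_difference.csv")
        (out / f"{prefix}.json").write_text(json.dumps(self.to_json_dict(), indent=1))


def _split_regions(panels) -> dict[str, TrialPanel]:
    if isinstance(panels, TrialPanel):
        return {name: panels.channel(name) for name in panels.channel_names}
    return dict(panels)


def pair_table(
    panels,
    method: str = "sdn",
    p: int = 1,
    q: int = 1,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    difference_alpha: float | None = None,
    opts: dict | None = None,
) -> PairTable:
    """Run the chosen directed test for every ordered pair of regions.

    ``panels`` is either a mapping name -> univariate :class:`TrialPanel`
    with a common trial structure, or one multi-channel panel whose channels
    are the regions.  Significance uses a Bonferroni threshold
    ``alpha / n_tests`` over the directed tests actually run
    (``correction="none"`` disables the division).  Non-convergent pairs are
    recorded in ``failures`` and flagged in ``converged`` — never dropped.
    """
    regions = _split_regions(panels)
    names = list(regions)
    if len(names) < 2:
        raise ValueError("pair_table needs at least two regions")
    n_tests = len(names) * (len(names) - 1)
    divisor = n_tests if correction == "bonferroni" else 1
    threshold = alpha / divisor
    if difference_alpha is None:
        difference_alpha = alpha

    idx = pd.Index(names, name="source")
    cols = pd.Index(names, name="target")
    stat = pd.DataFrame(np.nan, index=idx, columns=cols)
    pval = pd.DataFrame(np.nan, index=idx, columns=cols)
    sig = pd.DataFrame(False, index=idx, columns=cols)
    conv = pd.DataFrame(True, index=idx, columns=cols)
    failures: list[str] = []

    tests: dict[tuple[str, str], CausalityTest] = {}
    if method == "classical":
        for src in names:
            for tgt in names:
                if src != tgt:
                    tests[(src, tgt)] = classical_gc(regions[tgt], regions[src], p=p)
    elif method == "sdn":
        # one unrestricted joint fit per unordered pair serves both directions
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                pa, pb = regions[a], regions[b]
                restr_fits = {
                    restriction: fit_joint(pa, pb, p=p, q=q,
                                           restriction=restriction, opts=opts)
                    for restriction in ("y_to_x_zero", "x_to_y_zero")
                }
                full = fit_joint(pa, pb, p=p, q=q, restriction="none", opts=opts,
                                 start_models=[f.model for f in restr_fits.values()])
                for src, tgt, restriction in (
                    (b, a, "y_to_x_zero"),
                    (a, b, "x_to_y_zero"),
                ):
                    restr = restr_fits[restriction]
                    G = 2.0 * (full.loglik - restr.loglik)
                    df = full.n_params - restr.n_params
                    tests[(src, tgt)] = CausalityTest(
                        direction=f"{src}->{tgt}",
                        statistic=float(G),
                        df=int(df),
                        p_value=float(stats.chi2.sf(max(G, 0.0), df)),
                        method="sdn",
                        full_fit=full,
                        restricted_fit=restr,
                        converged=bool(full.converged and restr.converged),
                    )
    else:
        raise ValueError(f"unknown method {method!r}")

    for (src, tgt), t in tests.items():
        stat.loc[src, tgt] = t.statistic
        pval.loc[src, tgt] = t.p_value
        sig.loc[src, tgt] = bool(t.p_value < threshold)
        conv.loc[src, tgt] = t.converged
        if not t.converged:
            failures.append(f"{src}->{tgt}: non-convergent fit")

    diff = pd.DataFrame(np.nan, index=idx, columns=cols)
    diff_p = pd.DataFrame(np.nan, index=idx, columns=cols)
    diff_sig = pd.DataFrame(False, index=idx, columns=cols)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ta, tb = tests[(a, b)], tests[(b, a)]
            dt = difference_test(
                ta.statistic, tb.statistic, df=ta.df, alpha=difference_alpha,
                direction_forward=f"{a}->{b}", direction_backward=f"{b}->{a}",
            )
            diff.loc[a, b] = dt.delta
            diff.loc[b, a] = -dt.delta
            diff_p.loc[a, b] = diff_p.loc[b, a] = dt.p_value
            if dt.dominant == f"{a}->{b}":
                diff_sig.loc[a, b] = True
            elif dt.dominant == f"{b}->{a}":
                diff_sig.loc[b, a] = True

    return PairTable(
        method=method,
        alpha=alpha,
        n_tests=n_tests,
        bonferroni_divisor=divisor,
        statistic=stat,
        p_value=pval,
        significant=sig,
        converged=conv,
        difference=diff,
        difference_p=diff_p,
        difference_significant=diff_sig,
        failures=failures,
    )
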