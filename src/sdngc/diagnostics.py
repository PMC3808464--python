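"""Projection-based diagnostics for signal-dependent noise.

The observed series is split into a "signal" (the part predictable from its
own past) and a "noise" (the residual, which produces the variation across
repeated trials).  The signal is estimated by least-squares projection of the
current value onto a subspace spanned by basis functions of the lagged
values — linear, second-order polynomial, or sixth-order Fourier bases — with
one coefficient vector fitted per channel, pooled over all trials.  The noise
variance at each within-trial time point is the across-trial variance of the
residuals at that point.

Signal-dependent noise shows up as a positive correlation, across within-trial
time points, between the squared estimated signal (trial-averaged) and the
estimated noise variance.  :func:`model_concordance` checks that the fitted
AR-BEKK model's one-step mean and conditional variance track these empirical
estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .arbekk import ARBEKKModel, JointARBEKKModel
from .estimation import FitResult
from .panel import TrialPanel

__all__ = [
    "BasisSpec",
    "EmpiricalSN",
    "build_design",
    "empirical_signal_noise",
    "sdn_correlation",
    "model_concordance",
    "DEFAULT_LAG_MAXIMA",
]

# default lag sweep maxima per basis family for the diagnostic sweep
DEFAULT_LAG_MAXIMA = {"linear": 9, "poly2": 6, "fourier6": 2}
_FOURIER_ORDER = 6


@dataclass(frozen=True)
class BasisSpec:
    """Projection-basis specification.

    ``family``: ``"linear"`` (lagged values), ``"poly2"`` (lagged values and
    their squares) or ``"fourier6"`` (order-1..6 sine/cosine pairs of each
    range-normalized lagged value).  Regressor count per lag is 1, 2 and 12
    respectively, plus an intercept when ``include_intercept``.
    """

    family: str = "poly2"
    n_lags: int = 1
    include_intercept: bool = True

    def __post_init__(self) -> None:
        if self.family not in ("linear", "poly2", "fourier6"):
            raise ValueError(f"unknown basis family {self.family!r}")
        if self.n_lags < 1:
            raise ValueError("n_lags must be >= 1")

    @property
    def n_regressors(self) -> int:
        per_lag = {"linear": 1, "poly2": 2, "fourier6": 2 * _FOURIER_ORDER}[self.family]
        return per_lag * self.n_lags + int(self.include_intercept)


def _basis_columns(lags: np.ndarray, spec: BasisSpec, lo: float, hi: float) -> np.ndarray:
    """Expand a (rows, n_lags) lag matrix into basis regressors."""
    if spec.family == "linear":
        cols = [lags]
    elif spec.family == "poly2":
        cols = [lags, lags**2]
    else:  # fourier6: rescale each lagged value to [-1, 1] by the panel range
        span = hi - lo
        if span <= 0:
            span = 1.0
        u = 2.0 * (lags - lo) / span - 1.0
        cols = []
        for j in range(1, _FOURIER_ORDER + 1):
            cols.append(np.sin(j * np.pi * u))
            cols.append(np.cos(j * np.pi * u))
    X = np.concatenate(cols, axis=1)
    if spec.include_intercept:
        X = np.column_stack([np.ones(X.shape[0]), X])
    return X


def build_design(
    panel: TrialPanel, spec: BasisSpec, channel: int = 0,
    condition_on: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Design matrix and response for one channel's projection.

    Rows are (trial, t) pairs with ``t >= condition_on`` (default: the number
    of lags; pass a larger common window when sweeping lag counts so nested
    projections are compared on the same rows).  Returns
    ``(X, y, trial_index, time_index)``.
    """
    V = panel.values[:, :, channel]
    n, T = V.shape
    L = spec.n_lags
    m = L if condition_on is None else int(condition_on)
    if m < L:
        raise ValueError(f"condition_on={m} must be >= n_lags={L}")
    if T < m + 2:
        raise ValueError(f"trial length {T} too short for n_lags={L}")
    lags = np.stack([V[:, m - j : T - j] for j in range(1, L + 1)], axis=2)
    rows = lags.reshape(-1, L)
    y = V[:, m:].reshape(-1)
    lo, hi = float(V.min()), float(V.max())
    X = _basis_columns(rows, spec, lo, hi)
    trial_idx = np.repeat(np.arange(n), T - m)
    time_idx = np.tile(np.arange(m, T), n)
    return X, y, trial_idx, time_idx


@dataclass
class EmpiricalSN:
    """Projection-based signal/noise estimates for a panel.

    ``signal_hat``/``residual`` have shape (n_trials, n_scored, n_channels)
    over the scored within-trial indices ``t_index``; ``noise_var`` (shape
    (n_scored, n_channels)) is the across-trial residual variance at each
    within-trial time point.  ``dropped_columns`` records collinear design
    columns removed per channel.
    """

    signal_hat: np.ndarray
    residual: np.ndarray
    noise_var: np.ndarray
    basis: BasisSpec
    r2: float
    t_index: np.ndarray
    panel: TrialPanel
    coefficients: list[np.ndarray] = field(default_factory=list)
    dropped_columns: list[list[int]] = field(default_factory=list)


def _lstsq_drop_collinear(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Least squares after dropping collinear columns (pivoted QR rank test)."""
    ncol = X.shape[1]
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size else 1.0)
    rank = int(np.sum(diag > tol))
    keep = np.sort(piv[:rank])
    dropped = sorted(set(range(ncol)) - set(keep.tolist()))
    beta = np.zeros(ncol)
    beta[keep], *_ = np.linalg.lstsq(X[:, keep], y, rcond=None)
    return beta, dropped


def empirical_signal_noise(
    panel: TrialPanel, spec: BasisSpec, min_trials: int = 10,
    condition_on: int | None = None,
) -> EmpiricalSN:
    """Estimate signal, residual noise and per-time-point noise variance.

    The projection is fitted pooled over all trials (one coefficient vector
    per channel); the noise variance at within-trial index t is the variance
    of the residuals across trials at that index.
    """
    n, T, k = panel.values.shape
    if n < min_trials:
        raise ValueError(
            f"{n} trials are too few to estimate across-trial noise variance "
            f"(need >= {min_trials})"
        )
    L = spec.n_lags if condition_on is None else int(condition_on)
    n_scored = T - L
    signal = np.empty((n, n_scored, k))
    resid = np.empty((n, n_scored, k))
    coefs, dropped_all = [], []
    ss_res = ss_tot = 0.0
    for c in range(k):
        X, y, trial_idx, _ = build_design(panel, spec, channel=c,
                                          condition_on=condition_on)
        beta, dropped = _lstsq_drop_collinear(X, y)
        yhat = X @ beta
        signal[:, :, c] = yhat.reshape(n, n_scored)
        resid[:, :, c] = (y - yhat).reshape(n, n_scored)
        coefs.append(beta)
        dropped_all.append(dropped)
        ss_res += float(np.sum((y - yhat) ** 2))
        ss_tot += float(np.sum((y - y.mean()) ** 2))
    noise_var = resid.var(axis=0, ddof=1)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return EmpiricalSN(
        signal_hat=signal,
        residual=resid,
        noise_var=noise_var,
        basis=spec,
        r2=r2,
        t_index=np.arange(L, T),
        panel=panel,
        coefficients=coefs,
        dropped_columns=dropped_all,
    )


def sdn_correlation(
    esn: EmpiricalSN, method: str = "pearson", pool_channels: bool = True
) -> tuple[float, float]:
    """Correlation between the trial-mean squared signal and the noise
    variance across within-trial time points.

    A significantly positive correlation is the signature of signal-dependent
    noise.  Channels are pooled by default; ``method`` may be ``"pearson"``
    (the relation is approximately linear) or ``"spearman"``.
    """
    mean_sq_signal = np.mean(esn.signal_hat**2, axis=0)  # (n_scored, k)
    noise_var = esn.noise_var
    if mean_sq_signal.shape[0] < 5:
        raise ValueError("need at least 5 within-trial time points")
    if pool_channels:
        xs, ys = mean_sq_signal.reshape(-1), noise_var.reshape(-1)
    else:
        xs, ys = mean_sq_signal[:, 0], noise_var[:, 0]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("constant inputs: correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(xs, ys)
    elif method == "spearman":
        r, p = stats.spearmanr(xs, ys)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r), float(p)


def _model_predictions(model, V: np.ndarray, t_index: np.ndarray):
    """One-step mean prediction and conditional variance diagonal at t_index."""
    n, T, k = V.shape
    mean = np.zeros((n, T, k))
    for i, Ai in enumerate(model.A, start=1):
        mean[:, i:, :] += V[:, :T - i, :] @ Ai.T
    if isinstance(model, JointARBEKKModel):
        B_list = [np.vstack([bx, by]) for bx, by in zip(model.Bx, model.By)]
        W = model.W_full()
    else:
        B_list, W = model.B, model.W
    var = np.broadcast_to(np.diag(W), (n, T, k)).copy()
    for j, Bj in enumerate(B_list, start=1):
        U = np.zeros((n, T, k))
        U[:, j:, :] = V[:, :T - j, :] @ Bj.T
        var[:, j:, :] += U[:, j:, :] ** 2
    m = max(model.p, model.q)
    usable = t_index[t_index >= m]
    return mean[:, usable, :], var[:, usable, :], usable


def model_concordance(fit: FitResult, esn: EmpiricalSN) -> tuple[float, float]:
    """Correlate the empirical signal/noise estimates with the model's.

    Returns ``(r_signal, r_variance)``: the correlation of the projection
    signal with the model's one-step mean prediction (pointwise over trials
    and scored times), and of the across-trial noise variance with the
    per-time average of the model conditional variance.  ``r_variance`` is
    NaN when the model variance is constant (the homoskedastic VAR case).
    """
    model = fit.model
    if not isinstance(model, (ARBEKKModel, JointARBEKKModel)):
        raise TypeError("model_concordance needs an AR-BEKK fit")
    V = esn.panel.values
    if V.shape[2] != model.k:
        raise ValueError("fit and empirical estimates come from different panels")
    mean, var, usable = _model_predictions(model, V, esn.t_index)
    sel = np.isin(esn.t_index, usable)
    emp_sig = esn.signal_hat[:, sel, :]
    emp_nv = esn.noise_var[sel, :]
    r_signal = float(np.corrcoef(emp_sig.reshape(-1), mean.reshape(-1))[0, 1])
    model_nv = var.mean(axis=0)
    if np.ptp(model_nv) < 1e-12:
        r_variance = float("nan")
    else:
        r_variance = float(np.corrcoef(emp_nv.reshape(-1), model_nv.reshape(-1))[0, 1])
    return r_signal, r_variance
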