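"""Exact conditional likelihood and constrained ML fitting of AR-BEKK models.

The conditional log-likelihood sums, over trials and over time points beyond
the conditioning window ``m = max(p, q)``::

    l_t = -0.5 * [ k ln(2 pi) + ln det H_t + r_t' H_t^{-1} r_t ]

with residual ``r_t = x_t - sum_i A_i x_{t-i}`` and conditional covariance
``H_t`` from the volatility recursion.  The first ``m`` observations of every
trial are conditioned on and never scored, in both full and restricted fits,
so likelihoods of nested models are comparable.

Fitting maximizes this likelihood subject to both stability conditions
(spectral radii kept below ``1 - margin``), with the baseline covariance
parameterized through its Cholesky factor so positive definiteness needs no
constraint.  The primary optimizer is an interior-point-style constrained
method (``trust-constr``), with an active-set-style method (``SLSQP``) as the
fallback when the primary fails to improve on the initial point.

Initialization follows a two-stage least-squares scheme: the mean matrices
come from per-equation OLS of the VAR, and the volatility terms start as
diagonal matrices obtained by regressing the squared AR residuals of each
channel on its squared lagged values (intercept -> baseline variance, slopes
-> squared volatility coefficients), floored to keep the start valid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import optimize

from .arbekk import (
    ARBEKKModel,
    JointARBEKKModel,
    companion_matrix,
    first_order_stable,
    second_moment_operator,
)
from .panel import TrialPanel

__all__ = [
    "FitResult",
    "LikelihoodError",
    "log_likelihood",
    "init_params",
    "init_joint_params",
    "fit",
    "fit_joint",
    "count_free_params",
]

LOG_2PI = float(np.log(2.0 * np.pi))
VAR_FLOOR = 1e-6  # floor for initial variance intercepts
DEFAULT_OPTS = {
    "maxiter": 500,
    "ftol": 1e-8,
    "margin": 1e-6,
    "methods": ("slsqp", "trust-constr"),
}


class LikelihoodError(RuntimeError):
    """The conditional covariance lost positive definiteness numerically."""


# ---------------------------------------------------------------------------
# Log-likelihood
# ---------------------------------------------------------------------------

def _cond_window(model) -> int:
    return max(model.p, model.q)


def log_likelihood(model: ARBEKKModel | JointARBEKKModel, panel: TrialPanel) -> float:
    """Exact conditional log-likelihood of ``panel`` under ``model``."""
    V = panel.values
    if V.shape[2] != model.k:
        raise ValueError(
            f"model dimension {model.k} does not match panel channels {V.shape[2]}"
        )
    m = _cond_window(model)
    if V.shape[1] <= m:
        raise ValueError(f"panel length {V.shape[1]} too short for orders (m={m})")
    if isinstance(model, JointARBEKKModel):
        return _joint_ll(model, V)
    return _marginal_ll(model, V)


def _residuals(V: np.ndarray, A: list[np.ndarray], m: int) -> np.ndarray:
    T = V.shape[1]
    R = V[:, m:, :].copy()
    for i, Ai in enumerate(A, start=1):
        R -= V[:, m - i : T - i, :] @ Ai.T
    return R


def _marginal_ll(model: ARBEKKModel, V: np.ndarray) -> float:
    m = _cond_window(model)
    R = _residuals(V, model.A, m)
    n, Tm, k = R.shape
    if k == 1:
        w = float(model.W[0, 0])
        h = np.full((n, Tm), w)
        T = V.shape[1]
        for j, Bj in enumerate(model.B, start=1):
            h += (V[:, m - j : T - j, 0] * float(Bj[0, 0])) ** 2
        if np.any(h <= 0):
            raise LikelihoodError("non-positive conditional variance")
        r = R[:, :, 0]
        return float(-0.5 * np.sum(LOG_2PI + np.log(h) + r * r / h))
    T = V.shape[1]
    H = np.broadcast_to(model.W, (n, Tm, k, k)).copy()
    for j, Bj in enumerate(model.B, start=1):
        U = V[:, m - j : T - j, :] @ Bj.T
        H += U[..., :, None] * U[..., None, :]
    return _gauss_ll_batch(R, H)


def _gauss_ll_batch(R: np.ndarray, H: np.ndarray) -> float:
    try:
        L = np.linalg.cholesky(H)
    except np.linalg.LinAlgError as exc:
        raise LikelihoodError("conditional covariance is not positive definite") from exc
    k = R.shape[-1]
    y = np.linalg.solve(L, R[..., None])[..., 0]
    quad = np.sum(y * y)
    logdet = 2.0 * np.sum(np.log(np.einsum("...ii->...i", L)))
    n_pts = R.shape[0] * R.shape[1]
    return float(-0.5 * (n_pts * k * LOG_2PI + logdet + quad))


def _joint_ll(model: JointARBEKKModel, V: np.ndarray) -> float:
    m = _cond_window(model)
    R = _residuals(V, model.A, m)
    T = V.shape[1]
    total = 0.0
    for rows, B_list, W in (
        (slice(0, model.kx), model.Bx, model.Wx),
        (slice(model.kx, model.k), model.By, model.Wy),
    ):
        Rb = R[:, :, rows]
        kb = Rb.shape[2]
        if kb == 1:
            w = float(W[0, 0])
            h = np.full(Rb.shape[:2], w)
            for j, Bj in enumerate(B_list, start=1):
                h += (V[:, m - j : T - j, :] @ Bj[0]) ** 2
            if np.any(h <= 0):
                raise LikelihoodError("non-positive conditional variance")
            r = Rb[:, :, 0]
            total += float(-0.5 * np.sum(LOG_2PI + np.log(h) + r * r / h))
        else:
            n, Tm = Rb.shape[:2]
            Hb = np.broadcast_to(W, (n, Tm, kb, kb)).copy()
            for j, Bj in enumerate(B_list, start=1):
                U = V[:, m - j : T - j, :] @ Bj.T
                Hb += U[..., :, None] * U[..., None, :]
            total += _gauss_ll_batch(Rb, Hb)
    return total


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def _pooled_var_ols(V: np.ndarray, p: int, m: int) -> tuple[list[np.ndarray], np.ndarray]:
    """Per-equation OLS of the VAR on trials pooled; returns A list + residuals."""
    n, T, k = V.shape
    Y = V[:, m:, :].reshape(-1, k)
    X = np.concatenate([V[:, m - i : T - i, :] for i in range(1, p + 1)], axis=2)
    X = X.reshape(-1, k * p)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    A = [coef[(i - 1) * k : i * k, :].T for i in range(1, p + 1)]
    E = Y - X @ coef
    return A, E


def init_params(panel: TrialPanel, p: int = 1, q: int = 1) -> ARBEKKModel:
    """Least-squares starting model: OLS mean, diagonal volatility from
    regressing squared residuals on squared lags; projected into the stable
    region if necessary."""
    V = panel.values
    n, T, k = V.shape
    m = max(p, q)
    if T <= m + 1:
        raise ValueError("panel too short for least-squares initialization")
    if float(np.var(V)) < 1e-12:
        raise ValueError("degenerate (constant) panel: cannot initialize")
    A, E = _pooled_var_ols(V, p, m)
    w = np.empty(k)
    Bdiag = np.zeros((q, k))
    for i in range(k):
        e2 = E[:, i] ** 2
        regs = [np.ones_like(e2)]
        for j in range(1, q + 1):
            regs.append((V[:, m - j : T - j, i].reshape(-1)) ** 2)
        X2 = np.column_stack(regs)
        beta, *_ = np.linalg.lstsq(X2, e2, rcond=None)
        w[i] = max(float(beta[0]), VAR_FLOOR)
        for j in range(q):
            Bdiag[j, i] = np.sqrt(max(float(beta[1 + j]), 0.0))
    B = [np.diag(Bdiag[j]) for j in range(q)]
    model = ARBEKKModel(A=A, B=B, W_chol=np.diag(np.sqrt(w)))
    return _project_stable(model)


def init_joint_params(
    panel: TrialPanel, kx: int, p: int = 1, q: int = 1, restriction: str = "none"
) -> JointARBEKKModel:
    """Starting joint model from the stacked panel, with restricted blocks zeroed."""
    base = init_params(panel, p, q)
    k = base.k
    ky = k - kx
    A = [Ai.copy() for Ai in base.A]
    Bx = [Bj[:kx, :].copy() for Bj in base.B]
    By = [Bj[kx:, :].copy() for Bj in base.B]
    W = base.W
    model = JointARBEKKModel(
        kx=kx,
        ky=ky,
        A=A,
        Bx=Bx,
        By=By,
        Wx_chol=np.linalg.cholesky(W[:kx, :kx]),
        Wy_chol=np.linalg.cholesky(W[kx:, kx:]),
        restriction=restriction,
    )
    _apply_restriction(model)
    return _project_stable(model)


def _apply_restriction(model: JointARBEKKModel) -> None:
    kx = model.kx
    if model.restriction == "y_to_x_zero":
        for Ai in model.A:
            Ai[:kx, kx:] = 0.0
        for Bj in model.Bx:
            Bj[:, kx:] = 0.0
    elif model.restriction == "x_to_y_zero":
        for Ai in model.A:
            Ai[kx:, :kx] = 0.0
        for Bj in model.By:
            Bj[:, :kx] = 0.0


def _project_stable(model, target: float = 0.95):
    """Shrink coefficients until both stability radii are below ``target``."""
    _, r1 = first_order_stable(model.A)
    if r1 >= target:
        scale = target / (r1 + 1e-12)
        for Ai in model.A:
            Ai *= scale
    if model.p <= 1 and model.q <= 1:
        for _ in range(200):
            M = second_moment_operator(model)
            r2 = float(np.max(np.abs(np.linalg.eigvals(M))))
            if r2 < target:
                break
            blist = (
                model.Bx + model.By if isinstance(model, JointARBEKKModel) else model.B
            )
            if any(np.any(b != 0) for b in blist):
                for b in blist:
                    b *= 0.9
            else:
                for Ai in model.A:
                    Ai *= 0.95
    return model


# ---------------------------------------------------------------------------
# Parameter vector mapping
# ---------------------------------------------------------------------------

def _tril_indices(k: int):
    return np.tril_indices(k)


class _ParamMap:
    """Bijection between a model's free coefficients and a flat vector."""

    def __init__(self, template: ARBEKKModel | JointARBEKKModel):
        self.joint = isinstance(template, JointARBEKKModel)
        self.template = template
        self.p, self.q = template.p, template.q
        if self.joint:
            k, kx = template.k, template.kx
            self.k, self.kx, self.ky = k, kx, template.ky
            amask = np.ones((k, k), dtype=bool)
            bxmask = np.ones((template.kx, k), dtype=bool)
            bymask = np.ones((template.ky, k), dtype=bool)
            if template.restriction == "y_to_x_zero":
                amask[:kx, kx:] = False
                bxmask[:, kx:] = False
            elif template.restriction == "x_to_y_zero":
                amask[kx:, :kx] = False
                bymask[:, :kx] = False
            self.amask, self.bxmask, self.bymask = amask, bxmask, bymask
            from .arbekk import _block_diag_mask

            self._vec_mask = _block_diag_mask(template.kx, template.ky)
            self.n_params = (
                self.p * int(amask.sum())
                + self.q * (int(bxmask.sum()) + int(bymask.sum()))
                + kx * (kx + 1) // 2
                + self.ky * (self.ky + 1) // 2
            )
        else:
            k = template.k
            self.k = k
            self.n_params = self.p * k * k + self.q * k * k + k * (k + 1) // 2

    def pack(self, model) -> np.ndarray:
        parts = []
        if self.joint:
            for Ai in model.A:
                parts.append(Ai[self.amask])
            for Bj in model.Bx:
                parts.append(Bj[self.bxmask])
            for Bj in model.By:
                parts.append(Bj[self.bymask])
            parts.append(model.Wx_chol[_tril_indices(self.kx)])
            parts.append(model.Wy_chol[_tril_indices(self.ky)])
        else:
            for Ai in model.A:
                parts.append(Ai.reshape(-1))
            for Bj in model.B:
                parts.append(Bj.reshape(-1))
            parts.append(model.W_chol[_tril_indices(self.k)])
        return np.concatenate(parts)

    def unpack(self, theta: np.ndarray):
        theta = np.asarray(theta, dtype=float)
        pos = 0

        def take(count):
            nonlocal pos
            out = theta[pos : pos + count]
            pos += count
            return out

        if self.joint:
            k, kx, ky = self.k, self.kx, self.ky
            A = []
            for _ in range(self.p):
                Ai = np.zeros((k, k))
                Ai[self.amask] = take(int(self.amask.sum()))
                A.append(Ai)
            Bx, By = [], []
            for _ in range(self.q):
                Bj = np.zeros((kx, k))
                Bj[self.bxmask] = take(int(self.bxmask.sum()))
                Bx.append(Bj)
            for _ in range(self.q):
                Bj = np.zeros((ky, k))
                Bj[self.bymask] = take(int(self.bymask.sum()))
                By.append(Bj)
            Lx = np.zeros((kx, kx))
            Lx[_tril_indices(kx)] = take(kx * (kx + 1) // 2)
            Ly = np.zeros((ky, ky))
            Ly[_tril_indices(ky)] = take(ky * (ky + 1) // 2)
            return JointARBEKKModel(
                kx=kx, ky=ky, A=A, Bx=Bx, By=By,
                Wx_chol=Lx, Wy_chol=Ly, restriction=self.template.restriction,
            )
        k = self.k
        A = [take(k * k).reshape(k, k).copy() for _ in range(self.p)]
        B = [take(k * k).reshape(k, k).copy() for _ in range(self.q)]
        L = np.zeros((k, k))
        L[_tril_indices(k)] = take(k * (k + 1) // 2)
        return ARBEKKModel(A=A, B=B, W_chol=L)


def count_free_params(model: ARBEKKModel | JointARBEKKModel) -> int:
    """Number of free parameters (restriction-aware)."""
    return _ParamMap(model).n_params


def _pmap_radii(pmap: _ParamMap, theta: np.ndarray) -> np.ndarray:
    """Both stability radii straight from the parameter vector (p = q <= 1).

    Avoids building model objects: the constraint functions are evaluated
    thousands of times per fit by the finite-difference machinery.
    """
    theta = np.asarray(theta, dtype=float)
    k = pmap.k
    if pmap.joint:
        na = int(pmap.amask.sum())
        A1 = np.zeros((k, k))
        A1[pmap.amask] = theta[:na]
        pos = na
        if pmap.q == 1:
            nbx = int(pmap.bxmask.sum())
            nby = int(pmap.bymask.sum())
            Bt = np.zeros((k, k))
            Bt[: pmap.kx][pmap.bxmask] = theta[pos : pos + nbx]
            Bt[pmap.kx :][pmap.bymask] = theta[pos + nbx : pos + nbx + nby]
        else:
            Bt = None
    else:
        A1 = theta[: k * k].reshape(k, k)
        Bt = theta[k * k : 2 * k * k].reshape(k, k) if pmap.q == 1 else None
    r1 = float(np.max(np.abs(np.linalg.eigvals(A1))))
    M = _small_kron(A1, A1)
    if Bt is not None:
        BB = _small_kron(Bt, Bt)
        if pmap.joint:
            BB[~pmap._vec_mask, :] = 0.0
        M = M + BB
    r2 = float(np.max(np.abs(np.linalg.eigvals(M))))
    return np.array([r1, r2])


def _small_kron(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    k = a.shape[0]
    return (a[:, None, :, None] * b[None, :, None, :]).reshape(k * k, k * k)


# ---------------------------------------------------------------------------
# Analytic gradient for univariate blocks (the workhorse p=q<=1 case)
# ---------------------------------------------------------------------------

def _scalar_block_ll_grad(xt, Z, a, b, l):
    """Log-likelihood and gradient for one univariate block.

    xt: (N,) target; Z: (N, d) lagged regressors; a: (d,) mean row;
    b: (d,) volatility row or None (q=0); l: scalar Cholesky of baseline var.
    """
    r = xt - Z @ a
    if b is None:
        h = np.full_like(r, l * l)
        s = None
    else:
        s = Z @ b
        h = l * l + s * s
    if np.any(h <= 0):
        raise LikelihoodError("non-positive conditional variance")
    ll = -0.5 * np.sum(LOG_2PI + np.log(h) + r * r / h)
    inv_h = 1.0 / h
    g_a = Z.T @ (r * inv_h)
    c = (r * r * inv_h - 1.0) * inv_h
    g_b = Z.T @ (c * s) if b is not None else None
    g_l = l * np.sum(c)
    return float(ll), g_a, g_b, float(g_l)


def _make_objective(pmap: _ParamMap, panel: TrialPanel) -> tuple[Callable, bool]:
    """Negative mean log-likelihood; analytic gradient for scalar blocks."""
    V = panel.values
    n, T, k = V.shape
    m = max(pmap.p, pmap.q)
    n_obs = n * (T - m)
    scale = 1.0 / n_obs

    scalar = (
        pmap.p <= 1
        and pmap.q <= 1
        and ((pmap.joint and pmap.kx == 1 and pmap.ky == 1) or (not pmap.joint and pmap.k == 1))
    )
    if not scalar:
        def objective(theta):
            model = pmap.unpack(theta)
            try:
                return -scale * log_likelihood(model, panel)
            except LikelihoodError:
                return 1e10
        return objective, False

    Z = V[:, m - 1 : T - 1, :].reshape(-1, k)  # lag-1 states
    if pmap.joint:
        tx = V[:, m:, 0].reshape(-1)
        ty = V[:, m:, 1].reshape(-1)
        has_b = pmap.q == 1
        na = int(pmap.amask.sum())
        nbx = int(pmap.bxmask.sum()) if has_b else 0
        nby = int(pmap.bymask.sum()) if has_b else 0
        ax_mask = pmap.amask[0]
        ay_mask = pmap.amask[1]
        nax = int(ax_mask.sum())
        bx_mask = pmap.bxmask[0] if has_b else None
        by_mask = pmap.bymask[0] if has_b else None

        def objective(theta):
            pos = 0
            a_free = theta[pos : pos + na]; pos += na
            ax = np.zeros(2); ax[ax_mask] = a_free[:nax]
            ay = np.zeros(2); ay[ay_mask] = a_free[nax:]
            if has_b:
                bx = np.zeros(2); bx[bx_mask] = theta[pos : pos + nbx]; pos += nbx
                by = np.zeros(2); by[by_mask] = theta[pos : pos + nby]; pos += nby
            else:
                bx = by = None
            lx = theta[pos]; ly = theta[pos + 1]
            try:
                llx, gax, gbx, glx = _scalar_block_ll_grad(tx, Z, ax, bx, lx)
                lly, gay, gby, gly = _scalar_block_ll_grad(ty, Z, ay, by, ly)
            except LikelihoodError:
                return 1e10, np.zeros_like(theta)
            grad = np.empty_like(theta)
            pos = 0
            grad[pos : pos + nax] = gax[ax_mask]; pos += nax
            grad[pos : pos + na - nax] = gay[ay_mask]; pos += na - nax
            if has_b:
                grad[pos : pos + nbx] = gbx[bx_mask]; pos += nbx
                grad[pos : pos + nby] = gby[by_mask]; pos += nby
            grad[pos] = glx
            grad[pos + 1] = gly
            return -scale * (llx + lly), -scale * grad
        return objective, True

    # marginal k=1
    xt = V[:, m:, 0].reshape(-1)
    Z1 = V[:, m - 1 : T - 1, 0].reshape(-1, 1)
    has_b = pmap.q == 1

    def objective(theta):
        a = theta[0:1]
        if has_b:
            b = theta[1:2]
            l = theta[2]
        else:
            b = None
            l = theta[1]
        try:
            ll, ga, gb, gl = _scalar_block_ll_grad(xt, Z1, a, b, l)
        except LikelihoodError:
            return 1e10, np.zeros_like(theta)
        grad = np.empty_like(theta)
        grad[0] = ga[0]
        if has_b:
            grad[1] = gb[0]
            grad[2] = gl
        else:
            grad[1] = gl
        return -scale * ll, -scale * grad

    return objective, True


# ---------------------------------------------------------------------------
# Constrained fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Outcome of a constrained maximum-likelihood fit."""

    model: ARBEKKModel | JointARBEKKModel
    loglik: float
    n_params: int
    n_obs: int
    converged: bool
    algorithm: str
    optimizer_trace: dict = field(default_factory=dict)

    def to_json(self) -> str:
        m = self.model
        if isinstance(m, JointARBEKKModel):
            coeffs = {
                "kind": "joint",
                "kx": m.kx, "ky": m.ky,
                "A": [a.tolist() for a in m.A],
                "Bx": [b.tolist() for b in m.Bx],
                "By": [b.tolist() for b in m.By],
                "Wx": m.Wx.tolist(), "Wy": m.Wy.tolist(),
                "restriction": m.restriction,
            }
        else:
            coeffs = {
                "kind": "marginal",
                "A": [a.tolist() for a in m.A],
                "B": [b.tolist() for b in m.B],
                "W": m.W.tolist(),
            }
        return json.dumps(
            {
                "model": coeffs,
                "loglik": self.loglik,
                "n_params": self.n_params,
                "n_obs": self.n_obs,
                "converged": self.converged,
                "algorithm": self.algorithm,
                "optimizer_trace": self.optimizer_trace,
            },
            indent=1,
        )


def _radii(pmap: _ParamMap, theta: np.ndarray) -> np.ndarray:
    return _pmap_radii(pmap, theta)


def _optimize(pmap, objective, has_grad, theta0, opts) -> list:
    margin = opts["margin"]
    bound = 1.0 - margin

    def cons_fun(theta):
        return bound - _radii(pmap, theta)

    candidates = []
    methods = opts.get("methods", DEFAULT_OPTS["methods"])
    import warnings

    for method in methods:
        try:
            if method == "trust-constr":
                nlc = optimize.NonlinearConstraint(cons_fun, 0.0, np.inf)
                with warnings.catch_warnings():
                    # quasi-Newton curvature updates can degenerate harmlessly
                    warnings.simplefilter("ignore", UserWarning)
                    res = optimize.minimize(
                        objective,
                        theta0,
                        jac=has_grad,
                        method="trust-constr",
                        constraints=[nlc],
                        options={"maxiter": opts["maxiter"], "gtol": opts["ftol"],
                                 "xtol": opts["ftol"]},
                    )
            else:
                cons = [{"type": "ineq", "fun": lambda th, i=i: cons_fun(th)[i]}
                        for i in range(2)]
                res = optimize.minimize(
                    objective,
                    theta0,
                    jac=has_grad,
                    method="SLSQP",
                    constraints=cons,
                    options={"maxiter": opts["maxiter"], "ftol": opts["ftol"]},
                )
            candidates.append((method, res))
            if res.success and np.all(cons_fun(res.x) > -1e-9):
                break
        except (LikelihoodError, np.linalg.LinAlgError) as exc:  # pragma: no cover
            candidates.append((method, optimize.OptimizeResult(
                x=theta0, fun=np.inf, success=False, message=str(exc))))
    return candidates


def _finish_fit(pmap, panel, starts, opts) -> FitResult:
    objective, has_grad = _make_objective(pmap, panel)

    def obj_val(theta):
        out = objective(theta)
        return out[0] if has_grad else out

    margin_feas = 1.0 - opts["margin"] / 2
    scored = []
    for th in starts:
        feasible = bool(np.all(_radii(pmap, th) <= margin_feas))
        scored.append((obj_val(th), feasible, th))
    feasible_starts = [s for s in scored if s[1]] or scored
    f0, _, theta0 = min(feasible_starts, key=lambda s: s[0])
    candidates = _optimize(pmap, objective, has_grad, theta0, opts)

    margin = opts["margin"]
    best_theta, best_f, best_alg, best_res = theta0, f0, "initial", None
    converged = False
    for method, res in candidates:
        if not np.all(np.isfinite(res.x)):
            continue
        radii = _radii(pmap, res.x)
        feasible = np.all(radii <= 1.0 - margin / 2)
        if feasible and res.fun < best_f:
            best_theta, best_f, best_alg, best_res = res.x, res.fun, method, res
            converged = bool(res.success)
        elif res.success and feasible and best_res is None:
            best_res = res

    V = panel.values
    m = max(pmap.p, pmap.q)
    n_obs = V.shape[0] * (V.shape[1] - m)
    model = pmap.unpack(best_theta)
    trace = {
        "initial_negloglik_per_obs": float(f0),
        "attempts": [
            {"method": meth, "success": bool(r.success),
             "message": str(getattr(r, "message", "")),
             "nit": int(getattr(r, "nit", -1)),
             "fun": float(r.fun) if np.isfinite(r.fun) else None}
            for meth, r in candidates
        ],
    }
    return FitResult(
        model=model,
        loglik=float(-best_f * n_obs),
        n_params=pmap.n_params,
        n_obs=n_obs,
        converged=converged,
        algorithm=best_alg,
        optimizer_trace=trace,
    )


def fit(
    panel: TrialPanel,
    p: int = 1,
    q: int = 1,
    opts: dict | None = None,
    start_models: list | None = None,
) -> FitResult:
    """Constrained ML fit of the single-block AR-BEKK model."""
    if q > 1 or p > 1:
        raise ValueError("constrained fitting supports p, q <= 1")
    opts = {**DEFAULT_OPTS, **(opts or {})}
    init = init_params(panel, p, q)
    pmap = _ParamMap(init)
    starts = [pmap.pack(init)] + [pmap.pack(m) for m in (start_models or [])]
    return _finish_fit(pmap, panel, starts, opts)


def fit_joint(
    panel_x: TrialPanel,
    panel_y: TrialPanel,
    p: int = 1,
    q: int = 1,
    restriction: str = "none",
    opts: dict | None = None,
    start_models: list | None = None,
) -> FitResult:
    """Constrained ML fit of the partitioned joint AR-BEKK model.

    Under ``restriction="y_to_x_zero"`` the y->x mean block and the y-columns
    of Bx are held at zero (and symmetrically for ``"x_to_y_zero"``).
    ``start_models`` supplies extra warm starts (e.g. a restricted solution
    when fitting the full model, which guarantees the nesting inequality up
    to optimizer tolerance); the best feasible start is used.
    """
    if q > 1 or p > 1:
        raise ValueError("joint fitting supports p, q <= 1")
    if panel_x.values.shape[:2] != panel_y.values.shape[:2]:
        raise ValueError("panels have misaligned trial structure")
    opts = {**DEFAULT_OPTS, **(opts or {})}
    stacked = panel_x.stack(panel_y)
    init = init_joint_params(stacked, kx=panel_x.n_channels, p=p, q=q,
                             restriction=restriction)
    pmap = _ParamMap(init)
    starts = [pmap.pack(init)] + [pmap.pack(m) for m in (start_models or [])]
    return _finish_fit(pmap, stacked, starts, opts)
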