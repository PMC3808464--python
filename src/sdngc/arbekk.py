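"""The AR-BEKK process: autoregressive mean with signal-dependent noise.

The model couples the conditional covariance of the innovations to the past of
the *process itself* (not, as in residual-driven BEKK volatility models, to the
past residuals).  For a k-dimensional series ``x_t``::

    x_t = sum_i A_i x_{t-i} + H_t^{1/2} eps_t
    H_t = W + sum_j B_j x_{t-j} x_{t-j}' B_j'

with ``eps_t`` i.i.d. standard Gaussian.  The quadratic form makes ``H_t``
positive definite by construction and makes the noise variance a quadratic
function of the signal ("signal-dependent noise").  With all ``B_j = 0`` the
conditional covariance is time invariant and the model reduces to an ordinary
Gaussian VAR.

For causal testing a partitioned two-block version over ``z_t = (x_t, y_t)``
is used, in which the two blocks' innovation processes are independent, so the
joint conditional covariance is block-diagonal::

    Hx_t = Wx + sum_j (Bx_j z_{t-j})(Bx_j z_{t-j})'     (and likewise Hy_t)

Cross-coefficients of the mean matrices and the y-columns of ``Bx`` encode a
directed influence y -> x in the mean and in the variance respectively.

Stability requires (i) the mean recursion to be stable (spectral radius of the
companion matrix below one) and (ii), for the first-order model, the
second-moment operator ``A (x) A + B (x) B`` (Kronecker products; with a
block-diagonal projection in the joint case) to have spectral radius below
one, which guarantees a finite stationary second moment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .panel import TrialPanel

__all__ = [
    "ARBEKKModel",
    "JointARBEKKModel",
    "UnstableModelError",
    "first_order_stable",
    "second_order_stable",
    "second_moment_operator",
    "conditional_covariance",
    "stationary_second_moment",
    "simulate",
]

DEFAULT_BURN_IN = 500  # samples discarded before each recorded trial


class UnstableModelError(RuntimeError):
    """Simulation or moment computation requested for an unstable model."""


def _as_matrix_list(mats: Sequence[np.ndarray] | np.ndarray, name: str) -> list[np.ndarray]:
    if isinstance(mats, np.ndarray) and mats.ndim <= 2:
        mats = [mats]
    out = []
    for m in mats:
        m = np.atleast_2d(np.asarray(m, dtype=float))
        if m.shape[0] != m.shape[1] and name == "A":
            raise ValueError(f"{name} matrices must be square, got {m.shape}")
        out.append(m)
    if len(out) == 0:
        return out
    shapes = {m.shape for m in out}
    if len(shapes) != 1:
        raise ValueError(f"{name} matrices have mismatched shapes: {shapes}")
    return out


@dataclass
class ARBEKKModel:
    """Coefficients of the (single-block) AR-BEKK model.

    ``A`` holds the p mean matrices, ``B`` the q volatility matrices and
    ``W_chol`` a lower-triangular factor of the baseline conditional
    covariance ``W = W_chol @ W_chol.T``.  ``q = 0`` (empty ``B``) is the
    Gaussian VAR special case.
    """

    A: list[np.ndarray]
    B: list[np.ndarray] = field(default_factory=list)
    W_chol: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.A = _as_matrix_list(self.A, "A")
        self.B = _as_matrix_list(self.B, "B") if len(self.B) else []
        if not self.A:
            raise ValueError("at least one mean matrix is required")
        k = self.A[0].shape[0]
        if self.W_chol is None:
            self.W_chol = np.eye(k)
        self.W_chol = np.atleast_2d(np.asarray(self.W_chol, dtype=float))
        if self.W_chol.shape != (k, k):
            raise ValueError("W_chol shape does not match process dimension")
        for m in self.B:
            if m.shape != (k, k):
                raise ValueError("B matrices must match process dimension")

    @property
    def k(self) -> int:
        return self.A[0].shape[0]

    @property
    def p(self) -> int:
        return len(self.A)

    @property
    def q(self) -> int:
        return len(self.B)

    @property
    def W(self) -> np.ndarray:
        return self.W_chol @ self.W_chol.T


@dataclass
class JointARBEKKModel:
    """Partitioned two-block AR-BEKK model over z = (x, y) for causal testing.

    ``A`` are (kx+ky) square mean matrices over the stacked state; ``Bx``
    (shape kx x (kx+ky)) and ``By`` (ky x (kx+ky)) feed the x- and y-block
    conditional covariances.  The two innovation processes are independent,
    so the joint conditional covariance is blockdiag(Hx_t, Hy_t).

    ``restriction`` records which causal direction, if any, is constrained
    to zero: under ``"y_to_x_zero"`` the x-row/y-column block of every mean
    matrix and the y-columns of every ``Bx`` are identically zero.
    """

    kx: int
    ky: int
    A: list[np.ndarray]
    Bx: list[np.ndarray] = field(default_factory=list)
    By: list[np.ndarray] = field(default_factory=list)
    Wx_chol: np.ndarray = None  # type: ignore[assignment]
    Wy_chol: np.ndarray = None  # type: ignore[assignment]
    restriction: str = "none"

    def __post_init__(self) -> None:
        k = self.kx + self.ky
        self.A = _as_matrix_list(self.A, "A")
        self.Bx = _as_matrix_list(self.Bx, "Bx") if len(self.Bx) else []
        self.By = _as_matrix_list(self.By, "By") if len(self.By) else []
        if self.Wx_chol is None:
            self.Wx_chol = np.eye(self.kx)
        if self.Wy_chol is None:
            self.Wy_chol = np.eye(self.ky)
        self.Wx_chol = np.atleast_2d(np.asarray(self.Wx_chol, dtype=float))
        self.Wy_chol = np.atleast_2d(np.asarray(self.Wy_chol, dtype=float))
        for m in self.A:
            if m.shape != (k, k):
                raise ValueError("joint A matrices must be (kx+ky) square")
        for m in self.Bx:
            if m.shape != (self.kx, k):
                raise ValueError("Bx matrices must be kx x (kx+ky)")
        for m in self.By:
            if m.shape != (self.ky, k):
                raise ValueError("By matrices must be ky x (kx+ky)")
        if self.restriction not in ("none", "y_to_x_zero", "x_to_y_zero"):
            raise ValueError(f"unknown restriction {self.restriction!r}")
        if len(self.Bx) != len(self.By):
            raise ValueError("Bx and By must have the same order q")

    @property
    def k(self) -> int:
        return self.kx + self.ky

    @property
    def p(self) -> int:
        return len(self.A)

    @property
    def q(self) -> int:
        return len(self.Bx)

    @property
    def Wx(self) -> np.ndarray:
        return self.Wx_chol @ self.Wx_chol.T

    @property
    def Wy(self) -> np.ndarray:
        return self.Wy_chol @ self.Wy_chol.T

    def stacked_B(self) -> list[np.ndarray]:
        """Full (kx+ky)-square volatility matrices [Bx_j; By_j]."""
        return [np.vstack([bx, by]) for bx, by in zip(self.Bx, self.By)]

    def W_full(self) -> np.ndarray:
        W = np.zeros((self.k, self.k))
        W[: self.kx, : self.kx] = self.Wx
        W[self.kx :, self.kx :] = self.Wy
        return W


# ---------------------------------------------------------------------------
# Stability
# ---------------------------------------------------------------------------

def companion_matrix(A: Sequence[np.ndarray]) -> np.ndarray:
    """Companion embedding of the VAR(p) mean recursion."""
    A = _as_matrix_list(A, "A")
    k, p = A[0].shape[0], len(A)
    C = np.zeros((k * p, k * p))
    C[:k, :] = np.hstack(A)
    if p > 1:
        C[k:, : k * (p - 1)] = np.eye(k * (p - 1))
    return C


def first_order_stable(A: Sequence[np.ndarray]) -> tuple[bool, float]:
    """First-order (mean) stability: companion spectral radius below one."""
    radius = float(np.max(np.abs(np.linalg.eigvals(companion_matrix(A)))))
    return radius < 1.0, radius


def _block_diag_mask(kx: int, ky: int) -> np.ndarray:
    """vec-ordering mask selecting entries inside the two diagonal blocks."""
    k = kx + ky
    block = np.array([0] * kx + [1] * ky)
    same = block[:, None] == block[None, :]
    return same.reshape(-1, order="F")


def second_moment_operator(model: ARBEKKModel | JointARBEKKModel) -> np.ndarray:
    """The k^2 x k^2 operator of the stationary second-moment recursion.

    For the single-block model this is ``A1 (x) A1 + B1 (x) B1``.  For the
    joint model the volatility term is projected onto the block-diagonal
    entries of vec(S), because the joint conditional covariance is
    blockdiag(Hx, Hy).
    """
    if model.p > 1 or model.q > 1:
        raise ValueError(
            "second-order stability is defined for the first-order model "
            f"(p=q=1); got p={model.p}, q={model.q}"
        )
    A1 = model.A[0]
    M = np.kron(A1, A1)
    if isinstance(model, JointARBEKKModel):
        if model.q == 1:
            Bt = model.stacked_B()[0]
            BB = np.kron(Bt, Bt)
            mask = _block_diag_mask(model.kx, model.ky)
            BB[~mask, :] = 0.0
            M = M + BB
    else:
        if model.q == 1:
            B1 = model.B[0]
            M = M + np.kron(B1, B1)
    return M


def second_order_stable(model: ARBEKKModel | JointARBEKKModel) -> tuple[bool, float]:
    """Second-order stability: spectral radius of the moment operator < 1."""
    M = second_moment_operator(model)
    radius = float(np.max(np.abs(np.linalg.eigvals(M))))
    return radius < 1.0, radius


def is_stable(model: ARBEKKModel | JointARBEKKModel) -> bool:
    ok1, _ = first_order_stable(model.A)
    if model.p <= 1 and model.q <= 1:
        ok2, _ = second_order_stable(model)
    else:  # higher-order mean: only the first-order condition is available
        ok2 = True
    return ok1 and ok2


# ---------------------------------------------------------------------------
# Conditional covariance and stationary moments
# ---------------------------------------------------------------------------

def conditional_covariance(model: ARBEKKModel, history: np.ndarray) -> np.ndarray:
    """Conditional covariance H_t = W + sum_j B_j x_{t-j} x_{t-j}' B_j'.

    ``history`` has shape (m, k) with ``history[-j]`` the state at lag j.
    """
    history = np.atleast_2d(np.asarray(history, dtype=float))
    if history.shape[0] < model.q:
        raise ValueError(
            f"history of length {history.shape[0]} is insufficient for q={model.q}"
        )
    H = model.W.copy()
    for j, Bj in enumerate(model.B, start=1):
        v = Bj @ history[-j]
        H += np.outer(v, v)
    return H


def stationary_second_moment(model: ARBEKKModel | JointARBEKKModel) -> np.ndarray:
    """Solve the fixed point vec(S) = M vec(S) + vec(W) of the first-order model."""
    stable, radius = second_order_stable(model)
    if not stable:
        raise UnstableModelError(
            f"no stationary second moment: operator radius {radius:.4f} >= 1"
        )
    M = second_moment_operator(model)
    W = model.W_full() if isinstance(model, JointARBEKKModel) else model.W
    k = W.shape[0]
    vecS = np.linalg.solve(np.eye(k * k) - M, W.reshape(-1, order="F"))
    S = vecS.reshape(k, k, order="F")
    return 0.5 * (S + S.T)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _chol_psd(H: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(H)
    except np.linalg.LinAlgError as exc:
        raise UnstableModelError("conditional covariance lost positive definiteness") from exc


def simulate(
    model: ARBEKKModel | JointARBEKKModel,
    T: int,
    n_trials: int = 1,
    seed: int | np.random.Generator | None = None,
    burn_in: int = DEFAULT_BURN_IN,
    dt: float = 1.0,
    allow_unstable: bool = False,
    initial_state: np.ndarray | None = None,
) -> TrialPanel:
    """Simulate independent trials of an AR-BEKK (or joint) process.

    Trials start from ``initial_state`` (zero by default), run ``burn_in``
    extra steps that are discarded, and are mutually independent.
    Reproducible given ``seed``.  Unstable models are refused unless
    ``allow_unstable=True``.  A nonzero ``initial_state`` with
    ``burn_in=0`` emulates trial-locked transients (every trial released
    from the same state, as in a stimulus-locked recording).
    """
    if not allow_unstable and not is_stable(model):
        _, r1 = first_order_stable(model.A)
        raise UnstableModelError(
            f"model fails stability checks (mean radius {r1:.3f}); "
            "pass allow_unstable=True to override"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = model.k
    m = max(model.p, model.q, 1)
    total = T + burn_in
    joint = isinstance(model, JointARBEKKModel)
    x0 = np.zeros(k) if initial_state is None else np.asarray(initial_state, float)
    if x0.shape != (k,):
        raise ValueError(f"initial_state must have shape ({k},)")

    scalar_blocks = (not joint and k == 1) or (joint and model.kx == 1 and model.ky == 1)
    if scalar_blocks and model.p <= 1 and model.q <= 1:
        return _simulate_first_order_scalar(model, T, n_trials, rng, burn_in, dt, x0)

    out = np.zeros((n_trials, total + m, k))
    out[:, :m, :] = x0
    eps = rng.standard_normal((n_trials, total + m, k))
    if joint:
        Lx0, Ly0 = model.Wx_chol, model.Wy_chol
    else:
        L0 = model.W_chol
    for t in range(m, total + m):
        mean = np.zeros((n_trials, k))
        for i, Ai in enumerate(model.A, start=1):
            mean += out[:, t - i, :] @ Ai.T
        if joint:
            Hx = np.broadcast_to(model.Wx, (n_trials, model.kx, model.kx)).copy()
            Hy = np.broadcast_to(model.Wy, (n_trials, model.ky, model.ky)).copy()
            for j in range(1, model.q + 1):
                vx = out[:, t - j, :] @ model.Bx[j - 1].T
                vy = out[:, t - j, :] @ model.By[j - 1].T
                Hx += vx[:, :, None] * vx[:, None, :]
                Hy += vy[:, :, None] * vy[:, None, :]
            Lx = np.linalg.cholesky(Hx)
            Ly = np.linalg.cholesky(Hy)
            ex = np.einsum("nij,nj->ni", Lx, eps[:, t, : model.kx])
            ey = np.einsum("nij,nj->ni", Ly, eps[:, t, model.kx :])
            innov = np.concatenate([ex, ey], axis=1)
        else:
            H = np.broadcast_to(model.W, (n_trials, k, k)).copy()
            for j in range(1, model.q + 1):
                v = out[:, t - j, :] @ model.B[j - 1].T
                H += v[:, :, None] * v[:, None, :]
            L = np.linalg.cholesky(H)
            innov = np.einsum("nij,nj->ni", L, eps[:, t, :])
        out[:, t, :] = mean + innov
    values = out[:, m + burn_in :, :]
    names = _default_names(model)
    return TrialPanel(values, dt=dt, channel_names=names, meta={"generator": "arbekk"})


def _default_names(model) -> list[str]:
    if isinstance(model, JointARBEKKModel):
        return [f"x{i}" for i in range(model.kx)] + [f"y{i}" for i in range(model.ky)]
    return [f"ch{i}" for i in range(model.k)]


def _simulate_first_order_scalar(model, T, n_trials, rng, burn_in, dt, x0) -> TrialPanel:
    """Fast path: first-order model with univariate block(s)."""
    joint = isinstance(model, JointARBEKKModel)
    total = T + burn_in
    if joint:
        A = model.A[0]
        bx = model.Bx[0][0] if model.q else np.zeros(2)
        by = model.By[0][0] if model.q else np.zeros(2)
        wx = float(model.Wx[0, 0])
        wy = float(model.Wy[0, 0])
        z = np.tile(x0, (n_trials, 1))
        eps = rng.standard_normal((n_trials, total, 2))
        out = np.empty((n_trials, total, 2))
        for t in range(total):
            hx = wx + (z @ bx) ** 2
            hy = wy + (z @ by) ** 2
            mean = z @ A.T
            z = mean + np.sqrt(np.column_stack([hx, hy])) * eps[:, t, :]
            out[:, t, :] = z
    else:
        a = float(model.A[0][0, 0])
        b = float(model.B[0][0, 0]) if model.q else 0.0
        w = float(model.W[0, 0])
        x = np.full(n_trials, float(x0[0]))
        eps = rng.standard_normal((n_trials, total))
        out = np.empty((n_trials, total))
        for t in range(total):
            h = w + (b * x) ** 2
            x = a * x + np.sqrt(h) * eps[:, t]
            out[:, t] = x
        out = out[:, :, None]
    values = out[:, burn_in:, :]
    return TrialPanel(
        values, dt=dt, channel_names=_default_names(model), meta={"generator": "arbekk"}
    )
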