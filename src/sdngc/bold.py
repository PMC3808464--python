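"""Synthetic BOLD trials from Poisson spike trains through the hemodynamic
(Balloon-model) state equations.

Cortical spiking is close to Poisson: the spike-count variance in a window
equals the mean count.  Feeding such trains into the standard biophysical
model linking neuronal activity to the BOLD response propagates that
count variability nonlinearly into the measured signal, producing noise
whose variance grows with the squared signal — the phenomenon the AR-BEKK
model captures.  The state equations are::

    ds/dt = efficacy * u(t) - s / tau_s - (f - 1) / tau_f
    df/dt = s
    dv/dt = (f - v**(1/alpha)) / tau_0
    dq/dt = (f * E(f, E0) / E0 - v**(1/alpha) * q / v) / tau_0

with ``E(f, E0) = 1 - (1 - E0)**(1/f)`` the oxygen extraction, initial state
``(s, f, v, q) = (0, 1, 1, 1)``, and readout::

    BOLD = V0 * (k1 (1 - q) + k2 (1 - q/v) + k3 (1 - v)) + e_t

``u(t)`` is the neuronal drive, here the binned spike counts treated as a
piecewise-constant input, so a single spike in a bin injects
``efficacy * dt`` into the vasodilatory signal.  This keeps the states in
their physical domain across the 5-80 Hz range (per-spike injections large
enough to be visible at the BOLD scale drive the flow variable out of its
domain).  The observation constants default to 1.5-T values
``k1 = 7 E0, k2 = 2, k3 = 2 E0 - 0.2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import TrialPanel

__all__ = [
    "SpikeTrain",
    "HemodynamicParams",
    "IntegrationError",
    "poisson_spikes",
    "hemodynamic_forward",
    "simulate_bold_trials",
]


class IntegrationError(RuntimeError):
    """The hemodynamic state left its physical domain (f, v, q > 0)."""


@dataclass
class SpikeTrain:
    """Binned Poisson spike counts."""

    dt: float
    counts: np.ndarray
    rate: float
    duration: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be nonnegative")

    @property
    def rate_series(self) -> np.ndarray:
        """Instantaneous rate (spikes/second) per bin."""
        return self.counts / self.dt

    @property
    def drive(self) -> np.ndarray:
        """Binned counts as the piecewise-constant neuronal drive."""
        return np.asarray(self.counts, dtype=float)


@dataclass
class HemodynamicParams:
    """Biophysical constants of the hemodynamic model.

    Time constants in seconds; ``alpha`` is Grubb's exponent, ``E0`` the
    resting oxygen extraction fraction, ``V0`` the resting blood volume
    fraction.  ``efficacy`` scales the neuronal drive (vasodilatory-signal
    increment per spike); ``obs_noise_sd`` is additive Gaussian observation
    noise on the BOLD readout.
    """

    tau_s: float = 0.8
    tau_f: float = 0.4
    tau_0: float = 1.0
    alpha: float = 0.32
    E0: float = 0.34
    V0: float = 0.02
    k1: float = field(default=None)  # type: ignore[assignment]
    k2: float = 2.0
    k3: float = field(default=None)  # type: ignore[assignment]
    efficacy: float = 0.5
    obs_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.k1 is None:
            self.k1 = 7.0 * self.E0
        if self.k3 is None:
            self.k3 = 2.0 * self.E0 - 0.2
        if min(self.tau_s, self.tau_f, self.tau_0) <= 0:
            raise ValueError("time constants must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.E0 < 1:
            raise ValueError("E0 must lie in (0, 1)")
        if self.V0 <= 0:
            raise ValueError("V0 must be positive")


def poisson_spikes(
    rate: float, duration: float, dt: float = 1e-3,
    seed: int | np.random.Generator | None = None,
) -> SpikeTrain:
    """Homogeneous Poisson spike train binned at ``dt``.

    Counts per bin are independent Poisson(rate * dt); the total count over
    the window has mean and variance ``rate * duration`` (Fano factor 1).
    """
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    if dt <= 0 or duration <= 0:
        raise ValueError("dt and duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_bins = int(round(duration / dt))
    counts = rng.poisson(rate * dt, size=n_bins)
    return SpikeTrain(dt=dt, counts=counts, rate=rate, duration=duration)


def _derivs(state, u_rate, pr: HemodynamicParams):
    s, f, v, q = state
    if np.any(f <= 0) or np.any(v <= 0) or np.any(q <= 0):
        raise IntegrationError("state left the physical domain (f, v, q > 0)")
    E = 1.0 - (1.0 - pr.E0) ** (1.0 / f)
    v_out = v ** (1.0 / pr.alpha)
    ds = pr.efficacy * u_rate - s / pr.tau_s - (f - 1.0) / pr.tau_f
    df = s
    dv = (f - v_out) / pr.tau_0
    dq = (f * E / pr.E0 - v_out * q / v) / pr.tau_0
    return np.array([ds, df, dv, dq])


def hemodynamic_forward(
    u: np.ndarray,
    params: HemodynamicParams | None = None,
    dt: float = 1e-3,
    method: str = "euler",
    seed: int | np.random.Generator | None = None,
) -> tuple[dict, np.ndarray]:
    """Integrate the hemodynamic states driven by the neuronal input ``u``.

    ``u`` is the drive sampled at ``dt`` (piecewise constant; for spike
    input, the binned counts); leading axes are treated as independent
    trials.  Returns a
    dict of state trajectories ``{"s", "f", "v", "q"}`` and the BOLD series,
    all shaped like ``u``.  Explicit Euler at the input resolution by
    default; ``method="rk4"`` uses a 4th-order step for convergence checks.
    """
    if dt > 0.010 + 1e-12:
        raise ValueError("integration step must be <= 10 ms for accuracy")
    pr = params or HemodynamicParams()
    u = np.asarray(u, dtype=float)
    batch = u.shape[:-1]
    n_steps = u.shape[-1]
    state = np.zeros((4,) + batch)
    state[1:] = 1.0  # (s, f, v, q) = (0, 1, 1, 1)
    traj = np.empty((4,) + batch + (n_steps,))
    for t in range(n_steps):
        ut = u[..., t]
        if method == "euler":
            state = state + dt * _derivs(state, ut, pr)
        elif method == "rk4":
            k1 = _derivs(state, ut, pr)
            k2 = _derivs(state + 0.5 * dt * k1, ut, pr)
            k3 = _derivs(state + 0.5 * dt * k2, ut, pr)
            k4 = _derivs(state + dt * k3, ut, pr)
            state = state + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        else:
            raise ValueError(f"unknown integration method {method!r}")
        traj[..., t] = state
    s, f, v, q = traj
    bold = pr.V0 * (pr.k1 * (1.0 - q) + pr.k2 * (1.0 - q / v) + pr.k3 * (1.0 - v))
    if pr.obs_noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        bold = bold + pr.obs_noise_sd * rng.standard_normal(bold.shape)
    return {"s": s, "f": f, "v": v, "q": q}, bold


def simulate_bold_trials(
    rate: float = 40.0,
    n_trials: int = 100,
    total_seconds: float = 25.0,
    out_hz: float = 1.0,
    seed: int | np.random.Generator | None = None,
    params: HemodynamicParams | None = None,
    stim_seconds: float = 1.0,
    dt: float = 1e-3,
) -> TrialPanel:
    """Repeated BOLD trials from independent 1-s Poisson spike trains.

    Each trial draws a fresh spike train (``rate`` Hz for ``stim_seconds``),
    integrates the hemodynamic model at ``dt`` over ``total_seconds``, and
    decimates the BOLD series to ``out_hz`` (every ``1/(out_hz*dt)``-th
    sample, starting at t = 0).  Defaults give a (100 trials x 25 samples)
    panel at 1 Hz.
    """
    step = 1.0 / (out_hz * dt)
    if abs(step - round(step)) > 1e-9:
        raise ValueError("out_hz * total_seconds must give an integral decimation")
    step = int(round(step))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_steps = int(round(total_seconds / dt))
    stim_steps = int(round(stim_seconds / dt))
    counts = rng.poisson(rate * dt, size=(n_trials, stim_steps))
    u = np.zeros((n_trials, n_steps))
    u[:, :stim_steps] = counts
    _, bold = hemodynamic_forward(u, params=params, dt=dt, seed=rng)
    values = bold[:, ::step]
    return TrialPanel(
        values[:, :, None],
        dt=1.0 / out_hz,
        channel_names=["bold"],
        meta={
            "generator": "bold",
            "rate_hz": rate,
            "stim_seconds": stim_seconds,
            "dt_integration": dt,
        },
    )
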