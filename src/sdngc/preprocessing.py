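"""Per-trial denoising and normalization applied before causal analysis.

Each trial is wavelet-denoised (Daubechies-2, multilevel DWT, soft
thresholding at the universal threshold ``lambda = sigma * sqrt(2 ln N)``
with the noise level estimated once from the first-level detail coefficients,
``sigma = median(|d1|) / 0.6745``), then detrended by removing the
least-squares line and centered to zero mean.  Trials from all subjects are
then pooled and treated as repeated realizations of a common model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .panel import TrialPanel

__all__ = [
    "PreprocConfig",
    "wavelet_denoise",
    "detrend_center",
    "pool_trials",
    "preprocess_panel",
    "universal_threshold",
]

_MAD_TO_SD = 0.6745  # Gaussian consistency constant for the median absolute deviation


@dataclass
class PreprocConfig:
    wavelet: str = "db2"
    threshold_rule: str = "universal"
    noise_rescaling: str = "first-level"
    thresholding: str = "soft"
    denoise: bool = True
    detrend: str = "linear"  # "linear" | "none"
    center: bool = True

    def __post_init__(self) -> None:
        if self.threshold_rule != "universal":
            raise ValueError("only the universal threshold rule is implemented")
        if self.noise_rescaling != "first-level":
            raise ValueError("only first-level noise rescaling is implemented")
        if self.thresholding not in ("soft", "hard"):
            raise ValueError("thresholding must be 'soft' or 'hard'")
        if self.detrend not in ("linear", "none"):
            raise ValueError("detrend must be 'linear' or 'none'")


def universal_threshold(series: np.ndarray, wavelet: str = "db2") -> float:
    """sigma_hat * sqrt(2 ln N), sigma_hat from first-level detail coefficients."""
    series = np.asarray(series, dtype=float)
    _, d1 = pywt.dwt(series, wavelet, mode="symmetric")
    sigma = float(np.median(np.abs(d1))) / _MAD_TO_SD
    return sigma * np.sqrt(2.0 * np.log(series.size))


def wavelet_denoise(series: np.ndarray, config: PreprocConfig | None = None) -> np.ndarray:
    """Multilevel wavelet shrinkage of one trial's series.

    Decomposition depth is ``floor(log2 N) - 1`` (capped at the wavelet's
    maximum useful level); detail coefficients at every level are thresholded
    at the universal threshold with the first-level noise estimate; output
    length equals input length.
    """
    config = config or PreprocConfig()
    series = np.asarray(series, dtype=float)
    N = series.size
    if N < 4:
        raise ValueError("series too short for one decomposition level")
    max_level = pywt.dwt_max_level(N, pywt.Wavelet(config.wavelet).dec_len)
    level = max(1, min(int(np.floor(np.log2(N))) - 1, max_level))
    coeffs = pywt.wavedec(series, config.wavelet, mode="symmetric", level=level)
    lam = universal_threshold(series, config.wavelet)
    out = [coeffs[0]] + [
        pywt.threshold(c, lam, mode=config.thresholding) for c in coeffs[1:]
    ]
    rec = pywt.waverec(out, config.wavelet, mode="symmetric")
    return rec[:N]


def detrend_center(series: np.ndarray) -> np.ndarray:
    """Remove the least-squares line, then the mean (idempotent)."""
    series = np.asarray(series, dtype=float)
    if series.size < 3:
        raise ValueError("series too short to detrend")
    t = np.arange(series.size, dtype=float)
    slope, intercept = np.polyfit(t, series, 1)
    out = series - (slope * t + intercept)
    return out - out.mean()


def pool_trials(per_subject_panels: list[TrialPanel]) -> TrialPanel:
    """Concatenate subjects' trials into one panel, keeping provenance.

    All panels must share trial length, dt and channels; each trial's subject
    tag is retained in ``meta["subject"]`` (trials pooled this way are treated
    as repeated realizations from a common underlying model).
    """
    if not per_subject_panels:
        raise ValueError("no panels to pool")
    first = per_subject_panels[0]
    subjects: list[str] = []
    for i, pnl in enumerate(per_subject_panels):
        if pnl.n_times != first.n_times or pnl.n_channels != first.n_channels:
            raise ValueError(f"panel {i} has mismatched length or channels")
        if abs(pnl.dt - first.dt) > 1e-12:
            raise ValueError(f"panel {i} has mismatched dt")
        if list(pnl.channel_names) != list(first.channel_names):
            raise ValueError(f"panel {i} has mismatched channel names")
        subjects.extend(pnl._subjects())
    values = np.concatenate([p.values for p in per_subject_panels], axis=0)
    meta = dict(first.meta)
    meta["subject"] = subjects
    return TrialPanel(values, dt=first.dt, channel_names=list(first.channel_names),
                      meta=meta)


def preprocess_panel(panel: TrialPanel, config: PreprocConfig | None = None) -> TrialPanel:
    """Apply the per-trial chain (denoise -> detrend -> center) channelwise."""
    config = config or PreprocConfig()
    values = panel.values.copy()
    n, T, k = values.shape
    for i in range(n):
        for c in range(k):
            s = values[i, :, c]
            if config.denoise:
                s = wavelet_denoise(s, config)
            if config.detrend == "linear":
                s = detrend_center(s)
            elif config.center:
                s = s - s.mean()
            values[i, :, c] = s
    return TrialPanel(values, dt=panel.dt, channel_names=list(panel.channel_names),
                      meta=dict(panel.meta))
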