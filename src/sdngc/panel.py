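"""Multi-trial time-series panels and their plain-text serialization.

A :class:`TrialPanel` holds repeated realizations (trials) of a multi-channel
series sampled on a uniform grid.  It is the universal data carrier of the
package: simulators produce panels, the estimators and causality tests consume
them.  Panels round-trip through long-format CSV
(``subject,condition,region,trial,t,value``) with a JSON sidecar for the
sampling interval and free-form metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TrialPanel", "PanelFormatError", "read_panel", "write_panel"]


class PanelFormatError(ValueError):
    """Raised when a panel file violates the long-format CSV contract."""


@dataclass
class TrialPanel:
    """Repeated realizations of a multi-channel series on a uniform time grid.

    Parameters
    ----------
    values
        Array of shape ``(n_trials, n_times, n_channels)``.  No missing
        values are allowed after preprocessing.
    dt
        Sampling interval in seconds; must be positive.
    channel_names
        One label per channel (brain region names in the fMRI application).
    meta
        Free-form provenance: subject/condition tags, generator settings.
        ``meta["subject"]`` may hold one subject label per trial.
    """

    values: np.ndarray
    dt: float = 1.0
    channel_names: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2:  # single channel convenience
            self.values = self.values[:, :, None]
        if self.values.ndim != 3:
            raise ValueError(
                "values must have shape (n_trials, n_times, n_channels), "
                f"got ndim={self.values.ndim}"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("panel contains non-finite values")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.channel_names is None:
            self.channel_names = [f"ch{i}" for i in range(self.values.shape[2])]
        if len(self.channel_names) != self.values.shape[2]:
            raise ValueError("channel_names length does not match channel axis")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    @property
    def n_channels(self) -> int:
        return self.values.shape[2]

    def channel(self, name_or_index: str | int) -> "TrialPanel":
        """Extract a single channel as a univariate panel."""
        if isinstance(name_or_index, str):
            idx = self.channel_names.index(name_or_index)
        else:
            idx = int(name_or_index)
        return TrialPanel(
            self.values[:, :, [idx]],
            dt=self.dt,
            channel_names=[self.channel_names[idx]],
            meta=dict(self.meta),
        )

    def stack(self, other: "TrialPanel") -> "TrialPanel":
        """Concatenate channels of two aligned panels (same trials/grid)."""
        if other.n_trials != self.n_trials or other.n_times != self.n_times:
            raise ValueError("panels are not aligned (trial/time mismatch)")
        return TrialPanel(
            np.concatenate([self.values, other.values], axis=2),
            dt=self.dt,
            channel_names=list(self.channel_names) + list(other.channel_names),
            meta={**other.meta, **self.meta},
        )

    def _subjects(self) -> list[str]:
        subj = self.meta.get("subject")
        if subj is None:
            return ["s0"] * self.n_trials
        if isinstance(subj, str):
            return [subj] * self.n_trials
        if len(subj) != self.n_trials:
            raise ValueError("meta['subject'] length does not match trials")
        return [str(s) for s in subj]


def _sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".json")


def write_panel(panel: TrialPanel, path: str | Path) -> None:
    """Write a panel to long-format CSV plus a JSON metadata sidecar."""
    path = Path(path)
    n, T, k = panel.values.shape
    subjects = panel._subjects()
    condition = str(panel.meta.get("condition", "na"))
    trial_idx = np.repeat(np.arange(n), T * k)
    time_idx = np.tile(np.repeat(np.arange(T), k), n)
    region = np.tile(np.asarray(panel.channel_names, dtype=object), n * T)
    df = pd.DataFrame(
        {
            "subject": np.asarray(subjects, dtype=object)[trial_idx],
            "condition": condition,
            "region": region,
            "trial": trial_idx,
            "t": time_idx,
            "value": panel.values.reshape(-1),
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")  # lossless round-trip
    meta = {kk: vv for kk, vv in panel.meta.items()}
    sidecar = {
        "dt": panel.dt,
        "channel_names": list(panel.channel_names),
        "meta": _jsonable(meta),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def read_panel(path: str | Path) -> TrialPanel:
    """Read a long-format CSV panel written by :func:`write_panel`.

    Raises :class:`PanelFormatError` with a distinct message for missing
    columns, ragged trials, non-numeric values, or an empty file.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise PanelFormatError(f"empty panel file: {path}") from exc
    required = ["subject", "condition", "region", "trial", "t", "value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PanelFormatError(f"missing required columns {missing} in {path}")
    if len(df) == 0:
        raise PanelFormatError(f"panel file has a header but no rows: {path}")
    values_col = pd.to_numeric(df["value"], errors="coerce")
    if values_col.isna().any():
        bad = df.loc[values_col.isna()].index[0]
        raise PanelFormatError(f"non-numeric value at row {bad} of {path}")
    df["value"] = values_col

    regions = list(dict.fromkeys(df["region"].astype(str)))
    trials = sorted(df["trial"].unique())
    lengths = df.groupby(["trial", "region"])["t"].count()
    if lengths.nunique() != 1:
        raise PanelFormatError(f"ragged trials (unequal lengths) in {path}")
    T = int(lengths.iloc[0])

    values = np.empty((len(trials), T, len(regions)))
    subjects = []
    for ti, trial in enumerate(trials):
        sub = df[df["trial"] == trial]
        subjects.append(str(sub["subject"].iloc[0]))
        for ri, region in enumerate(regions):
            series = sub[sub["region"].astype(str) == region].sort_values("t")
            if len(series) != T:
                raise PanelFormatError(
                    f"ragged trials: trial {trial} region {region} in {path}"
                )
            values[ti, :, ri] = series["value"].to_numpy()

    dt, meta = 1.0, {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        side = json.loads(sidecar.read_text())
        dt = float(side.get("dt", 1.0))
        meta = dict(side.get("meta", {}))
        regions = side.get("channel_names", regions)
    meta.setdefault("subject", subjects)
    cond = df["condition"].astype(str).iloc[0]
    meta.setdefault("condition", cond)
    return TrialPanel(values, dt=dt, channel_names=list(regions), meta=meta)
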