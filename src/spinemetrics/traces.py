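"""Ratiometric Fura-2 Ca²⁺ trace quantification.

A store-operated Ca²⁺ entry (SOCE) protocol records a cell's 340 nm / 380 nm
excitation fluorescence while the bath switches from Ca²⁺-containing Ringer
to 0 mM Ca²⁺ + thapsigargin (store depletion) and back to Ca²⁺ (re-addition).
The background-subtracted ratio trace is summarized by the resting (basal)
ratio, the SOCE Δpeak and Δplateau relative to the pre-re-addition level,
the influx rate (slope of a linear fit to the five frames from one before to
four after re-addition) and the area under the curve during store depletion.
Ratios can be converted to absolute Ca²⁺ concentrations with the
Grynkiewicz relation when calibration constants are supplied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CalciumTrace:
    """Per-cell two-wavelength fluorescence time series with backgrounds and
    named protocol events (frame indices)."""

    time: np.ndarray            # seconds per frame
    f340: np.ndarray
    f380: np.ndarray
    bg340: np.ndarray
    bg380: np.ndarray
    events: dict = field(default_factory=dict)
    # events: tg_addition, ca_readdition (frames);
    #         basal_window, depletion_window, plateau_window ((start, stop) frames)

    def __post_init__(self):
        arrays = {}
        n = None
        for name in ("time", "f340", "f380", "bg340", "bg380"):
            a = np.asarray(getattr(self, name), dtype=float)
            if n is None:
                n = a.size
            elif a.size != n:
                raise ValueError(f"{name} length {a.size} != {n}")
            arrays[name] = a
        for name, a in arrays.items():
            object.__setattr__(self, name, a)
        for key, val in self.events.items():
            frames = np.atleast_1d(val)
            # windows are half-open (start, stop): stop == n_frames is valid
            upper = n if key.endswith("_window") else n - 1
            if np.any(frames < 0) or np.any(frames > upper):
                raise ValueError(f"event {key!r} out of range")

    @property
    def n_frames(self) -> int:
        return self.time.size

    def to_csv(self, path, events_path=None) -> None:
        pd.DataFrame({
            "frame": np.arange(self.n_frames), "time_s": self.time,
            "F340": self.f340, "F380": self.f380,
            "bg340": self.bg340, "bg380": self.bg380,
        }).to_csv(path, index=False)
        if events_path is None:
            events_path = Path(path).with_suffix(".events.json")
        with open(events_path, "w") as fh:
            json.dump({k: (list(map(int, np.atleast_1d(v))))
                       for k, v in self.events.items()}, fh, indent=1)

    @classmethod
    def from_csv(cls, path, events_path=None) -> "CalciumTrace":
        df = pd.read_csv(path)
        if events_path is None:
            events_path = Path(path).with_suffix(".events.json")
        with open(events_path) as fh:
            raw = json.load(fh)
        events = {k: (int(v[0]) if len(v) == 1 else tuple(v))
                  for k, v in raw.items()}
        return cls(time=df["time_s"].to_numpy(), f340=df["F340"].to_numpy(),
                   f380=df["F380"].to_numpy(), bg340=df["bg340"].to_numpy(),
                   bg380=df["bg380"].to_numpy(), events=events)


@dataclass(frozen=True)
class TraceFeatures:
    basal_ratio: float
    delta_peak: float
    delta_plateau: float
    influx_rate: float       # ratio/s (nM/s when calibrated)
    auc: float               # ratio·s over the depletion window

    def as_dict(self) -> dict:
        return {"basal": self.basal_ratio, "dpeak": self.delta_peak,
                "dplateau": self.delta_plateau, "rate": self.influx_rate,
                "auc": self.auc}


@dataclass(frozen=True)
class CalibrationConstants:
    """Grynkiewicz constants: ratio limits at zero/saturating Ca²⁺, the
    indicator K_d (nM) and beta, the 380 nm fluorescence ratio between the
    Ca²⁺-free and Ca²⁺-bound forms."""

    r_min: float
    r_max: float
    k_d: float
    beta: float

    def __post_init__(self):
        if not self.r_min < self.r_max:
            raise ValueError("R_min must be < R_max")
        if self.k_d <= 0 or self.beta <= 0:
            raise ValueError("K_d and beta must be positive")


def ratio_trace(trace: CalciumTrace) -> np.ndarray:
    """Background-subtracted 340/380 ratio per frame."""
    denom = trace.f380 - trace.bg380
    bad = np.flatnonzero(denom <= 0)
    if bad.size:
        raise ValueError(f"non-positive F380 - bg380 at frame {bad[0]}")
    return (trace.f340 - trace.bg340) / denom


def _window_slice(window) -> slice:
    start, stop = window
    if stop <= start:
        raise ValueError(f"empty window {window}")
    return slice(int(start), int(stop))


def trace_features(ratio: np.ndarray, events: dict, time: np.ndarray,
                   n_avg: int = 5) -> TraceFeatures:
    """Summarize a ratio trace.

    basal: mean over the basal window. Δpeak: maximum between Ca²⁺
    re-addition and the plateau window minus the mean of ``n_avg`` frames
    immediately before re-addition (the average ratio before the addition).
    Δplateau: plateau-window mean minus the same pre-addition level.
    """
    import warnings
    if not 5 <= n_avg <= 10:
        warnings.warn(f"n_avg={n_avg} outside the customary 5-10 frame range")
    ratio = np.asarray(ratio, dtype=float)
    basal = float(ratio[_window_slice(events["basal_window"])].mean())
    readd = int(events["ca_readdition"])
    if readd - n_avg < 0:
        raise ValueError("pre-re-addition averaging window leaves the trace")
    pre = float(ratio[readd - n_avg:readd].mean())
    plateau_sl = _window_slice(events["plateau_window"])
    if plateau_sl.start <= readd:
        raise ValueError("plateau window overlaps Ca2+ re-addition")
    peak = float(ratio[readd:plateau_sl.start].max())
    plateau = float(ratio[plateau_sl].mean())
    rate = influx_rate(ratio, time, readd)
    dep_auc = auc(ratio, time, events["depletion_window"],
                  baseline=basal)
    return TraceFeatures(basal_ratio=basal, delta_peak=peak - pre,
                         delta_plateau=plateau - pre, influx_rate=rate,
                         auc=dep_auc)


def influx_rate(ratio: np.ndarray, time: np.ndarray,
                readdition_frame: int) -> float:
    """Slope of an ordinary least-squares line through exactly five
    frames: the one before Ca²⁺ re-addition and the four from the event on
    (re-addition happens between frames, so the event frame is the first
    one after it)."""
    i0, i1 = readdition_frame - 1, readdition_frame + 4
    if i0 < 0 or i1 > len(ratio):
        raise ValueError("need 1 frame before and 4 after re-addition")
    t = np.asarray(time, dtype=float)[i0:i1]
    y = np.asarray(ratio, dtype=float)[i0:i1]
    t0 = t - t.mean()
    return float(np.dot(t0, y - y.mean()) / np.dot(t0, t0))


def auc(ratio: np.ndarray, time: np.ndarray, window,
        baseline: float | str = 0.0) -> float:
    """Trapezoidal area of (ratio − baseline) over the window (ratio·s).

    ``baseline`` is a number, or ``"pre-event"`` to use the mean of the 5
    frames before the window, or 0 for the raw integral.
    """
    sl = _window_slice(window)
    y = np.asarray(ratio, dtype=float)[sl]
    t = np.asarray(time, dtype=float)[sl]
    if y.size < 2:
        raise ValueError("window too short for integration")
    if baseline == "pre-event":
        if sl.start < 5:
            raise ValueError("no pre-event frames for baseline")
        baseline = float(np.asarray(ratio)[sl.start - 5:sl.start].mean())
    return float(np.trapezoid(y - float(baseline), t))


def calibrate(ratio, constants: CalibrationConstants,
              clip: bool = False) -> np.ndarray:
    """Grynkiewicz conversion [Ca²⁺] = K_d · β · (R − R_min)/(R_max − R), nM.

    Out-of-range ratios raise unless ``clip``, which floors at 0 nM and
    caps at R just inside R_max.
    """
    r = np.asarray(ratio, dtype=float)
    if clip:
        eps = 1e-9 * (constants.r_max - constants.r_min)
        r = np.clip(r, constants.r_min, constants.r_max - eps)
    else:
        if np.any(r >= constants.r_max):
            raise ValueError("ratio at or above R_max; saturated indicator")
        if np.any(r < constants.r_min):
            raise ValueError("ratio below R_min")
    out = constants.k_d * constants.beta * (r - constants.r_min) / (constants.r_max - r)
    return out if out.ndim else float(out)


def invert_calibration(ca_nm, constants: CalibrationConstants) -> np.ndarray:
    """Inverse of :func:`calibrate` (useful for round-trip checks)."""
    ca = np.asarray(ca_nm, dtype=float)
    kb = constants.k_d * constants.beta
    out = (constants.r_min + ca * constants.r_max / kb) / (1.0 + ca / kb)
    return out if out.ndim else float(out)


def normalize_to_reference(features: pd.DataFrame, group_col: str,
                           reference_group) -> pd.DataFrame:
    """Divide every numeric feature column by the reference group's median,
    yielding fold changes relative to that group."""
    if reference_group not in set(features[group_col]):
        raise ValueError(f"reference group {reference_group!r} absent")
    ref = features[features[group_col] == reference_group]
    out = features.copy()
    for col in features.columns:
        if col == group_col or not np.issubdtype(features[col].dtype, np.number):
            continue
        med = float(ref[col].median())
        if med == 0:
            raise ValueError(f"reference median of {col!r} is zero")
        out[col] = features[col] / med
    return out
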