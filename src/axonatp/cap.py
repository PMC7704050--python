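"""Compound action potential (CAP) quantification.

Optic-nerve function is monitored as the area under the stimulus-evoked
CAP waveform, which is proportional to the number of excited axons.  The
integration window runs from the beginning of the response (typically
0.2 ms after the stimulus) to the trough marking the end of the second
peak, spanning roughly 1.5 ms.  Experiment-long series of CAP areas are
normalised with the same two-point convention as the ATP trace (baseline
mean -> 1, MB+GD plateau -> 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .protocol import ProtocolSpec
from .ratio import NormalizedTrace

logger = logging.getLogger(__name__)

__all__ = [
    "CAPTrace",
    "CAPWindow",
    "CAPSeries",
    "detect_cap_window",
    "cap_area",
    "normalize_cap_series",
    "excitability_curve",
]

#: stimulus-artifact blanking interval: peaks are searched only after this
BLANK_MS = 0.15
#: fixed fallback window used when two peaks cannot be detected
FALLBACK_WINDOW = (0.2, 1.7)
#: pre-stimulus span used for the baseline voltage estimate
BASELINE_SPAN_MS = 0.5


@dataclass
class CAPTrace:
    """Stimulus-locked voltage sweep; time in ms relative to the stimulus."""

    time: np.ndarray  # ms
    voltage: np.ndarray  # mV
    sampling_khz: float = 20.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.time.shape != self.voltage.shape:
            raise ValueError("time and voltage must have the same shape")
        dt = np.diff(self.time)
        if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("CAP trace must be uniformly sampled")
        if self.time[-1] < 3.0:
            raise ValueError("CAP trace must cover at least 0-3 ms")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def baseline_voltage(self) -> float:
        """Mean voltage over the 0.5 ms preceding the stimulus (t < 0);
        falls back to the first pre-blanking samples if the sweep starts
        at the stimulus."""
        pre = (self.time >= -BASELINE_SPAN_MS) & (self.time < 0.0)
        if pre.any():
            return float(self.voltage[pre].mean())
        return float(self.voltage[self.time < BLANK_MS].mean())

    def baseline_noise_sd(self) -> float:
        pre = (self.time >= -BASELINE_SPAN_MS) & (self.time < 0.0)
        vals = self.voltage[pre] if pre.any() else self.voltage[self.time < BLANK_MS]
        return float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0


@dataclass(frozen=True)
class CAPWindow:
    """Integration window [t_start, t_end] in ms; ``fallback`` marks that
    peak detection failed and the fixed default window was used."""

    t_start: float
    t_end: float
    fallback: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.t_start < self.t_end):
            raise ValueError("window must satisfy 0 < t_start < t_end")

    @property
    def span(self) -> float:
        return self.t_end - self.t_start


@dataclass
class CAPSeries:
    """Experiment-long sequence of CAP areas with protocol annotations."""

    time: np.ndarray  # s
    area: np.ndarray  # mV*ms
    protocol: ProtocolSpec

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        if self.time.shape != self.area.shape:
            raise ValueError("time and area must have the same shape")


def detect_cap_window(
    trace: CAPTrace,
    prominence_k: float = 5.0,
    min_prominence: float = 1e-3,
) -> CAPWindow:
    """Data-driven CAP integration window.

    t_start is the first post-blanking crossing of the detection threshold
    (default 0.2 ms when no crossing is found); t_end is the first trough
    after the second detected peak.  When fewer than two peaks are found
    the fixed fallback window [0.2, 1.7] ms is returned with a warning.
    Peak prominence threshold: ``prominence_k`` times the pre-stimulus
    noise SD (with a small absolute floor for noiseless traces).
    """
    v = trace.voltage - trace.baseline_voltage()
    search = trace.time >= BLANK_MS
    prominence = max(prominence_k * trace.baseline_noise_sd(), min_prominence)
    peaks, _ = find_peaks(np.where(search, v, 0.0), prominence=prominence)
    if peaks.size < 2:
        logger.warning("CAP window detection failed (<2 peaks); using fallback %s",
                       FALLBACK_WINDOW)
        return CAPWindow(*FALLBACK_WINDOW, fallback=True)
    p1, p2 = peaks[0], peaks[1]

    thresh = prominence  # same noise-scaled threshold for response onset
    pre_peak = search & (np.arange(v.size) <= p1)
    crossing = np.nonzero(pre_peak & (v > thresh))[0]
    t_start = float(trace.time[crossing[0]]) if crossing.size else 0.2

    after = v[p2:]
    troughs, _ = find_peaks(-after, prominence=prominence)
    if troughs.size:
        t_end = float(trace.time[p2 + troughs[0]])
    else:
        # monotone return to baseline: take the first sample back at noise level
        below = np.nonzero(after < thresh)[0]
        t_end = float(trace.time[p2 + below[0]]) if below.size else float(trace.time[-1])
    window = CAPWindow(t_start=t_start, t_end=t_end)
    if not (0.5 <= window.span <= 3.0):
        logger.warning("detected CAP window span %.2f ms outside sanity band; "
                       "using fallback", window.span)
        return CAPWindow(*FALLBACK_WINDOW, fallback=True)
    return window


def cap_area(trace: CAPTrace, window: CAPWindow, rectified: bool = False) -> float:
    """Area under the CAP (mV*ms): trapezoidal integral of the voltage
    above the pre-stimulus baseline over the window.

    ``rectified=True`` integrates |v - baseline| instead of the signed
    excursion.
    """
    eps = 1e-9  # ms; tolerate float roundoff at the window edges
    if window.t_start < trace.time[0] - eps or window.t_end > trace.time[-1] + eps:
        raise ValueError("integration window outside the recorded trace")
    sel = (trace.time >= window.t_start - eps) & (trace.time <= window.t_end + eps)
    v = trace.voltage[sel] - trace.baseline_voltage()
    if rectified:
        v = np.abs(v)
    return float(np.trapezoid(v, trace.time[sel]))


def normalize_cap_series(
    series: CAPSeries,
    mbgd_window_s: float = 120.0,
    require_full_baseline: bool = True,
) -> NormalizedTrace:
    """Two-point normalization of a CAP-area series.

    Baseline-epoch mean maps to 1; when an MB+GD epoch is present its
    terminal plateau maps to 0, otherwise a baseline-only scaling
    (divide by the baseline mean) is applied.  The baseline epoch is
    expected to span >= 15 min unless ``require_full_baseline=False``.
    """
    protocol = series.protocol
    base = protocol.baseline
    if require_full_baseline and base.duration < 15 * 60 - 1e-9:
        raise ValueError(
            "baseline epoch shorter than 15 min; pass require_full_baseline=False "
            "to override"
        )
    base_vals = series.area[base.contains(series.time)]
    if base_vals.size == 0:
        raise ValueError("no samples in the baseline epoch")
    anchor1 = float(base_vals.mean())
    if protocol.by_label("MBGD"):
        mbgd = protocol.single("MBGD")
        tail = (series.time >= mbgd.end - mbgd_window_s) & (series.time < mbgd.end)
        tail_vals = series.area[tail]
        if tail_vals.size == 0:
            raise ValueError("no samples in the terminal MB+GD window")
        anchor0 = float(tail_vals.mean())
        if np.isclose(anchor1, anchor0):
            raise ValueError("degenerate normalization: anchors equal")
        value = (series.area - anchor0) / (anchor1 - anchor0)
    else:
        anchor0 = None
        if anchor1 == 0:
            raise ValueError("baseline mean is zero; cannot normalize")
        value = series.area / anchor1
    return NormalizedTrace(
        time=series.time,
        value=value,
        protocol=protocol,
        baseline_mean_raw=anchor1,
        mbgd_raw=anchor0,
    )


def excitability_curve(
    measurements: list[tuple[float, CAPTrace]],
    window: CAPWindow | None = None,
) -> pd.DataFrame:
    """CAP area as a function of stimulus intensity (0-1 mA).

    Returns a tidy frame with columns ``intensity_ma``, ``area`` and
    ``norm_area`` (each nerve's curve divided by its own maximum), plus a
    ``monotone`` attribute flag in ``DataFrame.attrs`` reporting whether
    the raw curve is non-decreasing.  Duplicate intensities are averaged
    with a warning.
    """
    if len(measurements) < 3:
        raise ValueError("excitability curve needs at least 3 intensities")
    intensities = [m[0] for m in measurements]
    if 0.0 not in intensities:
        raise ValueError("excitability curve must include the 0 mA point")
    rows = []
    for intensity, trace in measurements:
        win = window or detect_cap_window(trace)
        rows.append({"intensity_ma": float(intensity),
                     "area": cap_area(trace, win)})
    df = pd.DataFrame(rows)
    if df["intensity_ma"].duplicated().any():
        logger.warning("duplicate stimulus intensities aggregated by mean")
        df = df.groupby("intensity_ma", as_index=False)["area"].mean()
    df = df.sort_values("intensity_ma", ignore_index=True)
    max_area = df["area"].max()
    if max_area <= 0:
        raise ValueError("all CAP areas are non-positive")
    df["norm_area"] = df["area"] / max_area
    df.attrs["monotone"] = bool(np.all(np.diff(df["area"].to_numpy()) >= -1e-9 * max_area))
    return df
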