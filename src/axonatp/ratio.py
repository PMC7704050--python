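"""Ratiometric FRET ATP-sensor signal: F/C ratio, two-point normalization,
and decay/onset/recovery kinetics.

The ATP readout is the FRET-channel over CFP-channel intensity ratio (F/C)
of the ATeam-family sensor.  Each experiment is normalised to two anchors:
the baseline-epoch mean (set to 1) and the terminal plateau under
mitochondrial blockade + glucose deprivation, which depletes axonal ATP
(set to 0).  Kinetic parameters — maximal decay/recovery rate, onset delay
of recovery, recovery amplitude — are read off the normalised trace with
sliding-window linear regression.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .protocol import ProtocolSpec

logger = logging.getLogger(__name__)

__all__ = [
    "ChannelTimeSeries",
    "NormalizedTrace",
    "KineticsSummary",
    "fc_ratio",
    "normalize_trace",
    "sliding_slopes",
    "max_slope_rate",
    "onset_delay",
    "recovery_amplitude",
    "ramp_step_levels",
    "yfp_stability",
]

#: default sliding-window span for slope estimates: 5 samples at the
#: 10.4 s confocal frame interval (~52 s)
DEFAULT_SLOPE_WINDOW_S = 52.0
#: default onset threshold multiplier on the baseline slope SD
DEFAULT_K_SD = 3.0
#: window over which the terminal MB+GD plateau is averaged (anchor 0)
DEFAULT_MBGD_WINDOW_S = 120.0


@dataclass
class ChannelTimeSeries:
    """Timestamped CFP/FRET/YFP mean intensities with protocol annotations."""

    time: np.ndarray  # s
    cfp: np.ndarray
    fret: np.ndarray
    yfp: np.ndarray
    protocol: ProtocolSpec

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.cfp = np.asarray(self.cfp, dtype=float)
        self.fret = np.asarray(self.fret, dtype=float)
        self.yfp = np.asarray(self.yfp, dtype=float)
        n = self.time.size
        if any(a.shape != (n,) for a in (self.cfp, self.fret, self.yfp)):
            raise ValueError("all channels must match the time base")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.time, "cfp": self.cfp, "fret": self.fret, "yfp": self.yfp}
        )


@dataclass
class NormalizedTrace:
    """Two-point normalised trace: baseline mean -> 1, MB+GD anchor -> 0."""

    time: np.ndarray  # s
    value: np.ndarray  # dimensionless
    protocol: ProtocolSpec
    baseline_mean_raw: float
    mbgd_raw: float | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time.shape != self.value.shape:
            raise ValueError("time and value must have the same shape")

    @property
    def sample_interval(self) -> float:
        return float(np.median(np.diff(self.time)))

    def epoch_values(self, label: str) -> np.ndarray:
        masks = [e.contains(self.time) for e in self.protocol.by_label(label)]
        if not masks:
            raise ValueError(f"protocol has no {label!r} epoch")
        return self.value[np.logical_or.reduce(masks)]


@dataclass(frozen=True)
class KineticsSummary:
    """Headline kinetics of one GD/reperfusion experiment."""

    decay_rate: float  # per s, negative for a falling signal
    onset_delay: float  # s (nan = not detected)
    recovery_amplitude: float  # fraction of baseline
    slope_window_s: float = DEFAULT_SLOPE_WINDOW_S
    k_sd: float = DEFAULT_K_SD


# ---------------------------------------------------------------------------
# Ratio and normalization
# ---------------------------------------------------------------------------

def fc_ratio(series: ChannelTimeSeries) -> np.ndarray:
    """Pointwise FRET/CFP intensity ratio."""
    bad = np.nonzero(series.cfp <= 0)[0]
    if bad.size:
        raise ValueError(f"non-positive CFP intensity at sample index {bad[0]}")
    return series.fret / series.cfp


def normalize_trace(
    time: np.ndarray,
    ratio: np.ndarray,
    protocol: ProtocolSpec,
    mbgd_window_s: float = DEFAULT_MBGD_WINDOW_S,
) -> NormalizedTrace:
    """Two-point affine normalization of a raw F/C trace.

    anchor1 = mean raw ratio over the whole baseline epoch (maps to 1);
    anchor0 = mean raw ratio over the final ``mbgd_window_s`` seconds of the
    MB+GD epoch (maps to 0).  value = (x - anchor0) / (anchor1 - anchor0).
    """
    time = np.asarray(time, dtype=float)
    ratio = np.asarray(ratio, dtype=float)
    base = protocol.baseline
    base_vals = ratio[base.contains(time)]
    if base_vals.size == 0:
        raise ValueError("no samples in the baseline epoch")
    mbgd = protocol.single("MBGD")
    tail = (time >= mbgd.end - mbgd_window_s) & (time < mbgd.end)
    tail_vals = ratio[tail & mbgd.contains(time)]
    if tail_vals.size == 0:
        raise ValueError("no samples in the terminal MB+GD window")
    anchor1 = float(base_vals.mean())
    anchor0 = float(tail_vals.mean())
    if math.isclose(anchor1, anchor0, rel_tol=1e-12, abs_tol=1e-12):
        raise ValueError("degenerate normalization: baseline and MB+GD anchors equal")
    value = (ratio - anchor0) / (anchor1 - anchor0)
    return NormalizedTrace(
        time=time,
        value=value,
        protocol=protocol,
        baseline_mean_raw=anchor1,
        mbgd_raw=anchor0,
    )


# ---------------------------------------------------------------------------
# Sliding-window slopes and kinetics
# ---------------------------------------------------------------------------

def _window_samples(time: np.ndarray, window_s: float) -> int:
    dt = float(np.median(np.diff(time)))
    w = max(int(round(window_s / dt)), 3)
    return w


def sliding_slopes(
    time: np.ndarray, value: np.ndarray, window_s: float = DEFAULT_SLOPE_WINDOW_S
) -> np.ndarray:
    """Trailing-window least-squares slope at every sample (nan-padded head).

    slope[i] is the OLS slope over samples [i-w+1, i]; the first w-1 entries
    are nan.  Uniform sampling is assumed (the confocal frame clock).
    """
    time = np.asarray(time, dtype=float)
    value = np.asarray(value, dtype=float)
    w = _window_samples(time, window_s)
    if value.size < w:
        raise ValueError(f"trace shorter than the {w}-sample slope window")
    dt = float(np.median(np.diff(time)))
    # OLS slope for uniform x: sum((x - xbar) y) / sum((x - xbar)^2)
    x = (np.arange(w) - (w - 1) / 2.0) * dt
    denom = float(np.dot(x, x))
    kernel = x[::-1] / denom  # correlate -> trailing window
    slopes = np.full(value.size, np.nan)
    slopes[w - 1 :] = np.convolve(value, kernel, mode="valid")
    return slopes


def max_slope_rate(
    trace: NormalizedTrace,
    window_s: float = DEFAULT_SLOPE_WINDOW_S,
    epoch: str | tuple[float, float] | None = None,
) -> float:
    """Slope of maximal magnitude (sign retained) within an epoch.

    A least-squares line is fitted in a sliding window; the returned rate is
    the extreme windowed slope, negative for a decaying signal and positive
    for recovery.  ``epoch`` may be an epoch label or an explicit (t0, t1)
    span; None scans the whole trace.  Only windows fully inside the span
    are considered.
    """
    slopes = sliding_slopes(trace.time, trace.value, window_s)
    w = _window_samples(trace.time, window_s)
    if epoch is None:
        sel = np.ones(trace.time.size, dtype=bool)
    else:
        if isinstance(epoch, str):
            ep = trace.protocol.single(epoch)
            t0, t1 = ep.start, ep.end
        else:
            t0, t1 = epoch
        # keep only windows lying fully inside the span
        span = (trace.time >= t0) & (trace.time < t1)
        idx = np.nonzero(span)[0]
        if idx.size == 0:
            raise ValueError("epoch contains no samples")
        sel = np.zeros(trace.time.size, dtype=bool)
        sel[idx[idx >= idx[0] + w - 1]] = True
    cand = slopes[sel]
    cand = cand[~np.isnan(cand)]
    if cand.size == 0:
        raise ValueError("epoch shorter than the slope window")
    return float(cand[np.argmax(np.abs(cand))])


def onset_delay(
    trace: NormalizedTrace,
    event_time: float,
    k_sd: float = DEFAULT_K_SD,
    window_s: float = DEFAULT_SLOPE_WINDOW_S,
    direction: str = "abs",
    mode: str = "slope",
) -> float:
    """Delay from ``event_time`` to the first threshold crossing (seconds).

    The threshold is ``k_sd`` times the standard deviation of the windowed
    slopes (``mode="slope"``, default) or of the signal values
    (``mode="value"``) over the baseline epoch.  ``direction`` selects
    upward ("up"), downward ("down") or either ("abs") crossings.  Returns
    nan when the signal never crosses (not-detected marker).
    """
    if mode not in ("slope", "value"):
        raise ValueError("mode must be 'slope' or 'value'")
    base = trace.protocol.baseline
    if trace.time[0] > event_time or trace.time[-1] < event_time:
        raise ValueError("event_time outside the recorded trace")
    base_mask = base.contains(trace.time)
    if not base_mask.any():
        raise ValueError("no baseline epoch samples to estimate the threshold")
    if mode == "slope":
        signal = sliding_slopes(trace.time, trace.value, window_s)
        ref = signal[base_mask]
    else:
        signal = trace.value - float(trace.value[base_mask].mean())
        ref = signal[base_mask]
    ref = ref[~np.isnan(ref)]
    # the 1e-9 floor keeps float roundoff on perfectly flat traces from
    # registering as a crossing
    thresh = max(k_sd * float(np.std(ref, ddof=1)) if ref.size > 1 else 0.0, 1e-9)

    post = trace.time >= event_time
    sig = signal.copy()
    sig[~post] = np.nan
    if direction == "up":
        crossed = sig > thresh
    elif direction == "down":
        crossed = sig < -thresh
    elif direction == "abs":
        crossed = np.abs(sig) > thresh
    else:
        raise ValueError("direction must be 'up', 'down' or 'abs'")
    crossed &= ~np.isnan(sig)
    idx = np.nonzero(crossed)[0]
    if idx.size == 0:
        return float("nan")
    return float(trace.time[idx[0]] - event_time)


def recovery_amplitude(
    trace: NormalizedTrace,
    recovery_window: tuple[float, float] | None = None,
    terminal_s: float = 120.0,
) -> float:
    """Mean normalized value over the terminal part of the recovery window.

    Since the baseline is normalised to 1, the result reads directly as the
    fraction of baseline recovered.  ``recovery_window`` defaults to the
    reperfusion epoch.
    """
    if recovery_window is None:
        ep = trace.protocol.single("reperfusion")
        t0, t1 = ep.start, ep.end
    else:
        t0, t1 = recovery_window
    tail = (trace.time >= max(t0, t1 - terminal_s)) & (trace.time < t1)
    vals = trace.value[tail]
    if vals.size == 0:
        raise ValueError("empty recovery window")
    return float(vals.mean())


def ramp_step_levels(
    trace: NormalizedTrace,
    protocol: ProtocolSpec | None = None,
    tail_s: float = 15.0,
) -> pd.Series:
    """Per-frequency signal level during a stimulation ramp.

    For each ``stim_step`` epoch, the mean of the samples within its final
    ``tail_s`` seconds, keyed by the stimulation frequency (Hz).
    """
    protocol = protocol or trace.protocol
    steps = protocol.by_label("stim_step")
    if not steps:
        raise ValueError("protocol has no stim_step epochs")
    levels: dict[float, float] = {}
    for ep in steps:
        if ep.duration < tail_s:
            raise ValueError(
                f"stimulation step at {ep.start:.0f}s shorter than {tail_s} s"
            )
        sel = (trace.time >= ep.end - tail_s) & (trace.time < ep.end)
        vals = trace.value[sel]
        if vals.size == 0:
            raise ValueError(f"no samples in the final {tail_s} s of a step")
        levels[float(ep.payload["frequency_hz"])] = float(vals.mean())
    out = pd.Series(levels, name="level").sort_index()
    out.index.name = "frequency_hz"
    return out


def yfp_stability(
    series: ChannelTimeSeries,
    qc_threshold: float = 0.10,
) -> tuple[np.ndarray, float, bool]:
    """Baseline-normalised YFP trace, its max |deviation - 1|, and a QC flag.

    The YFP channel is ATP-independent; a large deviation indicates drift,
    focus loss or pH artefacts.  Returns (normalized trace, max deviation,
    flagged) where flagged is True when the deviation exceeds the threshold.
    """
    base = series.protocol.baseline
    base_vals = series.yfp[base.contains(series.time)]
    if base_vals.size == 0:
        raise ValueError("no baseline epoch samples for YFP normalization")
    norm = series.yfp / float(base_vals.mean())
    max_dev = float(np.max(np.abs(norm - 1.0)))
    flagged = max_dev > qc_threshold
    if flagged:
        logger.warning("YFP stability QC failed: max deviation %.3f", max_dev)
    return norm, max_dev, flagged


def summarize_kinetics(
    trace: NormalizedTrace,
    window_s: float = DEFAULT_SLOPE_WINDOW_S,
    k_sd: float = DEFAULT_K_SD,
) -> KineticsSummary:
    """Decay rate (GD), recovery-onset delay and recovery amplitude of a
    GD/reperfusion experiment."""
    gd = trace.protocol.single("GD")
    rep = trace.protocol.single("reperfusion")
    rate = max_slope_rate(trace, window_s, epoch="GD")
    delay = onset_delay(trace, rep.start, k_sd=k_sd, window_s=window_s, direction="up")
    amp = recovery_amplitude(trace, (rep.start, rep.end))
    del gd
    return KineticsSummary(
        decay_rate=rate,
        onset_delay=delay,
        recovery_amplitude=amp,
        slope_window_s=window_s,
        k_sd=k_sd,
    )
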