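"""Synthetic optic-nerve datasets: every input the analysis pipeline
consumes, generated from a seed.

Four input families are emulated with the statistical structure the ex
vivo experiments assume:

* TCSPC decay histograms — photons drawn component-wise from a
  multi-exponential decay, jittered by a Gaussian instrument response,
  optionally wrapped modulo the laser period, and binned (Monte-Carlo or
  noiseless-expectation mode);
* FLIM scenes — label-masked axon images with genotype-dependent lifetime
  means and two variance layers (across-axon and within-axon), with ground
  truth returned for recovery tests;
* three-channel (CFP/FRET/YFP) intensity time series whose F/C ratio
  follows a piecewise-exponential latent ATP trajectory shaped by the
  perfusion protocol (baseline, stimulation ramp, GD, delayed reperfusion
  recovery, terminal MB+GD collapse to the zero anchor);
* stimulus-locked biphasic CAP waveforms with a stimulus artifact and a
  terminal trough, with closed-form areas for oracle checks.

All randomness flows through one explicitly passed numpy Generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.special import erf

from .cap import CAPSeries, CAPTrace
from .flim import (
    DecayHistogram,
    IRFHistogram,
    MultiExpModel,
    exp_bin_kernel,
    make_bin_times,
)
from .protocol import ProtocolSpec
from .ratio import ChannelTimeSeries

__all__ = [
    "SimConfig",
    "GenotypeModel",
    "FlimScene",
    "gen_irf",
    "simulate_decay",
    "gen_flim_scene",
    "latent_trajectory",
    "gen_ratio_timeseries",
    "gen_cap_trace",
    "cap_trace_expected_area",
    "gen_cap_series",
    "gen_excitability_traces",
]

_NS = 1e-9


def _rng(seed_or_rng: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """TCSPC acquisition geometry for the simulator.

    Defaults follow the pulsed two-photon setup emulated here: 80 MHz
    repetition rate and a 27 ps nominal time bin.  ``n_bins`` defaults to
    filling the laser period.  ``wrap`` folds photons arriving after the
    recorded window back into it (the steady-state pile-up of multi-ns
    decays at a 12.5 ns period); switch it off, or lower
    ``rep_frequency``, when unbiased moments over a long window are needed.
    """

    seed: int = 0
    rep_frequency: float = 8.0e7  # Hz
    bin_width: float = 0.027  # ns
    n_bins: int | None = None
    irf_center: float = 2.0  # ns
    irf_width_sigma: float = 0.1  # ns
    photons_per_pixel: float = 2000.0
    wrap: bool = True

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.irf_width_sigma < 0:
            raise ValueError("irf_width_sigma must be >= 0")
        if self.rep_frequency <= 0:
            raise ValueError("rep_frequency must be positive")
        if self.n_bins is None:
            self.n_bins = int(math.floor(self.period / self.bin_width))
        if self.n_bins < 8:
            raise ValueError("configuration yields fewer than 8 bins")
        if self.wrap and self.window > self.period + 1e-9:
            raise ValueError(
                "recorded window exceeds the laser period with wrap enabled"
            )
        if not 0 <= self.irf_center <= self.window:
            raise ValueError("irf_center must lie inside the recorded window")

    @property
    def period(self) -> float:
        """Laser repetition period in ns."""
        return 1.0 / self.rep_frequency / _NS

    @property
    def window(self) -> float:
        """Recorded window length n_bins * bin_width in ns."""
        return self.n_bins * self.bin_width

    @property
    def bin_times(self) -> np.ndarray:
        return make_bin_times(self.n_bins, self.bin_width)


@dataclass
class GenotypeModel:
    """Lifetime statistics of one simulated genotype.

    ``mean_lifetime`` is the grand mean donor lifetime (ns);
    ``across_axon_sd`` spreads per-axon means, ``within_axon_sd`` spreads
    pixels inside an axon.  The two layers correspond to the across-axon
    and within-axon coefficient-of-variation analyses.
    """

    mean_lifetime: float  # ns
    within_axon_sd: float  # ns
    across_axon_sd: float  # ns
    n_axons: int = 8
    axon_length_um: float = 20.0
    pixel_size_um: float = 0.192

    def __post_init__(self) -> None:
        if self.mean_lifetime <= 0:
            raise ValueError("mean_lifetime must be positive")
        if self.within_axon_sd < 0 or self.across_axon_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_axons < 1:
            raise ValueError("n_axons must be >= 1")


# ---------------------------------------------------------------------------
# IRF and decay simulation
# ---------------------------------------------------------------------------

def gen_irf(
    cfg: SimConfig,
    n_photons: float = 1e6,
    sampled: bool = False,
    rng: int | np.random.Generator | None = None,
) -> IRFHistogram:
    """Gaussian instrument response histogram.

    In expectation mode (default, noise disabled) bin contents are the
    truncated-Gaussian bin probabilities times the photon budget, so total
    counts equal the budget exactly.  ``sampled=True`` draws photons
    instead.  ``irf_width_sigma = 0`` degenerates to a single bin at
    ``irf_center``.
    """
    edges = np.arange(cfg.n_bins + 1) * cfg.bin_width
    if cfg.irf_width_sigma == 0:
        counts = np.zeros(cfg.n_bins)
        idx = min(int(cfg.irf_center / cfg.bin_width), cfg.n_bins - 1)
        counts[idx] = n_photons
    elif not sampled:
        z = (edges - cfg.irf_center) / (cfg.irf_width_sigma * math.sqrt(2.0))
        cdf = 0.5 * (1.0 + erf(z))
        probs = np.diff(cdf)
        total = probs.sum()
        if total <= 0:
            raise ValueError("IRF lies entirely outside the recorded window")
        counts = n_photons * probs / total
    else:
        gen = _rng(rng if rng is not None else cfg.seed)
        draws = gen.normal(cfg.irf_center, cfg.irf_width_sigma, int(n_photons))
        draws = np.mod(draws, cfg.window)
        counts, _ = np.histogram(draws, bins=edges)
    return IRFHistogram(
        bin_times=cfg.bin_times,
        counts=counts,
        bin_width=cfg.bin_width,
        rep_frequency=cfg.rep_frequency,
    )


def _sample_irf_times(
    irf: IRFHistogram, n: int, gen: np.random.Generator
) -> np.ndarray:
    """Draw arrival-time jitter from an IRF histogram (uniform within bin)."""
    probs = np.asarray(irf.counts, dtype=float)
    probs = probs / probs.sum()
    idx = gen.choice(irf.n_bins, size=n, p=probs)
    return irf.bin_times[idx] + gen.uniform(-0.5, 0.5, n) * irf.bin_width


def simulate_decay(
    model: MultiExpModel,
    irf: IRFHistogram,
    n_photons: int,
    cfg: SimConfig,
    rng: int | np.random.Generator | None = None,
    expectation: bool = False,
) -> DecayHistogram:
    """Simulate one TCSPC decay histogram.

    Monte-Carlo mode draws each photon as: component j with probability
    A_j / sum(A), exponential arrival with lifetime tau_j, additive IRF
    jitter, optional wrap modulo the recorded window, then binning.  With
    wrap enabled every photon lands in a bin, so counts conserve the
    photon number exactly.

    ``expectation=True`` returns the noiseless expected counts (float):
    the circular (wrap) or linear convolution of the exact per-bin
    exponential probabilities with the IRF bin distribution.
    """
    if n_photons <= 0:
        raise ValueError("n_photons must be positive")
    fracs = model.amplitudes / model.amplitudes.sum()
    edges = np.arange(cfg.n_bins + 1) * cfg.bin_width
    irf_probs = np.asarray(irf.counts, dtype=float)
    irf_probs = irf_probs / irf_probs.sum()

    if expectation:
        kern = exp_bin_kernel(model.lifetimes, fracs, cfg.bin_width,
                              cfg.n_bins, wrap=cfg.wrap)
        if cfg.wrap:
            spec = np.fft.rfft(irf_probs) * np.fft.rfft(kern)
            probs = np.fft.irfft(spec, n=cfg.n_bins)
        else:
            probs = np.convolve(irf_probs, kern)[: cfg.n_bins]
        counts = n_photons * np.clip(probs, 0.0, None)
    else:
        gen = _rng(rng if rng is not None else cfg.seed)
        comp = gen.choice(model.m, size=n_photons, p=fracs)
        taus = model.lifetimes[comp]
        t = gen.exponential(taus) + _sample_irf_times(irf, n_photons, gen)
        if cfg.wrap:
            t = np.mod(t, cfg.window)
        else:
            t = t[t < cfg.window]
        idx = np.minimum((t / cfg.bin_width).astype(np.int64), cfg.n_bins - 1)
        counts = np.bincount(idx, minlength=cfg.n_bins)
    return DecayHistogram(
        bin_times=cfg.bin_times,
        counts=counts,
        bin_width=cfg.bin_width,
        rep_frequency=cfg.rep_frequency,
    )


# ---------------------------------------------------------------------------
# FLIM scenes
# ---------------------------------------------------------------------------

@dataclass
class FlimScene:
    """One simulated nerve: label mask, per-pixel decays, and ground truth."""

    labels: np.ndarray  # 2D int16 label image, 0 = background
    pixel_coords: np.ndarray  # (N, 2) row/col of the labelled pixels
    decay_counts: np.ndarray  # (N, n_bins) photon counts
    irf: IRFHistogram
    cfg: SimConfig
    genotype: GenotypeModel
    truth_pixel_tau: np.ndarray  # (N,) ground-truth pixel lifetimes (ns)
    truth_axon_tau: np.ndarray  # (n_axons,) ground-truth axon means (ns)
    pixel_labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.pixel_labels is None:
            self.pixel_labels = self.labels[
                self.pixel_coords[:, 0], self.pixel_coords[:, 1]
            ]

    def counts_image(self) -> np.ndarray:
        """Dense (H, W, n_bins) decay stack (zeros on background)."""
        out = np.zeros(self.labels.shape + (self.decay_counts.shape[1],),
                       dtype=self.decay_counts.dtype)
        out[self.pixel_coords[:, 0], self.pixel_coords[:, 1]] = self.decay_counts
        return out


def gen_flim_scene(
    geno: GenotypeModel,
    cfg: SimConfig,
    rng: int | np.random.Generator | None = None,
    stripe_height: int = 2,
    gap: int = 1,
    image_shape: tuple[int, int] | None = None,
    irf_photons: float = 1e6,
) -> FlimScene:
    """Simulate a FLIM scene of parallel axon segments.

    Axons are laid out as contiguous horizontal stripes separated by
    background rows (stand-ins for the manually segmented axon masks of a
    real nerve).  Per-axon mean lifetimes are drawn with
    ``across_axon_sd``; pixel lifetimes within an axon with
    ``within_axon_sd``; per-pixel photon numbers are Poisson with mean
    ``cfg.photons_per_pixel`` and arrival times are simulated
    photon-by-photon as in :func:`simulate_decay`.
    """
    gen = _rng(rng if rng is not None else cfg.seed)
    px_len = max(int(round(geno.axon_length_um / geno.pixel_size_um)), 1)
    need_h = geno.n_axons * (stripe_height + gap) + gap
    if image_shape is None:
        shape = (need_h, px_len)
    else:
        shape = image_shape
        if shape[0] < need_h or shape[1] < px_len:
            raise ValueError(
                f"mask area {shape} insufficient for {geno.n_axons} axons "
                f"of {px_len} px"
            )
    labels = np.zeros(shape, dtype=np.int16)
    for k in range(geno.n_axons):
        r0 = gap + k * (stripe_height + gap)
        labels[r0 : r0 + stripe_height, :px_len] = k + 1

    coords = np.argwhere(labels > 0)
    pix_labels = labels[coords[:, 0], coords[:, 1]]
    n_px = coords.shape[0]

    axon_tau = gen.normal(geno.mean_lifetime, geno.across_axon_sd, geno.n_axons)
    axon_tau = np.clip(axon_tau, 0.05, None)
    pixel_tau = gen.normal(axon_tau[pix_labels - 1], geno.within_axon_sd)
    pixel_tau = np.clip(pixel_tau, 0.05, None)

    irf = gen_irf(cfg, n_photons=irf_photons)

    n_ph = gen.poisson(cfg.photons_per_pixel, n_px)
    total = int(n_ph.sum())
    pix_idx = np.repeat(np.arange(n_px), n_ph)
    arrivals = gen.exponential(pixel_tau[pix_idx])
    if cfg.irf_width_sigma > 0:
        arrivals += gen.normal(cfg.irf_center, cfg.irf_width_sigma, total)
    else:
        arrivals += cfg.irf_center
    arrivals = np.mod(arrivals, cfg.window) if cfg.wrap else arrivals
    keep = arrivals < cfg.window
    arrivals, pix_idx = arrivals[keep], pix_idx[keep]
    bins = np.minimum((arrivals / cfg.bin_width).astype(np.int64), cfg.n_bins - 1)
    flat = np.bincount(pix_idx * cfg.n_bins + bins, minlength=n_px * cfg.n_bins)
    decay_counts = flat.reshape(n_px, cfg.n_bins).astype(np.int32)

    return FlimScene(
        labels=labels,
        pixel_coords=coords,
        decay_counts=decay_counts,
        irf=irf,
        cfg=cfg,
        genotype=geno,
        truth_pixel_tau=pixel_tau,
        truth_axon_tau=axon_tau,
    )


# ---------------------------------------------------------------------------
# Latent ATP trajectory and channel time series
# ---------------------------------------------------------------------------

def latent_trajectory(
    protocol: ProtocolSpec,
    kinetics: dict[str, dict[str, float]],
    time: np.ndarray,
) -> np.ndarray:
    """Piecewise latent normalized ATP trajectory over ``time`` (seconds).

    Baseline holds at 1.  Per-epoch closed forms, each continuous with the
    value carried from the previous epoch:

    * GD: exponential decay toward ``plateau`` at ``rate_per_s``;
    * stim_step: exponential relaxation (time constant ``tau_s``) toward a
      frequency-dependent level 1 - drop_max * f / (f + f_half);
    * reperfusion: hold for ``delay_s``, then exponential recovery (time
      constant ``tau_s``) toward ``plateau``;
    * MBGD: linear collapse to exactly 0 over ``ramp_s`` (the zero
      anchor), clamped there.
    """
    time = np.asarray(time, dtype=float)
    out = np.empty_like(time)
    v0 = 1.0
    for ep in protocol:
        if ep.label != "baseline" and ep.label not in kinetics:
            raise ValueError(f"kinetics missing for epoch {ep.label!r}")
        sel = ep.contains(time)
        tt = time[sel] - ep.start
        dur = ep.duration
        if ep.label == "baseline":
            out[sel] = 1.0
            v_end = 1.0
        elif ep.label == "GD":
            p = kinetics["GD"]
            v = p["plateau"] + (v0 - p["plateau"]) * np.exp(-p["rate_per_s"] * tt)
            out[sel] = v
            v_end = p["plateau"] + (v0 - p["plateau"]) * math.exp(
                -p["rate_per_s"] * dur
            )
        elif ep.label == "stim_step":
            p = kinetics["stim_step"]
            f = float(ep.payload["frequency_hz"])
            target = 1.0 - p["drop_max"] * f / (f + p["f_half"])
            v = target + (v0 - target) * np.exp(-tt / p["tau_s"])
            out[sel] = v
            v_end = target + (v0 - target) * math.exp(-dur / p["tau_s"])
        elif ep.label == "reperfusion":
            p = kinetics["reperfusion"]
            d = p["delay_s"]
            v = np.where(
                tt < d,
                v0,
                p["plateau"] + (v0 - p["plateau"]) * np.exp(
                    -np.clip(tt - d, 0.0, None) / p["tau_s"]
                ),
            )
            out[sel] = v
            v_end = (
                v0
                if dur < d
                else p["plateau"]
                + (v0 - p["plateau"]) * math.exp(-(dur - d) / p["tau_s"])
            )
        elif ep.label == "MBGD":
            p = kinetics["MBGD"]
            v = np.clip(v0 * (1.0 - tt / p["ramp_s"]), 0.0, None)
            out[sel] = v
            v_end = max(v0 * (1.0 - dur / p["ramp_s"]), 0.0)
        else:  # pragma: no cover - label set is closed
            raise ValueError(f"unhandled epoch label {ep.label!r}")
        v0 = v_end
    return out


def gen_ratio_timeseries(
    protocol: ProtocolSpec,
    kinetics: dict[str, dict[str, float]],
    noise_sd: float = 0.0,
    rng: int | np.random.Generator | None = None,
    dt: float = 10.4,
    cfp_level: float = 100.0,
    yfp_level: float = 100.0,
    ratio_anchors: tuple[float, float] = (0.6, 1.0),
    yfp_drift: float = 0.0,
) -> tuple[ChannelTimeSeries, dict[str, Any]]:
    """Three-channel confocal time series whose F/C ratio encodes the
    latent ATP trajectory.

    The raw F/C ratio is an affine image of the latent trajectory
    (``ratio_anchors`` = raw ratio at latent 0 and 1), realised as
    FRET = ratio * CFP with a constant CFP level; the YFP channel is
    approximately constant (optionally drifting by ``yfp_drift`` fraction
    over the experiment, for QC tests).  ``noise_sd`` is the per-channel
    additive noise SD as a fraction of the channel level.  Sampling every
    ``dt`` seconds (default: the 10.4 s confocal frame interval).

    Returns the series and a ground-truth dict (latent trajectory, raw
    anchors, kinetics).
    """
    gen = _rng(rng)
    time = np.arange(0.0, protocol.end, dt)
    latent = latent_trajectory(protocol, kinetics, time)
    r0, r1 = ratio_anchors
    raw_ratio = r0 + (r1 - r0) * latent
    n = time.size
    cfp = np.full(n, cfp_level)
    fret = raw_ratio * cfp_level
    yfp = yfp_level * (1.0 + yfp_drift * time / max(protocol.end, 1.0))
    if noise_sd > 0:
        cfp = cfp + gen.normal(0.0, noise_sd * cfp_level, n)
        fret = fret + gen.normal(0.0, noise_sd * cfp_level, n)
        yfp = yfp + gen.normal(0.0, noise_sd * yfp_level, n)
    series = ChannelTimeSeries(time=time, cfp=cfp, fret=fret, yfp=yfp,
                               protocol=protocol)
    truth = {
        "latent": latent,
        "ratio_anchors": (r0, r1),
        "kinetics": kinetics,
        "dt": dt,
    }
    return series, truth


# ---------------------------------------------------------------------------
# CAP waveforms and series
# ---------------------------------------------------------------------------

def _gauss(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def _gauss_integral(t0: float, t1: float, center: float, width: float) -> float:
    """Integral of exp(-(t-c)^2 / 2w^2) over [t0, t1]."""
    s = width * math.sqrt(2.0)
    return width * math.sqrt(math.pi / 2.0) * (
        erf((t1 - center) / s) - erf((t0 - center) / s)
    )


#: (latency ms, width ms, fraction of amplitude) of the terminal trough
DEFAULT_TROUGH = (1.6, 0.12, 0.15)


def gen_cap_trace(
    amplitude: float,
    peak_latencies: tuple[float, float] = (0.55, 1.05),
    noise_sd: float = 0.0,
    rng: int | np.random.Generator | None = None,
    sampling_khz: float = 20.0,
    t_span: tuple[float, float] = (-0.5, 5.0),
    lobe_widths: tuple[float, float] = (0.12, 0.18),
    second_fraction: float = 0.6,
    trough: tuple[float, float, float] = DEFAULT_TROUGH,
    artifact_fraction: float = 3.0,
) -> CAPTrace:
    """Synthetic biphasic CAP sweep.

    Two positive Gaussian lobes at ``peak_latencies`` (amplitudes
    ``amplitude`` and ``second_fraction * amplitude``), a small negative
    lobe marking the trough at the end of the second peak, and a brief
    biphasic stimulus artifact near t = 0 inside the blanking interval.
    The pre-stimulus baseline is zero-mean.  ``amplitude = 0`` yields a
    flat (noise-only) trace.
    """
    l1, l2 = peak_latencies
    for lat in (l1, l2):
        if not 0.2 < lat < 2.0:
            raise ValueError("peak latencies must lie in (0.2, 2.0) ms")
    gen = _rng(rng)
    dt = 1.0 / sampling_khz
    # integer-multiple grid so t = 0 is exact (keeps the stimulus sample
    # out of the pre-stimulus baseline mask)
    k0 = int(round(t_span[0] / dt))
    k1 = int(round(t_span[1] / dt))
    time = np.arange(k0, k1 + 1) * dt
    w1, w2 = lobe_widths
    tl, tw, tf = trough
    v = amplitude * (
        _gauss(time, l1, w1)
        + second_fraction * _gauss(time, l2, w2)
        - tf * _gauss(time, tl, tw)
    )
    # biphasic stimulus artifact, confined to the blanking interval
    art = artifact_fraction * amplitude
    v += art * (_gauss(time, 0.04, 0.015) - _gauss(time, 0.08, 0.015))
    if noise_sd > 0:
        v = v + gen.normal(0.0, noise_sd, time.size)
    return CAPTrace(time=time, voltage=v, sampling_khz=sampling_khz)


def cap_trace_expected_area(
    amplitude: float,
    window: tuple[float, float],
    peak_latencies: tuple[float, float] = (0.55, 1.05),
    lobe_widths: tuple[float, float] = (0.12, 0.18),
    second_fraction: float = 0.6,
    trough: tuple[float, float, float] = DEFAULT_TROUGH,
) -> float:
    """Closed-form (error-function) area of the noiseless generator
    waveform over ``window``, excluding the stimulus artifact (which lies
    inside the blanking interval)."""
    t0, t1 = window
    l1, l2 = peak_latencies
    w1, w2 = lobe_widths
    tl, tw, tf = trough
    return amplitude * (
        _gauss_integral(t0, t1, l1, w1)
        + second_fraction * _gauss_integral(t0, t1, l2, w2)
        - tf * _gauss_integral(t0, t1, tl, tw)
    )


def gen_cap_series(
    protocol: ProtocolSpec,
    kinetics: dict[str, dict[str, float]],
    baseline_area: float = 1.0,
    mbgd_area: float = 0.0,
    noise_sd: float = 0.0,
    rng: int | np.random.Generator | None = None,
    dt: float = 10.0,
) -> tuple[CAPSeries, dict[str, Any]]:
    """Experiment-long CAP-area series following a latent trajectory.

    The raw area is an affine image of the same piecewise latent model
    used for the ATP signal (latent 1 -> ``baseline_area``, latent 0 ->
    ``mbgd_area``), so the two-point normalization recovers the latent
    trajectory exactly on noiseless series.
    """
    gen = _rng(rng)
    time = np.arange(0.0, protocol.end, dt)
    latent = latent_trajectory(protocol, kinetics, time)
    area = mbgd_area + (baseline_area - mbgd_area) * latent
    if noise_sd > 0:
        area = area + gen.normal(0.0, noise_sd * baseline_area, time.size)
    series = CAPSeries(time=time, area=area, protocol=protocol)
    truth = {"latent": latent, "kinetics": kinetics, "dt": dt}
    return series, truth


def gen_excitability_traces(
    max_amplitude: float,
    intensities_ma: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.45, 0.6, 0.75, 1.0),
    half_intensity_ma: float = 0.25,
    hill: float = 4.0,
    noise_sd: float = 0.0,
    rng: int | np.random.Generator | None = None,
) -> list[tuple[float, CAPTrace]]:
    """CAP sweeps across stimulus intensities with saturating recruitment.

    The CAP amplitude scales as a Hill recruitment curve of the stimulus
    intensity; two genotypes differing only in ``max_amplitude`` produce
    different raw excitability curves but identical normalized-to-max
    curves (fewer active axons, same excitability).
    """
    gen = _rng(rng)
    out = []
    for i in intensities_ma:
        recruit = i**hill / (i**hill + half_intensity_ma**hill) if i > 0 else 0.0
        out.append(
            (float(i), gen_cap_trace(max_amplitude * recruit, noise_sd=noise_sd,
                                     rng=gen))
        )
    return out
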