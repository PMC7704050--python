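"""Pixel-wise lifetime maps and axon-level variability statistics.

Two variability readouts are computed from a lifetime map and an axon
label mask, mirroring how intra- and inter-axonal ATP heterogeneity is
quantified:

* within-axon CV — SD/mean of the lifetimes of all pixels inside one
  axon (one CV per axon);
* across-axon CV — the two-stage procedure: first the mean lifetime of
  each axon, then the CV of those per-axon means (one CV per nerve).

Sample (n-1) standard deviations are used throughout.  Group comparisons
are thin wrappers around the standard two-sample and multi-group tests.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .flim import IRFHistogram

logger = logging.getLogger(__name__)

__all__ = [
    "LifetimeMap",
    "AxonSegmentation",
    "NerveSummary",
    "pixel_lifetime_map",
    "within_axon_cv",
    "across_axon_cv",
    "whole_nerve_lifetime",
    "nerve_summary",
    "compare_groups",
    "GroupTestResult",
]

#: minimum valid pixels for an axon to enter the CV statistics
DEFAULT_MIN_PIXELS = 50


@dataclass
class LifetimeMap:
    """Per-pixel mean-lifetime image with its photon-count image.

    ``tau`` is nan outside ``mask``; statistics only ever touch masked
    pixels.
    """

    tau: np.ndarray  # ns, 2D
    photons: np.ndarray  # counts, 2D
    mask: np.ndarray  # bool, 2D
    pixel_size_um: float = 0.192

    def __post_init__(self) -> None:
        if not (self.tau.shape == self.photons.shape == self.mask.shape):
            raise ValueError("tau, photons and mask must be congruent")

    @property
    def valid_taus(self) -> np.ndarray:
        return self.tau[self.mask]


@dataclass
class AxonSegmentation:
    """Axon label image: 0 = background, k >= 1 = axon k.  Optional
    per-label physical segment lengths in micrometres."""

    labels: np.ndarray
    segment_lengths_um: dict[int, float] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label image must be 2D")
        if np.any(self.labels < 0):
            raise ValueError("labels must be non-negative")

    @property
    def axon_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclass(frozen=True)
class NerveSummary:
    """Per-nerve lifetime-variability summary."""

    whole_nerve_tau: float  # ns
    axon_means: pd.Series  # ns, indexed by axon id
    within_cv: pd.Series  # dimensionless, indexed by axon id
    across_cv: float  # dimensionless


def pixel_lifetime_map(
    counts: np.ndarray,
    bin_times: np.ndarray,
    irf: IRFHistogram,
    min_photons: int = 100,
    background: float = 0.0,
    pixel_size_um: float = 0.192,
) -> LifetimeMap:
    """Vectorised per-pixel moment lifetime map.

    ``counts`` is a (H, W, n_bins) decay stack sharing the IRF bin
    geometry.  tau_bar = F1/F0 - H1/H0 per pixel; pixels whose photon
    count falls below ``min_photons`` are masked invalid.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 3:
        raise ValueError("counts must be a (H, W, n_bins) stack")
    if counts.shape[-1] != irf.n_bins:
        raise ValueError("decay stack and IRF must share bin geometry")
    corrected = counts - background
    photons = counts.sum(axis=-1)
    f0 = corrected.sum(axis=-1)
    f1 = corrected @ np.asarray(bin_times, dtype=float)
    mask = (photons >= min_photons) & (f0 > 0)
    if not mask.any():
        raise ValueError("no pixel reaches the minimum photon count")
    tau = np.full(photons.shape, np.nan)
    tau[mask] = f1[mask] / f0[mask] - irf.delta_irf
    return LifetimeMap(tau=tau, photons=photons, mask=mask,
                       pixel_size_um=pixel_size_um)


def _axon_pixels(
    lifetime_map: LifetimeMap, seg: AxonSegmentation, axon_id: int
) -> np.ndarray:
    sel = (seg.labels == axon_id) & lifetime_map.mask
    return lifetime_map.tau[sel]


def _cv(values: np.ndarray) -> float:
    mean = float(values.mean())
    if mean == 0:
        return float("nan")
    return float(np.std(values, ddof=1)) / mean


def within_axon_cv(
    lifetime_map: LifetimeMap,
    seg: AxonSegmentation,
    min_pixels: int = DEFAULT_MIN_PIXELS,
) -> pd.Series:
    """Coefficient of variation of the pixel lifetimes within each axon.

    CV_k = SD(pixels in axon k) / mean(pixels in axon k), sample SD.
    Axons with fewer than ``min_pixels`` valid pixels are excluded with a
    logged warning.
    """
    if seg.labels.shape != lifetime_map.tau.shape:
        raise ValueError("segmentation and lifetime map shapes differ")
    out: dict[int, float] = {}
    for axon_id in seg.axon_ids:
        vals = _axon_pixels(lifetime_map, seg, int(axon_id))
        if vals.size < min_pixels:
            logger.warning(
                "axon %d excluded: %d valid pixels < minimum %d",
                axon_id, vals.size, min_pixels,
            )
            continue
        out[int(axon_id)] = _cv(vals)
    series = pd.Series(out, name="within_axon_cv", dtype=float)
    series.index.name = "axon_id"
    return series


def _axon_means(
    lifetime_map: LifetimeMap, seg: AxonSegmentation, min_pixels: int
) -> pd.Series:
    out: dict[int, float] = {}
    for axon_id in seg.axon_ids:
        vals = _axon_pixels(lifetime_map, seg, int(axon_id))
        if vals.size < min_pixels:
            logger.warning(
                "axon %d excluded from across-axon CV: %d pixels < %d",
                axon_id, vals.size, min_pixels,
            )
            continue
        out[int(axon_id)] = float(vals.mean())
    series = pd.Series(out, name="mean_tau_ns", dtype=float)
    series.index.name = "axon_id"
    return series


def across_axon_cv(
    lifetime_map: LifetimeMap,
    seg: AxonSegmentation,
    min_pixels: int = DEFAULT_MIN_PIXELS,
) -> float:
    """Across-axon CV of one nerve: the two-stage procedure.

    First the mean lifetime of all pixels within each axon, then the CV of
    these mean axonal lifetimes.
    """
    means = _axon_means(lifetime_map, seg, min_pixels)
    if means.size < 2:
        raise ValueError("across-axon CV requires at least 2 included axons")
    return _cv(means.to_numpy())


def whole_nerve_lifetime(
    lifetime_map: LifetimeMap,
    seg: AxonSegmentation | None = None,
) -> float:
    """Mean lifetime over the whole valid region (or over axon-masked
    pixels when a segmentation is given)."""
    if seg is None:
        vals = lifetime_map.valid_taus
    else:
        sel = (seg.labels > 0) & lifetime_map.mask
        vals = lifetime_map.tau[sel]
    if vals.size == 0:
        raise ValueError("empty region: no valid pixels")
    return float(vals.mean())


def nerve_summary(
    lifetime_map: LifetimeMap,
    seg: AxonSegmentation,
    min_pixels: int = DEFAULT_MIN_PIXELS,
) -> NerveSummary:
    """All per-nerve statistics in one pass."""
    means = _axon_means(lifetime_map, seg, min_pixels)
    if means.size < 2:
        raise ValueError("nerve summary requires at least 2 included axons")
    return NerveSummary(
        whole_nerve_tau=whole_nerve_lifetime(lifetime_map),
        axon_means=means,
        within_cv=within_axon_cv(lifetime_map, seg, min_pixels),
        across_cv=_cv(means.to_numpy()),
    )


# ---------------------------------------------------------------------------
# Group comparison statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupTestResult:
    statistic: float
    pvalue: float
    test: str
    pairwise: pd.DataFrame | None = None  # post-hoc table for >= 3 groups


def _dunn_posthoc(samples: list[np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-sum post-hoc z tests (two-sided, unadjusted p)."""
    all_vals = np.concatenate(samples)
    ranks = stats.rankdata(all_vals)
    n_total = all_vals.size
    # tie correction term
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    offsets = np.cumsum([0] + [s.size for s in samples])
    mean_ranks = [
        ranks[offsets[i] : offsets[i + 1]].mean() for i in range(len(samples))
    ]
    rows = []
    for i, j in itertools.combinations(range(len(samples)), 2):
        ni, nj = samples[i].size, samples[j].size
        se = math.sqrt(
            (n_total * (n_total + 1) / 12.0 - tie_term) * (1.0 / ni + 1.0 / nj)
        )
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": i, "group_b": j, "z": z, "pvalue": p})
    return pd.DataFrame(rows)


def compare_groups(
    *samples: np.ndarray,
    test: str = "student_t",
) -> GroupTestResult:
    """Standard two-sided group comparisons.

    Two samples: ``student_t`` (pooled variance) or ``welch``.  Three or
    more: ``anova_tukey`` (one-way ANOVA with Tukey HSD pairwise) or
    ``kruskal_dunn`` (Kruskal-Wallis with Dunn's pairwise z tests).
    """
    arrays = [np.asarray(s, dtype=float) for s in samples]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each sample needs n >= 2")
    if test in ("student_t", "welch"):
        if len(arrays) != 2:
            raise ValueError(f"{test} requires exactly 2 samples")
        res = stats.ttest_ind(arrays[0], arrays[1], equal_var=(test == "student_t"))
        return GroupTestResult(float(res.statistic), float(res.pvalue), test)
    if test == "anova_tukey":
        if len(arrays) < 3:
            raise ValueError("anova_tukey requires >= 3 samples")
        omni = stats.f_oneway(*arrays)
        hsd = stats.tukey_hsd(*arrays)
        rows = []
        for i, j in itertools.combinations(range(len(arrays)), 2):
            rows.append({
                "group_a": i, "group_b": j,
                "statistic": float(hsd.statistic[i, j]),
                "pvalue": float(hsd.pvalue[i, j]),
            })
        return GroupTestResult(float(omni.statistic), float(omni.pvalue),
                               test, pd.DataFrame(rows))
    if test == "kruskal_dunn":
        if len(arrays) < 3:
            raise ValueError("kruskal_dunn requires >= 3 samples")
        omni = stats.kruskal(*arrays)
        return GroupTestResult(float(omni.statistic), float(omni.pvalue),
                               test, _dunn_posthoc(arrays))
    raise ValueError(f"unknown test {test!r}")
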