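"""ATP-concentration <-> donor-lifetime calibration.

In patch-clamped cells dialysed with known ATP concentrations, the donor
fluorescence lifetime of the FRET ATP sensor decreases monotonically with
ATP (ATP binding raises FRET, shortening the donor lifetime).  A Hill-form
saturation curve

    tau(c) = tau_max - (tau_max - tau_min) * c^n / (K^n + c^n)

is fitted to (concentration, lifetime) data and can be inverted uniquely
on its monotone range.  Absolute lifetimes measured in cells differ from
those in tissue, so inverting the curve for a lifetime measured in a
different context carries an explicit non-transferability warning — the
inverse is a within-calibration-context estimate, never an absolute
tissue ATP concentration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationCurve",
    "TransferabilityWarning",
    "fit_calibration",
    "invert_calibration",
]

#: per-concentration replicate counts typical of patch-clamp calibration
#: datasets at (0, 1, 2, 4, 6, 10, 24) mM; used for SEM weighting when
#: replicate-level data are not supplied
DEFAULT_REPLICATES = (5, 3, 4, 2, 3, 2, 2)


class TransferabilityWarning(UserWarning):
    """Inverted concentrations are only valid in the calibration context."""


def _hill(c: np.ndarray, tau_max: float, tau_min: float, k: float, n: float
          ) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    return tau_max - (tau_max - tau_min) * c**n / (k**n + c**n)


@dataclass
class CalibrationCurve:
    """Fitted Hill-form lifetime-vs-ATP curve with diagnostics."""

    concentrations: np.ndarray  # mM
    lifetimes: np.ndarray  # ns (per-concentration means)
    tau_max: float  # ns, lifetime at zero ATP
    tau_min: float  # ns, fully saturated lifetime
    k: float  # mM, half-saturation
    n: float  # Hill coefficient
    residuals: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    degenerate: bool = False
    rmse: float = float("nan")

    def predict(self, c: np.ndarray | float) -> np.ndarray | float:
        return _hill(c, self.tau_max, self.tau_min, self.k, self.n)

    @property
    def c_max(self) -> float:
        return float(np.max(self.concentrations))


def fit_calibration(
    concentrations: np.ndarray,
    lifetimes: np.ndarray,
    sem: np.ndarray | None = None,
) -> CalibrationCurve:
    """Fit the Hill-form calibration curve.

    Needs >= 4 distinct concentrations including 0.  ``sem`` (per-point
    standard errors) weights the fit when given.  Non-monotone data beyond
    noise tolerance, or data with no spread, yield a flagged
    (``degenerate=True``) fit rather than an exception.
    """
    c = np.asarray(concentrations, dtype=float)
    tau = np.asarray(lifetimes, dtype=float)
    if c.shape != tau.shape:
        raise ValueError("concentrations and lifetimes must match in length")
    if np.unique(c).size < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if 0.0 not in c:
        raise ValueError("calibration must include the 0 mM point")
    order = np.argsort(c)
    c, tau = c[order], tau[order]
    if sem is not None:
        sem = np.asarray(sem, dtype=float)[order]

    span = tau.max() - tau.min()
    if span <= 1e-12:
        logger.warning("constant lifetimes across concentrations: degenerate fit")
        return CalibrationCurve(c, tau, tau_max=float(tau[0]),
                                tau_min=float(tau[-1]), k=1.0, n=1.0,
                                residuals=np.zeros_like(tau), degenerate=True,
                                rmse=0.0)

    p0 = (float(tau.max()), float(tau.min()),
          float(np.median(c[c > 0])), 1.0)
    bounds = ([1e-6, 1e-6, 1e-6, 0.2], [np.inf, np.inf, np.inf, 8.0])
    try:
        popt, _ = curve_fit(_hill, c, tau, p0=p0, sigma=sem, bounds=bounds,
                            maxfev=20000)
    except RuntimeError:
        logger.warning("calibration fit did not converge: degenerate flag set")
        return CalibrationCurve(c, tau, *p0, residuals=tau - _hill(c, *p0),
                                degenerate=True)
    tau_max, tau_min, k, n = (float(x) for x in popt)
    resid = tau - _hill(c, tau_max, tau_min, k, n)
    rmse = float(np.sqrt(np.mean(resid**2)))
    degenerate = tau_max <= tau_min or rmse > 0.5 * span
    if degenerate:
        logger.warning("calibration fit flagged: tau_max <= tau_min or poor fit")
    return CalibrationCurve(c, tau, tau_max, tau_min, k, n,
                            residuals=resid, degenerate=degenerate, rmse=rmse)


def invert_calibration(
    curve: CalibrationCurve,
    tau: float,
    same_context: bool = False,
) -> float:
    """Unique inverse of the monotone calibration fit (mM).

    ``tau`` must lie strictly inside (tau_min, tau_max); out-of-range
    lifetimes raise rather than extrapolate.  Unless ``same_context=True``
    a :class:`TransferabilityWarning` is emitted: absolute lifetimes
    differ between calibration cells and tissue, so the returned
    concentration must not be read as an absolute tissue value.
    """
    if curve.degenerate:
        raise ValueError("cannot invert a degenerate calibration fit")
    if not (curve.tau_min < tau < curve.tau_max):
        raise ValueError(
            f"tau = {tau:.4g} ns outside the invertible range "
            f"({curve.tau_min:.4g}, {curve.tau_max:.4g}) ns"
        )
    frac = (curve.tau_max - tau) / (curve.tau_max - curve.tau_min)
    c = curve.k * (frac / (1.0 - frac)) ** (1.0 / curve.n)
    if not same_context:
        warnings.warn(
            "calibration is context-specific; inverted concentration is not "
            "transferable to measurements from a different cellular environment",
            TransferabilityWarning,
            stacklevel=2,
        )
    return float(c)
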