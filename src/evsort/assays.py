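"""Quantitative models for the validation assays.

Microscale-thermophoresis binding isotherms are fitted with the Hill
equation

    response(x) = bottom + (top - bottom) * x^h / (Kd^h + x^h)

by bounded nonlinear least squares (Kd and the Hill coefficient h both
fitted; h can be fixed at 1). Droplet-digital-PCR concentrations use the
Poisson correction: with k positive droplets out of n, the mean copies per
droplet is lambda = -ln(1 - k/n) and the concentration is lambda / v
copies/uL for droplet volume v (QX200 convention 0.85 nL = 8.5e-4 uL).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .simulate import BindingCurve, hill_response

logger = logging.getLogger(__name__)

DROPLET_VOLUME_UL = 8.5e-4  # QX200 droplet volume in microliters


@dataclass
class BindingFit:
    kd: float
    hill_h: float
    top: float
    bottom: float
    se_kd: float
    converged: bool

    def predict(self, x):
        return hill_response(x, self.kd, self.hill_h, self.top, self.bottom)


@dataclass
class DdpcrSample:
    positive_droplets: int
    total_droplets: int
    droplet_volume_ul: float
    copies_per_ul: float
    ci95: tuple[float, float]


class SaturationError(ValueError):
    """Every droplet positive: the Poisson correction is undefined; dilute."""


def average_replicates(curves: list[BindingCurve]) -> BindingCurve:
    """Pointwise mean of replicate curves measured at identical
    concentrations (matching the instrument convention of averaging the
    temperature-jump data before fitting)."""
    if not curves:
        raise ValueError("no curves to average")
    conc = curves[0].concentrations
    for c in curves[1:]:
        if not np.allclose(c.concentrations, conc):
            raise ValueError("replicate curves measured at different concentrations")
    resp = np.mean([c.responses for c in curves], axis=0)
    return BindingCurve(conc, resp, replicate="mean")


def fit_hill(curve: BindingCurve, *, fix_h: bool = False) -> BindingFit:
    """Nonlinear least-squares Hill fit.

    Initialization: bottom/top from the response extremes, Kd from the
    concentration whose response is nearest the half-range, h = 1. Bounds:
    Kd in [min(x)/100, 100*max(x)], h in [0.2, 5]. Non-convergence returns
    the best iterate with ``converged=False`` (warned).
    """
    x, y = curve.concentrations, curve.responses
    if np.allclose(y, y[0]):
        raise ValueError("responses are all equal; nothing to fit")
    bottom0, top0 = float(y.min()), float(y.max())
    half = (top0 + bottom0) / 2
    kd0 = float(x[np.argmin(np.abs(y - half))])
    kd_lo, kd_hi = x.min() / 100, 100 * x.max()
    kd0 = float(np.clip(kd0, kd_lo, kd_hi))
    span = top0 - bottom0

    if fix_h:
        def f(x, kd, top, bottom):
            return hill_response(x, kd, 1.0, top, bottom)
        p0 = [kd0, top0, bottom0]
        bounds = ([kd_lo, bottom0 - 10 * span, bottom0 - 10 * span],
                  [kd_hi, top0 + 10 * span, top0 + 10 * span])
    else:
        def f(x, kd, h, top, bottom):
            return hill_response(x, kd, h, top, bottom)
        p0 = [kd0, 1.0, top0, bottom0]
        bounds = ([kd_lo, 0.2, bottom0 - 10 * span, bottom0 - 10 * span],
                  [kd_hi, 5.0, top0 + 10 * span, top0 + 10 * span])

    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(f, x, y, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError:
        logger.warning("fit_hill: optimizer did not converge; returning the "
                       "initial guess")
        popt = np.asarray(p0, float)
        pcov = np.full((len(p0), len(p0)), np.nan)
        converged = False
    se_kd = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else float("nan")
    if fix_h:
        kd, top, bottom = popt
        h = 1.0
    else:
        kd, h, top, bottom = popt
    return BindingFit(kd=float(kd), hill_h=float(h), top=float(top),
                      bottom=float(bottom), se_kd=se_kd, converged=converged)


def kd_confidence_interval(fit: BindingFit, level: float = 0.95) -> tuple[float, float]:
    """Curvature-based (Wald) interval for Kd."""
    if not np.isfinite(fit.se_kd):
        return (float("nan"), float("nan"))
    z = stats.norm.ppf(0.5 + level / 2)
    return (fit.kd - z * fit.se_kd, fit.kd + z * fit.se_kd)


def ddpcr_concentration(k: int, n: int,
                        v: float = DROPLET_VOLUME_UL) -> DdpcrSample:
    """Poisson-corrected ddPCR concentration with a 95% interval.

    The interval is the exact (Clopper-Pearson) binomial interval on the
    positive fraction k/n propagated through the same -ln(1 - p)/v
    transform; k = 0 gives concentration 0 with a lower bound of 0.
    """
    if n <= 0:
        raise ValueError("total droplet count must be positive")
    if not 0 <= k <= n:
        raise ValueError("positive droplets must lie in [0, total]")
    if k == n:
        raise SaturationError(
            "all droplets positive: concentration exceeds the dynamic range; "
            "dilute the sample and repeat"
        )
    lam = -np.log1p(-k / n)
    lo_p, hi_p = _clopper_pearson(k, n)
    ci = (float(-np.log1p(-lo_p) / v), float(-np.log1p(-hi_p) / v))
    return DdpcrSample(
        positive_droplets=k, total_droplets=n, droplet_volume_ul=v,
        copies_per_ul=float(lam / v), ci95=ci,
    )


def _clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    a = 1 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(a / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - a / 2, k + 1, n - k))
    # cap the upper bound below 1 so the log transform stays finite
    hi = min(hi, 1 - 1e-12)
    return lo, hi
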