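"""Filter-binding quantification and constrained Hill-slope fits.

A filter-binding assay partitions fluorescent RNA between a nitrocellulose
membrane (protein-bound) and a nylon membrane (free); the fraction bound is
retained / (retained + flowthrough) from background-corrected signals.
Binding curves — fraction bound Y against protein concentration X — are fit
with the "specific binding with Hill slope" model

    Y = Bmax · X^h / (K_D^h + X^h)

by nonlinear least squares, with Bmax constrained to 1 by default (the
fraction-bound scale is absolute).  95% confidence intervals come from the
asymptotic covariance of the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import t as student_t

__all__ = ["BindingCurve", "HillFit", "hill", "filter_fraction_bound", "fit_hill"]


def hill(x: np.ndarray, kd: float, h: float, bmax: float = 1.0) -> np.ndarray:
    """Specific binding with Hill slope: Bmax·x^h/(kd^h + x^h)."""
    x = np.asarray(x, dtype=float)
    xh = np.power(x, h)
    return bmax * xh / (kd ** h + xh)


@dataclass
class BindingCurve:
    """Concentration series with measured fraction bound per point."""

    concentrations: np.ndarray      # strictly positive, any concentration unit
    fraction_bound: np.ndarray      # in [0, 1]
    replicate_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.fraction_bound = np.asarray(self.fraction_bound, dtype=float)
        if self.concentrations.shape != self.fraction_bound.shape:
            raise ValueError("concentrations and fraction_bound lengths differ")
        if (self.concentrations <= 0).any():
            raise ValueError("concentrations must be strictly positive")
        if ((self.fraction_bound < 0) | (self.fraction_bound > 1)).any():
            raise ValueError("fraction_bound values must lie in [0, 1]")


@dataclass
class HillFit:
    """Fitted Hill parameters with asymptotic uncertainty."""

    kd: float
    h: float
    bmax: float
    kd_ci95: tuple[float, float]
    h_ci95: tuple[float, float]
    converged: bool
    residual_ss: float
    bmax_constrained: bool
    message: str = ""

    def predict(self, x: np.ndarray) -> np.ndarray:
        return hill(x, self.kd, self.h, self.bmax)

    def as_dict(self) -> dict:
        return {
            "kd": self.kd,
            "h": self.h,
            "bmax": self.bmax,
            "kd_ci95": list(self.kd_ci95),
            "h_ci95": list(self.h_ci95),
            "converged": self.converged,
            "residual_ss": self.residual_ss,
            "bmax_constrained": self.bmax_constrained,
            "message": self.message,
        }


def filter_fraction_bound(signal_retained: float, signal_flowthrough: float) -> float:
    """Fraction bound from background-corrected membrane signals.

    Inputs below zero (over-subtracted background) are clamped to 0 with a
    warning; both-zero input is an error because the fraction is undefined.
    """
    if signal_retained < 0 or signal_flowthrough < 0:
        warnings.warn("negative signal after background correction; clamping to 0")
        signal_retained = max(signal_retained, 0.0)
        signal_flowthrough = max(signal_flowthrough, 0.0)
    total = signal_retained + signal_flowthrough
    if total == 0:
        raise ValueError("total signal is zero; fraction bound undefined")
    return signal_retained / total


def fit_hill(curve: BindingCurve, constrain_bmax: bool = True) -> HillFit:
    """Least-squares fit of the Hill model to a binding curve.

    K_D is initialised at the concentration whose signal is nearest
    half-maximum, h at 1 (and Bmax at the signal maximum when free).
    Non-convergence is reported honestly via ``converged=False`` with the
    optimizer's message, never as a silent estimate.
    """
    x = curve.concentrations
    y = curve.fraction_bound
    if len(np.unique(x)) < 4:
        raise ValueError("need at least 4 distinct concentrations to fit")
    if np.allclose(y, 0):
        raise ValueError("all-zero signal; nothing to fit")

    ymax = y.max()
    kd0 = float(x[np.argmin(np.abs(y - ymax / 2))])
    if constrain_bmax:
        p0, bounds = [kd0, 1.0], ([1e-12, 1e-3], [np.inf, 100.0])
        model = lambda xx, kd, h: hill(xx, kd, h, 1.0)
    else:
        p0, bounds = [kd0, 1.0, max(ymax, 1e-3)], ([1e-12, 1e-3, 1e-12], [np.inf, 100.0, 2.0])
        model = hill

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                model, x, y, p0=p0, bounds=bounds, maxfev=20000, absolute_sigma=False
            )
        converged = bool(np.all(np.isfinite(popt)) and np.all(np.isfinite(np.diag(pcov))))
        message = "" if converged else "non-finite covariance"
    except RuntimeError as exc:    # optimizer failed
        popt = np.asarray(p0, float)
        pcov = np.full((len(p0), len(p0)), np.nan)
        converged, message = False, str(exc)

    kd, h = float(popt[0]), float(popt[1])
    bmax = 1.0 if constrain_bmax else float(popt[2])
    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(len(popt), np.nan)
    # finite-sample critical value (residual degrees of freedom), as
    # standard for nonlinear-regression confidence intervals
    z = float(student_t.ppf(0.975, max(len(x) - len(popt), 1)))
    resid = y - model(x, *popt)
    return HillFit(
        kd=kd,
        h=h,
        bmax=bmax,
        kd_ci95=(kd - z * se[0], kd + z * se[0]),
        h_ci95=(h - z * se[1], h + z * se[1]),
        converged=converged,
        residual_ss=float(resid @ resid),
        bmax_constrained=constrain_bmax,
        message=message,
    )
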