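"""Power-law viscosity-rate relationship and extrapolation.

Fitted viscosities fall with stretch rate (shear thinning, attributed to
the GAG matrix), well described by an allometric law ``eta = a * rate^b``
with ``b < 0``.  The fit is a least-squares straight line in log-log
space (slope = exponent, exp(intercept) = prefactor); an unweighted
nonlinear fit in linear space is available behind a flag but weights the
large slow-rate viscosities very differently and yields a materially
different exponent.

The fitted law extrapolates the viscosities to rates no tensile machine
reaches, in particular the physiological stretch rate of 2.5 s^-1
(15 000 % min^-1), and predicted stress-stretch curves at any rate follow
by inserting the extrapolated viscosities into the uniaxial closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .energy import ElasticParams, ViscousParams
from .estimation import CIRC, RADIAL, StressStrainCurve
from .stress import uniaxial_stress_circumferential, uniaxial_stress_radial

__all__ = [
    "PowerLawFit",
    "fit_power_law",
    "extrapolate_eta",
    "predict_curve",
    "percent_per_min_to_per_s",
]

PHYSIOLOGICAL_RATE = 2.5  # s^-1, in-vivo valve stretch rate


@dataclass(frozen=True)
class PowerLawFit:
    """``eta(rate) = prefactor * rate**exponent`` with its source points."""

    prefactor: float
    exponent: float
    rates: np.ndarray
    etas: np.ndarray
    fit_space: str = "log"

    def __post_init__(self) -> None:
        object.__setattr__(self, "rates", np.asarray(self.rates, dtype=float))
        object.__setattr__(self, "etas", np.asarray(self.etas, dtype=float))

    def eta_at(self, rate: float) -> float:
        return extrapolate_eta(self, rate)


def fit_power_law(points, fit_space: str = "log") -> PowerLawFit:
    """Fit ``eta = a * rate^b`` to ``(rate, eta)`` pairs.

    ``fit_space='log'`` (default) performs ordinary least squares on
    ``(ln rate, ln eta)``; ``'linear'`` performs an unweighted nonlinear
    fit of the allometric function itself.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two (rate, eta) points")
    rates, etas = pts[:, 0], pts[:, 1]
    if np.any(rates <= 0.0) or np.any(etas <= 0.0):
        raise ValueError("rates and viscosities must be positive")

    if fit_space == "log":
        slope, intercept = np.polyfit(np.log(rates), np.log(etas), 1)
        a, b = float(np.exp(intercept)), float(slope)
    elif fit_space == "linear":
        (a, b), _ = curve_fit(
            lambda r, a, b: a * r**b, rates, etas, p0=(float(etas[0]), -0.5)
        )
        a, b = float(a), float(b)
    else:
        raise ValueError("fit_space must be 'log' or 'linear'")
    return PowerLawFit(a, b, rates, etas, fit_space=fit_space)


def extrapolate_eta(fit: PowerLawFit, rate: float) -> float:
    """Evaluate the fitted law at a rate (s^-1); MPa*s."""
    if rate <= 0.0:
        raise ValueError("rate must be positive")
    return float(fit.prefactor * rate**fit.exponent)


def percent_per_min_to_per_s(rate_percent_per_min: float) -> float:
    """Convert a strain rate in % min^-1 to a stretch rate in s^-1."""
    if rate_percent_per_min < 0.0:
        raise ValueError("rate must be non-negative")
    return rate_percent_per_min / 100.0 / 60.0


def predict_curve(
    pe: ElasticParams,
    fits: tuple[PowerLawFit, PowerLawFit],
    rate: float,
    direction: str,
    lambda_grid,
) -> StressStrainCurve:
    """Predicted stress-stretch curve at an arbitrary rate.

    ``fits`` are the (eta1, eta2) power laws; both viscosities are read
    off the fitted lines at ``rate`` and inserted into the uniaxial
    closed form for ``direction``.
    """
    if rate <= 0.0:
        raise ValueError("rate must be positive")
    grid = np.asarray(lambda_grid, dtype=float)
    eta1 = extrapolate_eta(fits[0], rate)
    eta2 = extrapolate_eta(fits[1], rate)
    pv = ViscousParams(eta1, eta2, rate=rate)
    if direction == CIRC:
        stress = uniaxial_stress_circumferential(grid, rate, pe, pv)
    elif direction == RADIAL:
        stress = uniaxial_stress_radial(grid, rate, pe, pv)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    stress = np.atleast_1d(stress)
    return StressStrainCurve(
        direction=direction,
        rate=rate,
        stretch=grid,
        stress=stress,
        specimen="predicted",
        metadata={"eta1": eta1, "eta2": eta2, "source": "power-law extrapolation"},
    )
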