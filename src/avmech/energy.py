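"""Elastic and viscous potentials and their constitutive derivatives.

The elastic strain-energy function combines an exponential isotropic
matrix term with a Holzapfel-type fibre term::

    We = (alpha/2) (exp[beta (I1 - 3)] - 1) + (k1 / (2 k2)) (exp[k2 (I4 - 1)^2] - 1)

with ``alpha`` and ``k1`` stress-like (MPa), ``beta`` and ``k2``
dimensionless, all strictly positive.  The viscous dissipation potential
couples matrix viscosity to the isotropic rate invariant J2 and fibre
kinematics to J5::

    Wv = (1/4) (I1 - 3) (eta1 J2 + eta2 J5)

``eta1`` (matrix) and ``eta2`` (fibre kinematics) carry MPa*s and are
non-negative.  Wv is quadratic in Cdot, hence convex in Cdot and zero at
Cdot = 0, as required thermodynamically of a rate potential.

Collagen fibres buckle rather than support compression, so fibre terms
(those depending on I4, I5 or the fibre-rate invariants) are switched off
whenever the fibre family is shortened (I4 <= 1) or when the caller asks
for the radial-loading convention explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .kinematics import InvariantSet

__all__ = [
    "ElasticParams",
    "ViscousParams",
    "DerivativeCoefficients",
    "elastic_energy",
    "viscous_energy",
    "derivative_coefficients",
]


@dataclass(frozen=True)
class ElasticParams:
    """Elastic material parameters (alpha, k1 in MPa; beta, k2 dimensionless)."""

    alpha: float
    beta: float
    k1: float
    k2: float

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "k1", "k2"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"elastic parameter {name} must be strictly positive")

    def as_dict(self) -> dict[str, float]:
        return {"alpha": self.alpha, "beta": self.beta, "k1": self.k1, "k2": self.k2}


@dataclass(frozen=True)
class ViscousParams:
    """Viscosity parameters at one stretch rate.

    ``eta1`` is the matrix (GAG) viscosity, ``eta2`` the fibre-kinematics
    viscosity, both in MPa*s.  ``rate`` records the stretch rate (s^-1)
    this set belongs to.
    """

    eta1: float
    eta2: float
    rate: float = float("nan")

    def __post_init__(self) -> None:
        if self.eta1 < 0.0 or self.eta2 < 0.0:
            raise ValueError("viscosity parameters must be non-negative")

    def as_dict(self) -> dict[str, float]:
        return {"eta1": self.eta1, "eta2": self.eta2, "rate": self.rate}


# Index constants for the coefficient arrays (0-based).
_WE4, _WE5 = 3, 4
_WV2, _WV4, _WV5, _WV10, _WV11 = 1, 3, 4, 9, 10


@dataclass
class DerivativeCoefficients:
    """Constitutive functions ``(We)_i = dWe/dI_i`` and ``(Wv)_i = dWv/dJ_i``.

    ``we`` has shape (5,), ``wv`` shape (12,).  For the potentials above
    only We1, We4, Wv2 and Wv5 are nonzero.
    """

    we: np.ndarray = field(default_factory=lambda: np.zeros(5))
    wv: np.ndarray = field(default_factory=lambda: np.zeros(12))

    def __post_init__(self) -> None:
        self.we = np.asarray(self.we, dtype=float)
        self.wv = np.asarray(self.wv, dtype=float)
        if self.we.shape != (5,) or self.wv.shape != (12,):
            raise ValueError("coefficient arrays must have shapes (5,) and (12,)")

    def __getattr__(self, name: str):
        if name.startswith("We") and name[2:].isdigit():
            return float(self.we[int(name[2:]) - 1])
        if name.startswith("Wv") and name[2:].isdigit():
            return float(self.wv[int(name[2:]) - 1])
        raise AttributeError(name)


def elastic_energy(p: ElasticParams, I1, I4, fiber_active: bool = True):
    """Elastic strain energy (MPa) at invariants ``(I1, I4)``.

    Accepts scalars or arrays.  ``fiber_active=False`` drops the fibre
    term (radial-loading convention); otherwise the fibre term is zeroed
    pointwise wherever I4 <= 1 (compressed fibres).
    """
    I1 = np.asarray(I1, dtype=float)
    I4 = np.asarray(I4, dtype=float)
    iso = 0.5 * p.alpha * (np.exp(p.beta * (I1 - 3.0)) - 1.0)
    if fiber_active:
        fib = (p.k1 / (2.0 * p.k2)) * (np.exp(p.k2 * (I4 - 1.0) ** 2) - 1.0)
        fib = np.where(I4 > 1.0, fib, 0.0)
    else:
        fib = np.zeros_like(iso)
    out = iso + fib
    return float(out) if out.ndim == 0 else out


def viscous_energy(p: ViscousParams, I1, J2, J5, fiber_active: bool = True):
    """Viscous dissipation potential ``(I1-3)(eta1 J2 + eta2 J5)/4``.

    J2 and J5 are the quadratic rate invariants (both >= 0 for symmetric
    Cdot); the potential vanishes identically at Cdot = 0.
    """
    I1 = np.asarray(I1, dtype=float)
    J2 = np.asarray(J2, dtype=float)
    J5 = np.asarray(J5, dtype=float) if fiber_active else 0.0
    out = 0.25 * (I1 - 3.0) * (p.eta1 * J2 + p.eta2 * J5)
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


def derivative_coefficients(
    pe: ElasticParams,
    pv: ViscousParams | None,
    inv: InvariantSet,
    radial_fiber_off: bool | None = None,
) -> DerivativeCoefficients:
    """Evaluate ``(We)_i`` and ``(Wv)_i`` at a state.

    Fibre switch: with ``radial_fiber_off=None`` (default) fibre terms are
    zeroed automatically when I4 <= 1; ``True`` forces them off (the
    direction-based radial convention); ``False`` keeps them regardless.
    The switched coefficients are We4, We5, Wv4, Wv5, Wv10 and Wv11.
    """
    I1, I4 = inv.I1, inv.I4
    we = np.zeros(5)
    wv = np.zeros(12)

    we[0] = 0.5 * pe.alpha * pe.beta * math.exp(pe.beta * (I1 - 3.0))
    we[_WE4] = pe.k1 * (I4 - 1.0) * math.exp(pe.k2 * (I4 - 1.0) ** 2)

    if pv is not None:
        wv[_WV2] = 0.25 * pv.eta1 * (I1 - 3.0)
        wv[_WV5] = 0.25 * pv.eta2 * (I1 - 3.0)

    fiber_off = radial_fiber_off if radial_fiber_off is not None else (I4 <= 1.0)
    if fiber_off:
        we[[_WE4, _WE5]] = 0.0
        wv[[_WV4, _WV5, _WV10, _WV11]] = 0.0

    return DerivativeCoefficients(we=we, wv=wv)
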