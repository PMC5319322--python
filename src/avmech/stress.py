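"""Stress tensors for the transversely isotropic viscoelastic continuum.

The second Piola-Kirchhoff stress follows from the invariant-based chain
rule ``S = 2 dWe/dC - p C^-1 + 2 dWv/dCdot`` expanded over the seventeen
constitutive coefficients ``(We)_i``, ``(Wv)_i``; the Cauchy stress is the
push-forward ``sigma = F S F^T``.  For an incompressible material the
hydrostatic pressure ``p`` is an indeterminate Lagrange multiplier fixed
by a traction-free boundary condition (``sigma_22 = sigma_33 = 0`` in
uniaxial circumferential loading, ``sigma_33 = 0`` for a thin membrane).

Angular momentum requires the Cauchy tensor to be symmetric.  For this
invariant family that is *not* automatic: it holds iff

    (Wv)_12 = -(Wv)_10 / (lambda1^2 + lambda2^2)

``cauchy_general`` enforces this constraint by default; the raw,
potentially asymmetric assembly is retained behind a flag so the defect
can be measured.

The closed-form uniaxial stresses (MPa, stretch-rate in s^-1)::

    sigma_circ = alpha beta (l^2 - 1/l) exp[beta(l^2 + 2/l - 3)]
               + 2 k1 l^2 (l^2 - 1) exp[k2 (l^2 - 1)^2]
               + ldot (l^2 + 2/l - 3) (eta1 [2 l^3 + l^-3] + 2 eta2 l^3)

    sigma_rad  = alpha beta (l^2 - 1/l) exp[beta(l^2 + 2/l - 3)]
               + eta1 ldot (2 l^3 + l^-3) (l^2 + 2/l - 3)

are algebraically identical to the tensor pipeline with the pressure
eliminated analytically; the radial form carries no fibre contribution
(fibres in compression) and hence no k1, k2 or eta2 dependence.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .energy import DerivativeCoefficients, ElasticParams, ViscousParams
from .kinematics import Deformation, FiberDirection

__all__ = [
    "StressMeasure",
    "StressTensor",
    "second_pk_general",
    "cauchy_general",
    "symmetry_defect",
    "membrane_stresses",
    "uniaxial_stress_circumferential",
    "uniaxial_stress_radial",
    "engineering_to_cauchy",
]


class StressMeasure(str, Enum):
    CAUCHY = "cauchy"
    SECOND_PK = "second_pk"
    ENGINEERING = "engineering"


@dataclass(frozen=True)
class StressTensor:
    """A 3x3 stress tensor (MPa) tagged with its measure and the pressure used."""

    components: np.ndarray
    measure: StressMeasure
    pressure: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "components", np.asarray(self.components, dtype=float)
        )
        if self.components.shape != (3, 3):
            raise ValueError("stress tensor must be 3x3")

    def asymmetry(self) -> float:
        """Max absolute difference between the tensor and its transpose."""
        return float(np.max(np.abs(self.components - self.components.T)))


def second_pk_general(
    state: Deformation,
    fiber: FiberDirection,
    coeffs: DerivativeCoefficients,
    p: float = 0.0,
) -> StressTensor:
    """Second Piola-Kirchhoff tensor, full term-by-term assembly.

    Valid for arbitrary coefficient values, not only the package's chosen
    potentials.  The I3-derivative term is absorbed into the pressure
    (incompressibility).  A nonzero ``(Wv)_3`` with singular ``Cdot``
    raises, since the det(Cdot) derivative is then undefined.
    """
    C, Cd = state.C, state.Cdot
    MM = fiber.MM
    we, wv = coeffs.we, coeffs.wv
    C2 = C @ C
    eye = np.eye(3)

    S = -p * np.linalg.inv(C)
    S = S + 2.0 * we[0] * eye
    S = S + 2.0 * we[1] * (np.trace(C) * eye - C.T)
    S = S + 2.0 * we[3] * MM
    S = S + 2.0 * we[4] * (C @ MM + MM @ C)

    S = S + 2.0 * wv[0] * eye
    S = S + 4.0 * wv[1] * Cd.T
    if wv[2] != 0.0:
        det_cd = np.linalg.det(Cd)
        if abs(det_cd) < 1e-300:
            raise np.linalg.LinAlgError(
                "det(Cdot) term requested ((Wv)_3 != 0) but Cdot is singular"
            )
        S = S + 2.0 * wv[2] * det_cd * np.linalg.inv(Cd).T
    S = S + 2.0 * wv[3] * MM
    S = S + 2.0 * wv[4] * (Cd @ MM + MM @ Cd)
    S = S + 2.0 * wv[5] * C.T
    S = S + 2.0 * wv[6] * ((C @ Cd).T + (Cd @ C).T)
    S = S + 2.0 * wv[7] * C2.T
    S = S + 2.0 * wv[8] * ((C2 @ Cd).T + (Cd @ C2).T)
    S = S + 2.0 * wv[9] * (C @ MM).T
    S = S + 2.0 * wv[10] * (C @ MM @ Cd + Cd @ MM @ C)
    S = S + 2.0 * wv[11] * (C2 @ MM).T

    return StressTensor(S, StressMeasure.SECOND_PK, pressure=p)


def cauchy_general(
    state: Deformation,
    fiber: FiberDirection,
    coeffs: DerivativeCoefficients,
    p: float = 0.0,
    enforce_symmetry_constraint: bool = True,
) -> StressTensor:
    """Cauchy stress ``sigma = F S F^T``.

    With ``enforce_symmetry_constraint`` (the default, and the only mode
    public stress evaluation should use) ``(Wv)_12`` is overwritten by
    ``-(Wv)_10 / (lambda1^2 + lambda2^2)`` so the result is exactly
    symmetric for any coefficients, stretches and fibre angle.  Without
    it, the raw assembly is returned so the angular-momentum defect can
    be measured.
    """
    if enforce_symmetry_constraint:
        wv = coeffs.wv.copy()
        l1sq, l2sq = state.C[0, 0], state.C[1, 1]
        wv[11] = -wv[9] / (l1sq + l2sq)
        coeffs = DerivativeCoefficients(we=coeffs.we.copy(), wv=wv)
    S = second_pk_general(state, fiber, coeffs, p=p)
    F = state.F
    sigma = F @ S.components @ F.T
    return StressTensor(sigma, StressMeasure.CAUCHY, pressure=p)


def symmetry_defect(coeffs: DerivativeCoefficients, lambda1: float, lambda2: float) -> float:
    """Angular-momentum residual ``(Wv)_12 + (Wv)_10 / (l1^2 + l2^2)``.

    Zero iff the constitutive coefficients produce a symmetric Cauchy
    tensor at in-plane stretches ``(lambda1, lambda2)``.
    """
    if lambda1 <= 0.0 or lambda2 <= 0.0:
        raise ValueError("stretches must be positive")
    return float(coeffs.wv[11] + coeffs.wv[9] / (lambda1**2 + lambda2**2))


def membrane_stresses(
    state: Deformation,
    fiber: FiberDirection,
    coeffs: DerivativeCoefficients,
) -> tuple[float, float, float]:
    """Plane-stress components ``(sigma11, sigma22, sigma12)``.

    A valve leaflet is two orders of magnitude thinner than its in-plane
    dimensions, so the through-thickness stress is approximated as zero;
    the pressure is eliminated from ``sigma33 = 0``.  For on-axis fibres
    (phi in {0, pi/2}) ``sigma12 = 0``.
    """
    sig = cauchy_general(state, fiber, coeffs, p=0.0).components
    p = sig[2, 2]
    sig = sig - p * np.eye(3)
    return float(sig[0, 0]), float(sig[1, 1]), float(sig[0, 1])


def _uniaxial_terms(lam, rate, pe: ElasticParams):
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0.0):
        raise ValueError("stretch must be positive")
    i1m3 = lam**2 + 2.0 / lam - 3.0
    iso = pe.alpha * pe.beta * (lam**2 - 1.0 / lam) * np.exp(pe.beta * i1m3)
    return lam, i1m3, iso


def uniaxial_stress_circumferential(
    lam, rate: float, pe: ElasticParams, pv: ViscousParams | None = None
):
    """Cauchy stress (MPa) for uniaxial extension along the fibres."""
    lam, i1m3, iso = _uniaxial_terms(lam, rate, pe)
    fib = (
        2.0 * pe.k1 * lam**2 * (lam**2 - 1.0) * np.exp(pe.k2 * (lam**2 - 1.0) ** 2)
    )
    sigma = iso + fib
    if pv is not None:
        sigma = sigma + rate * i1m3 * (
            pv.eta1 * (2.0 * lam**3 + lam**-3) + 2.0 * pv.eta2 * lam**3
        )
    out = np.asarray(sigma)
    return float(out) if out.ndim == 0 else out


def uniaxial_stress_radial(
    lam, rate: float, pe: ElasticParams, pv: ViscousParams | None = None
):
    """Cauchy stress (MPa) for uniaxial extension transverse to the fibres.

    The compressed fibre family contributes nothing, so the stress is
    independent of k1, k2 and eta2.
    """
    lam, i1m3, iso = _uniaxial_terms(lam, rate, pe)
    sigma = iso
    if pv is not None:
        sigma = sigma + pv.eta1 * rate * (2.0 * lam**3 + lam**-3) * i1m3
    out = np.asarray(sigma)
    return float(out) if out.ndim == 0 else out


def engineering_to_cauchy(P, lam):
    """Convert engineering (nominal) stress to Cauchy stress: sigma = P * lambda."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0.0):
        raise ValueError("stretch must be positive")
    out = np.asarray(P, dtype=float) * lam
    return float(out) if out.ndim == 0 else out
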