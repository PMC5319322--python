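"""Finite-strain kinematics for pure homogeneous deformation states.

The constitutive framework works with the right Cauchy-Green tensor
``C = F^T F`` and its material time derivative ``Cdot``, together with a
single preferred fibre direction ``M`` lying in the 1-2 plane.  Frame
indifference and transverse isotropy let the energy functions depend on
deformation only through seventeen scalar invariants: five invariants of
``C`` (I1..I5, the classical isotropic set plus the fibre pseudo-invariants
``I4 = M.(CM)`` and ``I5 = M.(C^2 M)``) and twelve invariants involving
``Cdot`` (J1..J12).

Factory helpers construct diagonal (pure homogeneous) states, which is all
uniaxial and biaxial tensile protocols produce, but the invariant and
derivative routines accept arbitrary symmetric tensors so the general
stress assembly can be exercised and tested.

Axis convention: axis 1 = circumferential (mean collagen-fibre direction),
axis 2 = radial, axis 3 = through-thickness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FiberDirection",
    "Deformation",
    "InvariantSet",
    "make_uniaxial_state",
    "make_biaxial_state",
    "invariants",
    "invariant_derivatives",
]

_EYE = np.eye(3)


@dataclass(frozen=True)
class FiberDirection:
    """Preferred fibre family direction in the 1-2 plane.

    Parameters
    ----------
    phi : float
        Angle (radians) between the fibre family and axis 1
        (circumferential).  ``phi = 0`` puts the fibres on the
        circumferential axis; ``phi = pi/2`` on the radial axis.
    """

    phi: float = 0.0

    @property
    def M(self) -> np.ndarray:
        """Unit fibre vector ``[cos(phi), sin(phi), 0]``."""
        return np.array([math.cos(self.phi), math.sin(self.phi), 0.0])

    @property
    def MM(self) -> np.ndarray:
        """Structural tensor ``M (x) M``."""
        m = self.M
        return np.outer(m, m)


CIRCUMFERENTIAL_FIBER = FiberDirection(0.0)
RADIAL_FIBER = FiberDirection(math.pi / 2.0)


@dataclass(frozen=True)
class Deformation:
    """A pure homogeneous deformation state with principal stretch rates.

    ``F = diag(l1, l2, l3)``, ``C = diag(li^2)`` and
    ``Cdot_ii = 2 li ldot_i``.  If constructed as incompressible the
    stretches satisfy ``l1 l2 l3 = 1`` and the rates
    ``sum(ldot_i / li) = 0`` (isochoric rate condition).
    """

    lambda1: float
    lambda2: float
    lambda3: float
    lambdadot1: float = 0.0
    lambdadot2: float = 0.0
    lambdadot3: float = 0.0
    incompressible: bool = False

    def __post_init__(self) -> None:
        for lam in (self.lambda1, self.lambda2, self.lambda3):
            if lam <= 0.0:
                raise ValueError(f"principal stretches must be positive, got {lam}")
        if self.incompressible:
            j = self.lambda1 * self.lambda2 * self.lambda3
            if abs(j - 1.0) > 1e-12:
                raise ValueError(f"incompressible state has det F = {j!r} != 1")
            trace_rate = (
                self.lambdadot1 / self.lambda1
                + self.lambdadot2 / self.lambda2
                + self.lambdadot3 / self.lambda3
            )
            if abs(trace_rate) > 1e-12:
                raise ValueError("stretch rates violate the isochoric condition")

    @property
    def stretches(self) -> np.ndarray:
        return np.array([self.lambda1, self.lambda2, self.lambda3])

    @property
    def rates(self) -> np.ndarray:
        return np.array([self.lambdadot1, self.lambdadot2, self.lambdadot3])

    @property
    def F(self) -> np.ndarray:
        return np.diag(self.stretches)

    @property
    def C(self) -> np.ndarray:
        return np.diag(self.stretches**2)

    @property
    def Cdot(self) -> np.ndarray:
        return np.diag(2.0 * self.stretches * self.rates)


def make_uniaxial_state(
    stretch: float, rate: float = 0.0, incompressible_transverse: bool = True
) -> Deformation:
    """Incompressible uniaxial extension along axis 1.

    The transverse stretches follow from incompressibility with transverse
    symmetry, ``l2 = l3 = stretch**-0.5``, and their rates from
    differentiating that relation in time:
    ``ldot_2 = ldot_3 = -0.5 * stretch**-1.5 * rate``.

    The loading axis is axis 1; for radial loading relabel axes at the
    constitutive level (the closed-form stress helpers do this).
    """
    if stretch <= 0.0:
        raise ValueError(f"stretch must be positive, got {stretch}")
    if not incompressible_transverse:
        return Deformation(stretch, 1.0, 1.0, rate, 0.0, 0.0)
    lat = stretch**-0.5
    lat_rate = -0.5 * stretch**-1.5 * rate
    return Deformation(
        stretch, lat, lat, rate, lat_rate, lat_rate, incompressible=True
    )


def make_biaxial_state(
    lambda1: float,
    lambda2: float,
    rate1: float = 0.0,
    rate2: float = 0.0,
) -> Deformation:
    """Incompressible in-plane biaxial state: ``l3 = 1/(l1 l2)``.

    The through-thickness rate follows from differentiating the
    incompressibility constraint:
    ``ldot_3 = -l3 * (ldot_1/l1 + ldot_2/l2)``.
    """
    if lambda1 <= 0.0 or lambda2 <= 0.0:
        raise ValueError("in-plane stretches must be positive")
    lambda3 = 1.0 / (lambda1 * lambda2)
    rate3 = -lambda3 * (rate1 / lambda1 + rate2 / lambda2)
    return Deformation(
        lambda1, lambda2, lambda3, rate1, rate2, rate3, incompressible=True
    )


@dataclass(frozen=True)
class InvariantSet:
    """The seventeen transversely isotropic invariants of ``(C, Cdot, M)``.

    ``I`` holds I1..I5 (functions of C alone), ``J`` holds J1..J12
    (functions involving Cdot).  I-invariants are dimensionless; each J
    carries s^-1 or s^-2 according to its degree in Cdot.
    """

    I: np.ndarray = field(repr=False)
    J: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "I", np.asarray(self.I, dtype=float))
        object.__setattr__(self, "J", np.asarray(self.J, dtype=float))
        if self.I.shape != (5,) or self.J.shape != (12,):
            raise ValueError("InvariantSet needs 5 I-values and 12 J-values")

    def __getattr__(self, name: str) -> float:
        # I1..I5 / J1..J12 accessors
        if len(name) >= 2 and name[0] in "IJ" and name[1:].isdigit():
            idx = int(name[1:]) - 1
            arr = self.I if name[0] == "I" else self.J
            if 0 <= idx < arr.shape[0]:
                return float(arr[idx])
        raise AttributeError(name)


def _tensors(state: Deformation | tuple) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(state, Deformation):
        return state.C, state.Cdot
    c, cdot = state
    return np.asarray(c, dtype=float), np.asarray(cdot, dtype=float)


def invariants(state: Deformation | tuple, fiber: FiberDirection) -> InvariantSet:
    """Evaluate I1..I5 and J1..J12 at a deformation state.

    ``state`` is either a :class:`Deformation` or a ``(C, Cdot)`` pair of
    3x3 arrays (any symmetric tensors are accepted).
    """
    C, Cd = _tensors(state)
    m = fiber.M
    C2 = C @ C
    Cd2 = Cd @ Cd
    I = np.array(
        [
            np.trace(C),
            0.5 * (np.trace(C) ** 2 - np.trace(C2)),
            np.linalg.det(C),
            m @ C @ m,
            m @ C2 @ m,
        ]
    )
    J = np.array(
        [
            np.trace(Cd),
            np.trace(Cd2),
            np.linalg.det(Cd),
            m @ Cd @ m,
            m @ Cd2 @ m,
            np.trace(C @ Cd),
            np.trace(C @ Cd2),
            np.trace(C2 @ Cd),
            np.trace(C2 @ Cd2),
            m @ C @ Cd @ m,
            m @ C @ Cd2 @ m,
            m @ C2 @ Cd @ m,
        ]
    )
    return InvariantSet(I=I, J=J)


def invariant_derivatives(
    state: Deformation | tuple, fiber: FiberDirection
) -> tuple[list[np.ndarray], list[np.ndarray | None]]:
    """Derivative tensors ``dI_i/dC`` (5) and ``dJ_i/dCdot`` (12).

    Each tensor is the unconstrained matrix-calculus gradient, i.e. the one
    recovered by perturbing individual tensor entries with finite
    differences.  ``dJ3/dCdot`` requires a nonsingular ``Cdot``; when
    singular it is returned as ``None`` (undefined and unused whenever the
    corresponding constitutive coefficient vanishes, as it does for a rate
    potential without a det(Cdot) term).
    """
    C, Cd = _tensors(state)
    MM = fiber.MM
    C2 = C @ C

    dI = [
        _EYE.copy(),
        np.trace(C) * _EYE - C.T,
        _cofactor(C),  # det(C) C^-T, valid also for singular C
        MM.copy(),
        C @ MM + MM @ C,
    ]

    det_cd = np.linalg.det(Cd)
    if abs(det_cd) > 1e-300:
        dJ3 = det_cd * np.linalg.inv(Cd).T
    else:
        dJ3 = None

    dJ: list[np.ndarray | None] = [
        _EYE.copy(),
        2.0 * Cd.T,
        dJ3,
        MM.copy(),
        Cd @ MM + MM @ Cd,
        C.T,
        (C @ Cd).T + (Cd @ C).T,
        C2.T,
        (C2 @ Cd).T + (Cd @ C2).T,
        C @ MM,
        C @ MM @ Cd + Cd @ C @ MM,
        C2 @ MM,
    ]
    return dI, dJ


def _cofactor(A: np.ndarray) -> np.ndarray:
    """Cofactor matrix (gradient of the determinant), safe for singular A."""
    cof = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            minor = np.delete(np.delete(A, i, axis=0), j, axis=1)
            cof[i, j] = (-1) ** (i + j) * np.linalg.det(minor)
    return cof
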