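"""Strict local convexity checks of the energy function.

Material stability and well-posedness require the Hessian of the energy
``W`` with respect to the in-plane principal stretches,

    H = [[d2W/dl1^2,    d2W/dl1 dl2],
         [d2W/dl2 dl1,  d2W/dl2^2 ]],

to be positive definite over the working stretch domain, with the
through-thickness stretch eliminated by incompressibility
(``l3 = 1/(l1 l2)``).  Four redundant conditions are evaluated at every
grid point: positive diagonal entries, positive determinant, and positive
eigenvalues (mutually consistent for a symmetric 2x2 matrix; all four are
computed and reported independently).

For the elastic energy an analytic Hessian is available.  For the total
energy ``W = We + Wv`` the in-plane stretch rates are frozen at supplied
values (the through-thickness rate follows from the isochoric condition)
and the Hessian is computed by central finite differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .energy import ElasticParams, ViscousParams
from .kinematics import FiberDirection

__all__ = [
    "ConvexityReport",
    "total_energy",
    "hessian",
    "check_convexity",
    "sample_energy_surface",
]

# Relative tolerance absorbing floating-point noise at the undeformed point,
# where several Hessian contributions vanish identically.
_EIG_TOL = 1e-10


def total_energy(
    pe: ElasticParams,
    pv: ViscousParams | None,
    lambda1,
    lambda2,
    rates: tuple[float, float] | None = None,
    fiber: FiberDirection = FiberDirection(0.0),
    fiber_active: bool = True,
):
    """Energy ``W = We (+ Wv)`` at in-plane stretches, vectorized.

    Incompressibility fixes ``l3 = 1/(l1 l2)``; if ``rates = (ld1, ld2)``
    is given the through-thickness rate is
    ``ld3 = -l3 (ld1/l1 + ld2/l2)`` and the viscous potential is added.
    The fibre contribution is dropped pointwise where I4 <= 1.
    """
    l1 = np.asarray(lambda1, dtype=float)
    l2 = np.asarray(lambda2, dtype=float)
    if np.any(l1 <= 0.0) or np.any(l2 <= 0.0):
        raise ValueError("stretches must be positive")
    l3 = 1.0 / (l1 * l2)
    c2, s2 = math.cos(fiber.phi) ** 2, math.sin(fiber.phi) ** 2
    I1 = l1**2 + l2**2 + l3**2
    I4 = l1**2 * c2 + l2**2 * s2

    w = 0.5 * pe.alpha * (np.exp(pe.beta * (I1 - 3.0)) - 1.0)
    if fiber_active:
        # direction convention: the fibre family is either part of the
        # audited energy surface or not.  No pointwise I4-switch here --
        # it would make W discontinuous across I4 = 1 and wreck the
        # Hessian at the undeformed edge of the domain.
        w = w + (pe.k1 / (2.0 * pe.k2)) * (np.exp(pe.k2 * (I4 - 1.0) ** 2) - 1.0)

    if pv is not None and rates is not None:
        ld1, ld2 = rates
        ld3 = -l3 * (ld1 / l1 + ld2 / l2)
        cd1, cd2, cd3 = 2.0 * l1 * ld1, 2.0 * l2 * ld2, 2.0 * l3 * ld3
        J2 = cd1**2 + cd2**2 + cd3**2
        J5 = (cd1**2 * c2 + cd2**2 * s2) if fiber_active else 0.0
        w = w + 0.25 * (I1 - 3.0) * (pv.eta1 * J2 + pv.eta2 * J5)

    out = np.asarray(w)
    return float(out) if out.ndim == 0 else out


def _elastic_hessian_analytic(pe, l1, l2, fiber, fiber_active):
    l1 = np.asarray(l1, dtype=float)
    l2 = np.asarray(l2, dtype=float)
    c2, s2 = math.cos(fiber.phi) ** 2, math.sin(fiber.phi) ** 2
    I1 = l1**2 + l2**2 + (l1 * l2) ** -2
    I4 = l1**2 * c2 + l2**2 * s2

    dI1_1 = 2.0 * l1 - 2.0 * l1**-3 * l2**-2
    dI1_2 = 2.0 * l2 - 2.0 * l2**-3 * l1**-2
    d2I1_11 = 2.0 + 6.0 * l1**-4 * l2**-2
    d2I1_22 = 2.0 + 6.0 * l2**-4 * l1**-2
    d2I1_12 = 4.0 * l1**-3 * l2**-3
    dI4_1, dI4_2 = 2.0 * l1 * c2, 2.0 * l2 * s2
    d2I4_11, d2I4_22 = 2.0 * c2, 2.0 * s2

    e_iso = np.exp(pe.beta * (I1 - 3.0))
    we1 = 0.5 * pe.alpha * pe.beta * e_iso
    we11 = 0.5 * pe.alpha * pe.beta**2 * e_iso

    q = (I4 - 1.0) ** 2
    e_fib = np.exp(pe.k2 * q)
    we4 = pe.k1 * (I4 - 1.0) * e_fib if fiber_active else np.zeros_like(I4)
    we44 = pe.k1 * (1.0 + 2.0 * pe.k2 * q) * e_fib if fiber_active else np.zeros_like(I4)

    h11 = we11 * dI1_1**2 + we1 * d2I1_11 + we44 * dI4_1**2 + we4 * d2I4_11
    h22 = we11 * dI1_2**2 + we1 * d2I1_22 + we44 * dI4_2**2 + we4 * d2I4_22
    h12 = we11 * dI1_1 * dI1_2 + we1 * d2I1_12 + we44 * dI4_1 * dI4_2
    return h11, h22, h12


def _hessian_fd(pe, pv, l1, l2, rates, fiber, fiber_active, h=1e-4):
    def w(a, b):
        return total_energy(pe, pv, a, b, rates=rates, fiber=fiber,
                            fiber_active=fiber_active)

    w0 = w(l1, l2)
    h11 = (w(l1 + h, l2) - 2.0 * w0 + w(l1 - h, l2)) / h**2
    h22 = (w(l1, l2 + h) - 2.0 * w0 + w(l1, l2 - h)) / h**2
    h12 = (
        w(l1 + h, l2 + h) - w(l1 + h, l2 - h) - w(l1 - h, l2 + h) + w(l1 - h, l2 - h)
    ) / (4.0 * h**2)
    return h11, h22, h12


def hessian(
    pe: ElasticParams,
    pv: ViscousParams | None,
    lambda1: float,
    lambda2: float,
    rates: tuple[float, float] | None = None,
    fiber: FiberDirection = FiberDirection(0.0),
    fiber_active: bool = True,
    method: str = "auto",
) -> np.ndarray:
    """Symmetric 2x2 Hessian of W in the principal stretches.

    ``method='auto'`` uses the analytic elastic Hessian when no viscous
    parameters are supplied and finite differences otherwise;
    ``'analytic'`` / ``'fd'`` force a path (analytic requires ``pv=None``).
    """
    if lambda1 <= 0.0 or lambda2 <= 0.0:
        raise ValueError("stretches must be positive")
    use_analytic = (method == "analytic") or (method == "auto" and pv is None)
    if use_analytic:
        if pv is not None:
            raise ValueError("analytic Hessian is implemented for the elastic energy only")
        h11, h22, h12 = _elastic_hessian_analytic(pe, lambda1, lambda2, fiber, fiber_active)
    else:
        h11, h22, h12 = _hessian_fd(pe, pv, lambda1, lambda2, rates, fiber, fiber_active)
    return np.array([[float(h11), float(h12)], [float(h12), float(h22)]])


@dataclass
class ConvexityReport:
    """Grid-wise convexity audit of the energy function.

    ``table`` holds one row per grid point: stretches, Green-Lagrange
    strains ``E11 = (l1^2-1)/2`` and ``E22``, Hessian entries,
    determinant, eigenvalues and the four individual checks plus their
    conjunction (``ok``).  ``verdict`` is True iff every point passes.
    """

    table: pd.DataFrame
    verdict: bool
    first_violation: tuple[float, float] | None

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.verdict


def check_convexity(
    pe: ElasticParams,
    pv: ViscousParams | None = None,
    domain: tuple[tuple[float, float], tuple[float, float]] = ((1.0, 1.46), (1.0, 1.46)),
    n_grid: int = 51,
    rates: tuple[float, float] | None = None,
    fiber: FiberDirection = FiberDirection(0.0),
    fiber_active: bool = True,
) -> ConvexityReport:
    """Evaluate the four positive-definiteness conditions on a stretch grid.

    Failure is a report outcome (``verdict=False`` plus the first failing
    point), never an exception.
    """
    (a1, b1), (a2, b2) = domain
    if a1 <= 0.0 or a2 <= 0.0:
        raise ValueError("stretch domain must be positive")
    g1 = np.linspace(a1, b1, n_grid)
    g2 = np.linspace(a2, b2, n_grid)
    L1, L2 = np.meshgrid(g1, g2, indexing="ij")

    if pv is None:
        h11, h22, h12 = _elastic_hessian_analytic(pe, L1, L2, fiber, fiber_active)
    else:
        h11, h22, h12 = _hessian_fd(pe, pv, L1, L2, rates, fiber, fiber_active)

    det = h11 * h22 - h12**2
    mean = 0.5 * (h11 + h22)
    rad = np.sqrt((0.5 * (h11 - h22)) ** 2 + h12**2)
    eig_min, eig_max = mean - rad, mean + rad

    scale = np.abs(h11) + np.abs(h22)
    tol = _EIG_TOL * np.maximum(scale, 1.0)
    checks = {
        "d2w_dl1_pos": h11 > 0.0,
        "d2w_dl2_pos": h22 > 0.0,
        "det_pos": det > 0.0,
        "eigs_pos": (eig_min > -tol) & (eig_max > -tol),
    }
    ok = checks["d2w_dl1_pos"] & checks["d2w_dl2_pos"] & checks["det_pos"] & checks["eigs_pos"]

    table = pd.DataFrame(
        {
            "lambda1": L1.ravel(),
            "lambda2": L2.ravel(),
            "E11": (L1.ravel() ** 2 - 1.0) / 2.0,
            "E22": (L2.ravel() ** 2 - 1.0) / 2.0,
            "h11": np.ravel(h11),
            "h12": np.ravel(h12),
            "h22": np.ravel(h22),
            "det": det.ravel(),
            "eig_min": eig_min.ravel(),
            "eig_max": eig_max.ravel(),
            **{k: v.ravel() for k, v in checks.items()},
            "ok": ok.ravel(),
        }
    )
    verdict = bool(ok.all())
    first = None
    if not verdict:
        bad = table.loc[~table["ok"]].iloc[0]
        first = (float(bad["lambda1"]), float(bad["lambda2"]))
    return ConvexityReport(table=table, verdict=verdict, first_violation=first)


def sample_energy_surface(
    pe: ElasticParams,
    pv: ViscousParams | None = None,
    domain: tuple[tuple[float, float], tuple[float, float]] = ((1.0, 1.46), (1.0, 1.46)),
    n_grid: int = 51,
    rates: tuple[float, float] | None = None,
    fiber: FiberDirection = FiberDirection(0.0),
    fiber_active: bool = True,
) -> pd.DataFrame:
    """Tabulate W over a stretch grid for contour plotting.

    Returns columns ``lambda1, lambda2, E11, E22, W``; the Green-Lagrange
    coordinates are exact transforms of the stretch grid, so the same
    table serves contours in either plane.
    """
    (a1, b1), (a2, b2) = domain
    g1 = np.linspace(a1, b1, n_grid)
    g2 = np.linspace(a2, b2, n_grid)
    L1, L2 = np.meshgrid(g1, g2, indexing="ij")
    W = total_energy(pe, pv, L1, L2, rates=rates, fiber=fiber, fiber_active=fiber_active)
    return pd.DataFrame(
        {
            "lambda1": L1.ravel(),
            "lambda2": L2.ravel(),
            "E11": (L1.ravel() ** 2 - 1.0) / 2.0,
            "E22": (L2.ravel() ** 2 - 1.0) / 2.0,
            "W": np.ravel(W),
        }
    )
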