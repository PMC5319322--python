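"""Two-phase parameter estimation from multi-rate stress-stretch curves.

Phase 1 (elastic): the slowest-rate curves are taken as the elastic
baseline (slow enough for viscous relaxation to complete during the ramp)
and the purely elastic stress terms are fitted jointly to the
circumferential and radial curves.  ``alpha`` and ``beta`` describe the
isotropic matrix and are shared between directions; ``k1`` and ``k2``
(fibre stiffening) are informed by the circumferential curve only, since
the radial response carries no fibre contribution.

Phase 2 (viscous): with the elastic parameters frozen, the viscosities
``(eta1, eta2)`` are fitted per rate to the curve pair at that rate.
``eta1`` (matrix) is shared across directions; ``eta2`` (fibre
kinematics) is identified from the circumferential curve alone.

Both phases minimize stacked squared residuals with the
Levenberg-Marquardt algorithm, parameterized in log-space so positivity
is built in, with a small number of jittered, seeded restarts.  A
convexity audit of the resulting energy function is recorded with every
fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .convexity import check_convexity
from .energy import ElasticParams, ViscousParams
from .kinematics import FiberDirection
from .stress import uniaxial_stress_circumferential, uniaxial_stress_radial

__all__ = [
    "CIRC",
    "RADIAL",
    "StressStrainCurve",
    "FitConfig",
    "FitResult",
    "TwoPhaseResult",
    "elastic_baseline_rate",
    "fit_elastic",
    "fit_viscous",
    "fit_two_phase",
    "r_squared",
]

CIRC = "circumferential"
RADIAL = "radial"


@dataclass(frozen=True)
class StressStrainCurve:
    """One direction x one rate series of (stretch, Cauchy stress) samples."""

    direction: str
    rate: float
    stretch: np.ndarray
    stress: np.ndarray
    specimen: str = "1"
    stress_measure: str = "cauchy"
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "stretch", np.asarray(self.stretch, dtype=float))
        object.__setattr__(self, "stress", np.asarray(self.stress, dtype=float))
        if self.direction not in (CIRC, RADIAL):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.rate <= 0.0:
            raise ValueError("stretch rate must be positive")
        if self.stretch.shape != self.stress.shape or self.stretch.ndim != 1:
            raise ValueError("stretch and stress must be matching 1-d arrays")
        if np.any(np.diff(self.stretch) <= 0.0):
            raise ValueError("stretch must be strictly increasing")
        if self.stretch[0] < 1.0 - 1e-9:
            raise ValueError("stretch values must be >= 1")

    def __len__(self) -> int:
        return int(self.stretch.shape[0])

    def key(self) -> tuple[str, float, str]:
        return (self.direction, self.rate, self.specimen)


def elastic_baseline_rate(tau_slow: float, lambda_fail: float) -> float:
    """Stretch rate slow enough for viscous relaxation to fade during a ramp.

    99% of stress relaxation fades within five slow characteristic times,
    so ramping linearly from 1 to the failure stretch over ``5 tau``
    gives ``(lambda_fail - 1) / (5 tau)`` in s^-1.
    """
    if tau_slow <= 0.0:
        raise ValueError("relaxation time must be positive")
    if lambda_fail <= 1.0:
        raise ValueError("failure stretch must exceed 1")
    return (lambda_fail - 1.0) / (5.0 * tau_slow)


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings shared by both fitting phases.

    ``n_starts`` Levenberg-Marquardt runs are launched from the canonical
    initial guess plus log-normal jitter (scale ``jitter_scale``) and the
    lowest-SSE solution is kept.  ``weighting='equal'`` uses raw
    per-point residuals; ``'variance'`` scales each curve's residuals by
    the inverse standard deviation of its stresses.
    """

    n_starts: int = 5
    seed: int = 0
    jitter_scale: float = 0.5
    weighting: str = "equal"
    max_nfev: int = 2000

    def __post_init__(self) -> None:
        if self.weighting not in ("equal", "variance"):
            raise ValueError("weighting must be 'equal' or 'variance'")
        if self.n_starts < 1:
            raise ValueError("need at least one start")


@dataclass
class FitResult:
    """Outcome of one fitting phase."""

    elastic: ElasticParams | None = None
    viscous: ViscousParams | None = None
    r2: dict[tuple[str, float, str], float] = field(default_factory=dict)
    convexity_ok: bool | None = None
    residual_norm: float = math.nan
    n_evaluations: int = 0
    success: bool = False


@dataclass
class TwoPhaseResult:
    """Full pipeline outcome: one elastic fit plus one viscous fit per rate."""

    elastic: FitResult
    viscous: dict[float, FitResult]


def _curve_weights(curves: list[StressStrainCurve], weighting: str) -> list[float]:
    if weighting == "variance":
        return [1.0 / max(float(np.std(c.stress)), 1e-12) for c in curves]
    return [1.0 for c in curves]


def _model_stress(curve: StressStrainCurve, pe: ElasticParams,
                  pv: ViscousParams | None) -> np.ndarray:
    # The protocol is a constant-rate ramp, so the curve's nominal rate is
    # used at every sample.
    if curve.direction == CIRC:
        return uniaxial_stress_circumferential(curve.stretch, curve.rate, pe, pv)
    return uniaxial_stress_radial(curve.stretch, curve.rate, pe, pv)


def _multistart_lm(residual_fn, theta0: np.ndarray, cfg: FitConfig):
    def guarded(theta: np.ndarray) -> np.ndarray:
        # jittered starts can wander into overflow territory; keep the
        # residual finite so LM backtracks instead of aborting
        with np.errstate(over="ignore", invalid="ignore"):
            res = residual_fn(theta)
        return np.nan_to_num(res, nan=1e8, posinf=1e8, neginf=-1e8)

    rng = np.random.default_rng(cfg.seed)
    best = None
    for i in range(cfg.n_starts):
        start = theta0 if i == 0 else theta0 + rng.normal(0.0, cfg.jitter_scale, theta0.size)
        try:
            sol = least_squares(guarded, start, method="lm", max_nfev=cfg.max_nfev)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("Levenberg-Marquardt failed to converge from any start")
    return best


def fit_elastic(
    circ_elastic: StressStrainCurve,
    rad_elastic: StressStrainCurve,
    config: FitConfig | None = None,
) -> FitResult:
    """Phase 1: (alpha, beta, k1, k2) from the elastic-baseline curve pair.

    Viscous terms are excluded from the model; alpha and beta are shared
    between directions by construction of the stacked residual.
    """
    cfg = config or FitConfig()
    if circ_elastic.direction != CIRC or rad_elastic.direction != RADIAL:
        raise ValueError("expected one circumferential and one radial curve, in that order")
    curves = [circ_elastic, rad_elastic]
    weights = _curve_weights(curves, cfg.weighting)

    def residuals(theta: np.ndarray) -> np.ndarray:
        alpha, beta, k1, k2 = np.exp(theta)
        pe = ElasticParams(alpha, beta, k1, k2)
        res = [
            w * (_model_stress(c, pe, None) - c.stress)
            for c, w in zip(curves, weights)
        ]
        return np.concatenate(res)

    theta0 = np.log([0.01, 1.0, 0.1, 0.1])
    sol = _multistart_lm(residuals, theta0, cfg)
    pe = ElasticParams(*np.exp(sol.x))

    lam_max = max(float(c.stretch.max()) for c in curves)
    report = check_convexity(pe, domain=((1.0, lam_max), (1.0, lam_max)))
    r2 = {c.key(): r_squared_arrays(_model_stress(c, pe, None), c.stress) for c in curves}
    return FitResult(
        elastic=pe,
        r2=r2,
        convexity_ok=report.verdict,
        residual_norm=float(np.sqrt(2.0 * sol.cost)),
        n_evaluations=int(sol.nfev),
        success=bool(sol.success),
    )


def fit_viscous(
    curves_at_rate: list[StressStrainCurve],
    elastic: ElasticParams,
    config: FitConfig | None = None,
) -> FitResult:
    """Phase 2: (eta1, eta2) at one rate with the elastic parameters frozen.

    ``eta1`` is shared across the supplied curves; ``eta2`` enters the
    circumferential model only, so with a radial-only input it simply
    stays at its initial value (zero gradient).
    """
    cfg = config or FitConfig()
    rates = {c.rate for c in curves_at_rate}
    if len(curves_at_rate) == 0 or len(rates) != 1:
        raise ValueError("fit_viscous needs one or more curves sharing a single rate")
    rate = rates.pop()
    weights = _curve_weights(curves_at_rate, cfg.weighting)

    def residuals(theta: np.ndarray) -> np.ndarray:
        eta1, eta2 = np.exp(theta)
        pv = ViscousParams(eta1, eta2, rate=rate)
        res = [
            w * (_model_stress(c, elastic, pv) - c.stress)
            for c, w in zip(curves_at_rate, weights)
        ]
        return np.concatenate(res)

    theta0 = np.log([1.0, 1.0])
    sol = _multistart_lm(residuals, theta0, cfg)
    pv = ViscousParams(*np.exp(sol.x), rate=rate)

    lam_max = max(float(c.stretch.max()) for c in curves_at_rate)
    report = check_convexity(
        elastic, pv, domain=((1.0, lam_max), (1.0, lam_max)), rates=(rate, rate)
    )
    r2 = {
        c.key(): r_squared_arrays(_model_stress(c, elastic, pv), c.stress)
        for c in curves_at_rate
    }
    return FitResult(
        viscous=pv,
        elastic=elastic,
        r2=r2,
        convexity_ok=report.verdict,
        residual_norm=float(np.sqrt(2.0 * sol.cost)),
        n_evaluations=int(sol.nfev),
        success=bool(sol.success),
    )


def fit_two_phase(
    curves: list[StressStrainCurve],
    config: FitConfig | None = None,
    elastic_rate: float | None = None,
) -> TwoPhaseResult:
    """Run the full estimation pipeline on a multi-rate curve collection.

    The elastic phase uses the curve pair at ``elastic_rate`` (default:
    the slowest rate present); every other rate gets a viscous fit.  When
    several specimens exist per (direction, rate) the first is used.
    """
    cfg = config or FitConfig()
    all_rates = sorted({c.rate for c in curves})
    e_rate = elastic_rate if elastic_rate is not None else all_rates[0]

    def pick(direction: str, rate: float) -> StressStrainCurve | None:
        found = [c for c in curves if c.direction == direction and c.rate == rate]
        return min(found, key=lambda c: c.specimen) if found else None

    circ_e, rad_e = pick(CIRC, e_rate), pick(RADIAL, e_rate)
    if circ_e is None or rad_e is None:
        raise ValueError(f"missing elastic-baseline curve pair at rate {e_rate}")
    elastic_fit = fit_elastic(circ_e, rad_e, cfg)

    viscous: dict[float, FitResult] = {}
    for rate in all_rates:
        if rate == e_rate:
            continue
        pair = [c for c in (pick(CIRC, rate), pick(RADIAL, rate)) if c is not None]
        viscous[rate] = fit_viscous(pair, elastic_fit.elastic, cfg)
    return TwoPhaseResult(elastic=elastic_fit, viscous=viscous)


def r_squared_arrays(model: np.ndarray, data: np.ndarray) -> float:
    """Coefficient of determination ``1 - SS_res / SS_tot``."""
    data = np.asarray(data, dtype=float)
    model = np.asarray(model, dtype=float)
    ss_tot = float(np.sum((data - data.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined for constant data")
    return 1.0 - float(np.sum((model - data) ** 2)) / ss_tot


def r_squared(model_curve: StressStrainCurve, data_curve: StressStrainCurve) -> float:
    """R^2 of a model curve against data, interpolating the model onto the
    data's stretch grid."""
    model = np.interp(data_curve.stretch, model_curve.stretch, model_curve.stress)
    return r_squared_arrays(model, data_curve.stress)
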