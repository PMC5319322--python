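"""Stress assembly, symmetry constraint, and uniaxial closed forms."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from avmech import (
    DerivativeCoefficients,
    ElasticParams,
    ViscousParams,
    cauchy_general,
    derivative_coefficients,
    engineering_to_cauchy,
    invariants,
    make_biaxial_state,
    make_uniaxial_state,
    membrane_stresses,
    second_pk_general,
    symmetry_defect,
    uniaxial_stress_circumferential,
    uniaxial_stress_radial,
)
from avmech.kinematics import Deformation, FiberDirection


def random_coeffs(rng) -> DerivativeCoefficients:
    wv = rng.uniform(-1.0, 1.0, 12)
    wv[2] = 0.0  # det(Cdot) term needs a nonsingular rate tensor
    return DerivativeCoefficients(we=rng.uniform(-1.0, 1.0, 5), wv=wv)


def random_state(rng) -> Deformation:
    lams = rng.uniform(0.8, 1.6, 3)
    rates = rng.uniform(-0.5, 0.5, 3)
    return Deformation(*lams, *rates)


def eq_215_components(state, phi, co):
    """Independent expansion of the raw diagonal-state Cauchy components."""
    l1, l2, l3 = state.stretches
    d1, d2, d3 = state.rates
    c2, s2 = math.cos(phi) ** 2, math.sin(phi) ** 2
    s2phi = math.sin(2 * phi)
    we, wv = co.we, co.wv
    s11 = (
        2 * l1**2 * we[0] + 2 * l1**2 * (l2**2 + l3**2) * we[1]
        + 2 * l1**2 * we[3] * c2 + 4 * l1**4 * we[4] * c2
        + 2 * l1**2 * wv[0] + 8 * l1**3 * d1 * wv[1]
        + 8 * l1**2 * l2 * l3 * d2 * d3 * wv[2]
        + 2 * l1**2 * wv[3] * c2 + 8 * l1**3 * d1 * wv[4] * c2
        + 2 * l1**4 * wv[5] + 8 * l1**5 * d1 * wv[6]
        + 2 * l1**6 * wv[7] + 8 * l1**7 * d1 * wv[8]
        + 2 * l1**4 * wv[9] * c2 + 8 * l1**5 * d1 * wv[10] * c2
        + 2 * l1**6 * wv[11] * c2
    )
    s22 = (
        2 * l2**2 * we[0] + 2 * l2**2 * (l1**2 + l3**2) * we[1]
        + 2 * l2**2 * we[3] * s2 + 4 * l2**4 * we[4] * s2
        + 2 * l2**2 * wv[0] + 8 * l2**3 * d2 * wv[1]
        + 8 * l1 * l2**2 * l3 * d1 * d3 * wv[2]
        + 2 * l2**2 * wv[3] * s2 + 8 * l2**3 * d2 * wv[4] * s2
        + 2 * l2**4 * wv[5] + 8 * l2**5 * d2 * wv[6]
        + 2 * l2**6 * wv[7] + 8 * l2**7 * d2 * wv[8]
        + 2 * l2**4 * wv[9] * s2 + 8 * l2**5 * d2 * wv[10] * s2
        + 2 * l2**6 * wv[11] * s2
    )
    s33 = (
        2 * l3**2 * we[0] + 2 * l3**2 * (l1**2 + l2**2) * we[1]
        + 2 * l3**2 * wv[0] + 8 * l3**3 * d3 * wv[1]
        + 8 * l1 * l2 * l3**2 * d1 * d2 * wv[2]
        + 2 * l3**4 * wv[5] + 8 * l3**5 * d3 * wv[6]
        + 2 * l3**6 * wv[7] + 8 * l3**7 * d3 * wv[8]
    )
    s12 = (
        l1 * l2 * we[3] * s2phi + l1 * l2 * (l1**2 + l2**2) * we[4] * s2phi
        + l1 * l2 * wv[3] * s2phi
        + 2 * l1 * l2 * (l1 * d1 + l2 * d2) * wv[4] * s2phi
        + l1 * l2**3 * wv[9] * s2phi
        + 2 * l1**2 * l2**2 * (l1 * d2 + l2 * d1) * wv[10] * s2phi
        + l1 * l2**5 * wv[11] * s2phi
    )
    s21 = (
        l1 * l2 * we[3] * s2phi + l1 * l2 * (l1**2 + l2**2) * we[4] * s2phi
        + l1 * l2 * wv[3] * s2phi
        + 2 * l1 * l2 * (l1 * d1 + l2 * d2) * wv[4] * s2phi
        + l1**3 * l2 * wv[9] * s2phi
        + 2 * l1**2 * l2**2 * (l1 * d2 + l2 * d1) * wv[10] * s2phi
        + l1**5 * l2 * wv[11] * s2phi
    )
    return s11, s22, s33, s12, s21


class TestGeneralAssembly:
    def test_zero_coefficients_zero_pressure(self, rng):
        s = random_state(rng)
        S = second_pk_general(s, FiberDirection(0.3), DerivativeCoefficients())
        np.testing.assert_allclose(S.components, 0.0)

    def test_hydrostatic_cancellation_at_identity(self):
        s = make_uniaxial_state(1.0, 0.0)
        co = DerivativeCoefficients(we=[0.7, 0, 0, 0, 0], wv=np.zeros(12))
        S = second_pk_general(s, FiberDirection(0.0), co, p=2 * 0.7)
        np.testing.assert_allclose(S.components, 0.0, atol=1e-15)

    def test_matches_component_expansion(self, rng):
        """Tensor assembly reproduces an independent term-by-term hand
        expansion of the raw diagonal-state components."""
        for _ in range(10):
            s = random_state(rng)
            phi = rng.uniform(0.0, math.pi)
            co = random_coeffs(rng)
            sig = cauchy_general(
                s, FiberDirection(phi), co, p=0.0, enforce_symmetry_constraint=False
            ).components
            s11, s22, s33, s12, s21 = eq_215_components(s, phi, co)
            assert sig[0, 0] == pytest.approx(s11, rel=1e-10, abs=1e-12)
            assert sig[1, 1] == pytest.approx(s22, rel=1e-10, abs=1e-12)
            assert sig[2, 2] == pytest.approx(s33, rel=1e-10, abs=1e-12)
            assert sig[0, 1] == pytest.approx(s12, rel=1e-10, abs=1e-12)
            assert sig[1, 0] == pytest.approx(s21, rel=1e-10, abs=1e-12)
            assert sig[0, 2] == pytest.approx(0.0, abs=1e-12)
            assert sig[1, 2] == pytest.approx(0.0, abs=1e-12)

    def test_det_rate_term_with_singular_rate_raises(self):
        s = make_uniaxial_state(1.2, 0.0)  # Cdot = 0
        co = DerivativeCoefficients(wv=np.eye(12)[2] * 0.5)
        with pytest.raises(np.linalg.LinAlgError):
            second_pk_general(s, FiberDirection(0.0), co)


class TestSymmetryConstraint:
    @given(
        phi=st.floats(0.05, math.pi / 2 - 0.05),
        wv10=st.floats(-2.0, 2.0),
        l1=st.floats(0.9, 1.6),
        l2=st.floats(0.9, 1.6),
    )
    def test_constrained_tensor_symmetric(self, phi, wv10, l1, l2):
        rng = np.random.default_rng(7)
        s = Deformation(l1, l2, 1.0, 0.2, -0.1, 0.05)
        co = random_coeffs(rng)
        co.wv[9] = wv10
        sig = cauchy_general(s, FiberDirection(phi), co, p=0.3)
        scale = max(np.abs(sig.components).max(), 1.0)
        assert sig.asymmetry() <= 1e-9 * scale

    def test_defect_formula_reproduced(self, rng):
        # without the constraint, sigma12 - sigma21 equals
        # l1 l2 (l2^2 - l1^2) sin(2 phi) [Wv10 + (l1^2 + l2^2) Wv12]
        for _ in range(10):
            s = random_state(rng)
            phi = rng.uniform(0.1, 1.4)
            co = random_coeffs(rng)
            sig = cauchy_general(
                s, FiberDirection(phi), co, enforce_symmetry_constraint=False
            ).components
            l1, l2 = s.lambda1, s.lambda2
            pred = (
                l1 * l2 * (l2**2 - l1**2) * math.sin(2 * phi)
                * (co.wv[9] + (l1**2 + l2**2) * co.wv[11])
            )
            assert sig[0, 1] - sig[1, 0] == pytest.approx(pred, rel=1e-9, abs=1e-12)

    def test_on_axis_fibers_shear_free(self, rng):
        for phi in (0.0, math.pi / 2):
            s = random_state(rng)
            co = random_coeffs(rng)
            sig = cauchy_general(s, FiberDirection(phi), co).components
            assert sig[0, 1] == pytest.approx(0.0, abs=1e-12)
            assert sig[1, 0] == pytest.approx(0.0, abs=1e-12)

    def test_defect_scalar(self):
        co = DerivativeCoefficients()
        assert symmetry_defect(co, 1.2, 1.1) == 0.0
        co.wv[9] = 1.0
        co.wv[11] = -1.0 / (1.2**2 + 1.1**2)
        assert symmetry_defect(co, 1.2, 1.1) == pytest.approx(0.0, abs=1e-15)
        co2 = DerivativeCoefficients()
        co2.wv[9] = 2.0
        assert symmetry_defect(co2, 1.0, 1.0) == pytest.approx(1.0)


class TestMembrane:
    def test_undeformed_stress_free(self, ref_elastic, ref_viscous):
        s = make_biaxial_state(1.0, 1.0)
        inv = invariants(s, FiberDirection(0.0))
        co = derivative_coefficients(ref_elastic, ref_viscous[0.1], inv)
        assert membrane_stresses(s, FiberDirection(0.0), co) == (0.0, 0.0, 0.0)

    def test_equibiaxial_isotropic_symmetry(self, ref_elastic):
        s = make_biaxial_state(1.2, 1.2)
        inv = invariants(s, FiberDirection(0.0))
        co = derivative_coefficients(ref_elastic, None, inv, radial_fiber_off=True)
        s11, s22, s12 = membrane_stresses(s, FiberDirection(0.0), co)
        assert s11 == pytest.approx(s22, rel=1e-12)
        assert s12 == 0.0

    def test_matches_general_tensor_with_pressure_elimination(self, rng, ref_elastic, ref_viscous):
        s = make_biaxial_state(1.25, 1.1, 0.15, 0.05)
        fib = FiberDirection(0.0)
        co = derivative_coefficients(ref_elastic, ref_viscous[0.1], invariants(s, fib))
        s11, s22, s12 = membrane_stresses(s, fib, co)
        sig0 = cauchy_general(s, fib, co, p=0.0).components
        p = sig0[2, 2]
        assert s11 == pytest.approx(sig0[0, 0] - p, rel=1e-12)
        assert s22 == pytest.approx(sig0[1, 1] - p, rel=1e-12)


class TestUniaxialClosedForms:
    def test_stress_free_at_unit_stretch(self, ref_elastic, ref_viscous):
        for rate in (0.0, 0.5):
            assert uniaxial_stress_circumferential(1.0, rate, ref_elastic,
                                                   ref_viscous[0.5]) == 0.0
            assert uniaxial_stress_radial(1.0, rate, ref_elastic,
                                          ref_viscous[0.5]) == 0.0

    def test_reference_elastic_values(self, ref_elastic):
        # hand-evaluated elastic closed forms at the reference parameters
        assert uniaxial_stress_circumferential(1.2, 0.0, ref_elastic) == pytest.approx(
            0.8265, abs=2e-4
        )
        assert uniaxial_stress_radial(1.5, 0.0, ref_elastic) == pytest.approx(
            0.1073, abs=2e-4
        )

    def test_viscous_contribution_strictly_positive(self, ref_elastic, ref_viscous):
        lam = np.linspace(1.01, 1.45, 20)
        slow = uniaxial_stress_circumferential(lam, 0.0, ref_elastic, ref_viscous[0.1])
        fast = uniaxial_stress_circumferential(lam, 0.1, ref_elastic, ref_viscous[0.1])
        assert np.all(fast > slow)

    def test_rate_linearity(self, ref_elastic, ref_viscous):
        # at fixed stretch and viscosities the stress is affine in the rate
        pv = ref_viscous[0.1]
        s0 = uniaxial_stress_circumferential(1.3, 0.0, ref_elastic, pv)
        s1 = uniaxial_stress_circumferential(1.3, 0.1, ref_elastic, pv)
        s2 = uniaxial_stress_circumferential(1.3, 0.2, ref_elastic, pv)
        assert s2 - s1 == pytest.approx(s1 - s0, rel=1e-12)

    def test_radial_independent_of_fiber_parameters(self, ref_viscous):
        a = ElasticParams(0.0217, 1.389, 0.5853, 0.4250)
        b = ElasticParams(0.0217, 1.389, 5.0, 2.0)
        assert uniaxial_stress_radial(1.4, 0.1, a, ref_viscous[0.1]) == (
            uniaxial_stress_radial(1.4, 0.1, b, ref_viscous[0.1])
        )

    def test_radial_below_circumferential(self, ref_elastic, ref_viscous):
        lam = np.linspace(1.01, 1.45, 15)
        circ = uniaxial_stress_circumferential(lam, 0.1, ref_elastic, ref_viscous[0.1])
        rad = uniaxial_stress_radial(lam, 0.1, ref_elastic, ref_viscous[0.1])
        assert np.all(rad <= circ)

    def test_closed_forms_equal_tensor_pipeline(self, rng, ref_elastic):
        """Closed-form uniaxial stresses equal the general-tensor route
        (state -> coefficients -> Cauchy with traction-free pressure)
        within 1e-9 relative, over random stretches, rates and
        viscosities."""
        for _ in range(50):
            lam = rng.uniform(1.01, 1.8)
            rate = rng.uniform(0.0, 0.6)
            pv = ViscousParams(rng.uniform(0.1, 10.0), rng.uniform(1.0, 300.0), rate)
            state = make_uniaxial_state(lam, rate)

            fib_c = FiberDirection(0.0)
            co = derivative_coefficients(ref_elastic, pv, invariants(state, fib_c))
            sig = cauchy_general(state, fib_c, co, p=0.0).components
            circ = sig[0, 0] - sig[1, 1]  # pressure from sigma22 = 0
            expected = uniaxial_stress_circumferential(lam, rate, ref_elastic, pv)
            assert circ == pytest.approx(expected, rel=1e-9)

            fib_r = FiberDirection(math.pi / 2)  # loading transverse to fibres
            co_r = derivative_coefficients(ref_elastic, pv, invariants(state, fib_r))
            sig_r = cauchy_general(state, fib_r, co_r, p=0.0).components
            rad = sig_r[0, 0] - sig_r[1, 1]
            expected_r = uniaxial_stress_radial(lam, rate, ref_elastic, pv)
            assert rad == pytest.approx(expected_r, rel=1e-9)


class TestEngineeringConversion:
    def test_direct_product(self):
        assert engineering_to_cauchy(1.0, 1.0) == 1.0
        assert engineering_to_cauchy(2.0, 1.2) == pytest.approx(2.4)

    def test_preserves_ordering(self, rng):
        lam = np.sort(rng.uniform(1.0, 1.8, 20))
        P = np.sort(rng.uniform(0.0, 3.0, 20))
        sigma = engineering_to_cauchy(P, lam)
        assert np.all(np.diff(sigma) >= 0.0)

    def test_nonpositive_stretch_rejected(self):
        with pytest.raises(ValueError):
            engineering_to_cauchy(1.0, 0.0)
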