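"""Constitutive layer: invariants, energies, stresses, impairment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pelvifem.constitutive import (
    DEFAULT_FASCIA_COMPOSITION,
    CompositionError,
    DeformationState,
    HyperelasticParams,
    InvalidDeformationError,
    MixtureComposition,
    VoigtMixture,
    apply_impairment,
    cauchy_stress,
    evaluate_stress_state,
    invariants,
    mixture_energy,
    pk2_stress,
    strain_energy,
    stress_free_pressure,
    uniaxial_deformation_gradient,
    uniaxial_nominal_stress,
    uniaxial_nominal_stress_slope,
)
from pelvifem.materials import fascia_mixture


def uniaxial_c(lam: float) -> np.ndarray:
    """Right Cauchy-Green tensor of the isochoric uniaxial state."""
    return np.diag([lam**2, 1.0 / lam, 1.0 / lam])


class TestInvariants:
    def test_reference_configuration(self):
        assert invariants(np.eye(3)) == (3.0, 3.0, 1.0)

    def test_uniaxial_principal_stretch_forms(self):
        # principal-stretch expressions evaluated directly as the oracle
        lam = 1.2
        i1, i2, i3 = invariants(uniaxial_c(lam))
        assert i1 == pytest.approx(lam**2 + 2.0 / lam, rel=1e-14)
        assert i2 == pytest.approx(2.0 * lam + lam**-2, rel=1e-14)
        assert i3 == pytest.approx(1.0, abs=1e-14)

    def test_third_invariant_is_squared_jacobian(self):
        rng = np.random.default_rng(7)
        f = np.eye(3) + 0.1 * rng.normal(size=(3, 3))
        _, _, i3 = invariants(f.T @ f)
        assert i3 == pytest.approx(np.linalg.det(f) ** 2, rel=1e-12)

    def test_rejects_non_symmetric(self):
        c = np.eye(3)
        c[0, 1] = 0.3
        with pytest.raises(InvalidDeformationError):
            invariants(c)

    def test_rejects_indefinite(self):
        with pytest.raises(InvalidDeformationError):
            invariants(np.diag([1.0, -0.5, 1.0]))

    def test_deformation_state_rejects_inverted(self):
        with pytest.raises(InvalidDeformationError):
            DeformationState.from_deformation_gradient(np.diag([-1.0, 1.0, 1.0]))


class TestStrainEnergy:
    def test_zero_in_reference_state(self, all_material_params):
        for params in all_material_params.values():
            assert strain_energy(params, 3.0, 3.0) == 0.0

    def test_adipose_uniaxial_value(self, constituent_params):
        # hand evaluation: W = c10 e1 + c20 e1^2 with e1 = I1 - 3
        lam = 1.2
        e1 = lam**2 + 2.0 / lam - 3.0
        expected = 0.000835 * e1 + 0.0128 * e1 * e1
        i1, i2, _ = invariants(uniaxial_c(lam))
        assert strain_energy(constituent_params["adipose"], i1, i2) == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(8.907e-5 + 1.456e-4, rel=1e-3)

    def test_linear_in_coefficients(self, all_material_params):
        i1, i2, _ = invariants(uniaxial_c(1.15))
        for params in all_material_params.values():
            assert strain_energy(params.scaled(2.0), i1, i2) == pytest.approx(
                2.0 * strain_energy(params, i1, i2), rel=1e-14
            )


class TestMixture:
    def test_fraction_sum_enforced(self):
        with pytest.raises(CompositionError):
            MixtureComposition(0.05, 0.85, 0.05)
        with pytest.raises(CompositionError):
            MixtureComposition(-0.1, 1.05, 0.05)

    def test_degenerate_mixture_equals_constituent(self, constituent_params):
        fas = constituent_params["collagen_elastin_fascia"]
        ad = constituent_params["adipose"]
        sm = constituent_params["smooth_muscle"]
        comp = MixtureComposition(1.0, 0.0, 0.0)
        c = uniaxial_c(1.25)
        i1, i2, _ = invariants(c)
        assert mixture_energy(comp, fas, ad, sm, c) == pytest.approx(
            float(fas.strain_energy(i1, i2)), rel=1e-14
        )

    def test_zero_at_identity(self, constituent_params):
        fas = constituent_params["collagen_elastin_fascia"]
        ad = constituent_params["adipose"]
        sm = constituent_params["smooth_muscle"]
        assert (
            mixture_energy(DEFAULT_FASCIA_COMPOSITION, fas, ad, sm, np.eye(3)) == 0.0
        )

    def test_weighted_sum_is_exact(self, constituent_params):
        fas = constituent_params["collagen_elastin_fascia"]
        ad = constituent_params["adipose"]
        sm = constituent_params["smooth_muscle"]
        comp = MixtureComposition(0.5, 0.5, 0.0)
        c = uniaxial_c(1.3)
        i1, i2, _ = invariants(c)
        expected = 0.5 * fas.strain_energy(i1, i2) + 0.5 * ad.strain_energy(i1, i2)
        assert mixture_energy(comp, fas, ad, sm, c) == pytest.approx(
            float(expected), rel=1e-15
        )


class TestStressTensors:
    def test_reference_state_stress_free(self, all_material_params):
        for params in all_material_params.values():
            p = stress_free_pressure(params)
            result = evaluate_stress_state(params, np.eye(3), p)
            for tensor in (result.S, result.P, result.sigma):
                assert np.abs(tensor).max() < 1e-10

    def test_pk2_matches_energy_gradient(self):
        # deviatoric part of S against numeric differentiation of W(C)
        mixture = fascia_mixture()
        c = uniaxial_c(1.2)
        s = pk2_stress(mixture, c, p=0.0)
        h = 1e-7
        s_fd = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                dc = np.zeros((3, 3))
                dc[i, j] += 0.5 * h
                dc[j, i] += 0.5 * h
                i1p, i2p, _ = invariants(c + dc)
                i1m, i2m, _ = invariants(c - dc)
                wp = float(mixture.strain_energy(i1p, i2p))
                wm = float(mixture.strain_energy(i1m, i2m))
                s_fd[i, j] = 2.0 * (wp - wm) / (2.0 * h)
        assert np.abs(s - s_fd).max() / np.abs(s_fd).max() < 1e-6

    def test_mixture_stress_is_weighted_sum(self, constituent_params):
        fas = constituent_params["collagen_elastin_fascia"]
        ad = constituent_params["adipose"]
        sm = constituent_params["smooth_muscle"]
        mixture = VoigtMixture.from_composition(
            DEFAULT_FASCIA_COMPOSITION, fas=fas, ad=ad, sm=sm
        )
        c = uniaxial_c(1.15)
        s_mix = pk2_stress(mixture, c, p=0.0)
        s_sum = sum(
            f * pk2_stress(params, c, p=0.0) for f, params in mixture.phases
        )
        np.testing.assert_allclose(s_mix, s_sum, rtol=0, atol=1e-15)

    def test_cauchy_identity_and_uniaxial_relation(self):
        mixture = fascia_mixture()
        s = pk2_stress(mixture, np.eye(3), stress_free_pressure(mixture))
        np.testing.assert_allclose(cauchy_stress(s, np.eye(3)), s, atol=1e-15)
        # uniaxial: axial Cauchy stress = lambda x axial nominal stress
        lam = 1.3
        state = uniaxial_deformation_gradient(lam)
        state.require_isochoric()
        p_nom = uniaxial_nominal_stress(mixture, lam)
        # pressure from the traction-free lateral faces
        w1, w2 = mixture.energy_derivatives(state.I1, state.I2)
        p_hyd = 2.0 * (w1 / lam + w2 * (state.I1 / lam - 1.0 / lam**2))
        s = pk2_stress(mixture, state.C, p_hyd)
        sigma = cauchy_stress(s, state.F)
        assert sigma[1, 1] == pytest.approx(0.0, abs=1e-12)
        assert sigma[0, 0] == pytest.approx(lam * p_nom, rel=1e-10)

    def test_objectivity_under_rotation(self):
        mixture = fascia_mixture()
        rng = np.random.default_rng(11)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.linalg.det(q))
        f = uniaxial_deformation_gradient(1.2).F
        p = stress_free_pressure(mixture)
        sigma = cauchy_stress(pk2_stress(mixture, f.T @ f, p), f)
        fr = q @ f
        sigma_rot = cauchy_stress(pk2_stress(mixture, fr.T @ fr, p), fr)
        np.testing.assert_allclose(sigma_rot, q @ sigma @ q.T, atol=1e-12)


class TestUniaxialNominalStress:
    def test_zero_at_unit_stretch(self, all_material_params):
        for params in all_material_params.values():
            assert uniaxial_nominal_stress(params, 1.0) == 0.0

    def test_collagen_fascia_value(self, structure_params):
        # 2 * 0.64785 * (1 - 1.1^-3) evaluated by hand
        value = uniaxial_nominal_stress(
            structure_params["collagen_rich_fascia"], 1.1
        )
        assert value == pytest.approx(2.0 * 0.64785 * (1.0 - 1.1**-3), rel=1e-12)
        assert value == pytest.approx(0.3222, abs=5e-5)

    def test_default_fascia_mixture_value(self):
        assert uniaxial_nominal_stress(fascia_mixture(), 1.2) == pytest.approx(
            0.0580, abs=5e-5
        )

    def test_matches_energy_differentiation(self, all_material_params):
        # closed form vs dW/dlambda of the isochoric uniaxial energy
        lams = np.linspace(1.001, 1.7, 60)
        h = 1e-6
        for params in all_material_params.values():
            def w(l):
                return np.asarray(
                    params.strain_energy(l**2 + 2.0 / l, 2.0 * l + l**-2)
                )

            fd = (w(lams + h) - w(lams - h)) / (2.0 * h)
            closed = uniaxial_nominal_stress(params, lams)
            scale = np.abs(fd).max()
            assert np.abs(closed - fd).max() / scale < 1e-6

    def test_slope_matches_finite_difference(self):
        mixture = fascia_mixture()
        lams = np.linspace(1.01, 1.6, 20)
        h = 1e-6
        fd = (
            uniaxial_nominal_stress(mixture, lams + h)
            - uniaxial_nominal_stress(mixture, lams - h)
        ) / (2.0 * h)
        np.testing.assert_allclose(
            uniaxial_nominal_stress_slope(mixture, lams), fd, rtol=1e-6
        )

    def test_rejects_non_positive_stretch(self):
        with pytest.raises(InvalidDeformationError):
            uniaxial_nominal_stress(fascia_mixture(), 0.0)


class TestImpairment:
    def test_identity_at_zero(self, structure_params):
        pul = structure_params["pubourethral_ligament"]
        assert apply_impairment(pul, 0.0) == pul

    def test_maximum_impairment_multiplier(self, structure_params):
        pul = structure_params["pubourethral_ligament"]
        weak = apply_impairment(pul, 0.95)
        assert weak.c10 == pytest.approx(0.05 * pul.c10, rel=1e-15)
        assert weak.c20 == pytest.approx(0.05 * pul.c20, rel=1e-15)
        assert pul.c10 == 0.68  # original untouched

    def test_out_of_range_rejected(self, structure_params):
        pul = structure_params["pubourethral_ligament"]
        for bad in (-0.01, 0.951, 1.0):
            with pytest.raises(ValueError):
                apply_impairment(pul, bad)

    def test_stress_scales_linearly(self, structure_params):
        lams = np.linspace(1.0, 1.7, 30)
        for params in structure_params.values():
            weak = apply_impairment(params, 0.4)
            np.testing.assert_allclose(
                uniaxial_nominal_stress(weak, lams),
                0.6 * uniaxial_nominal_stress(params, lams),
                rtol=1e-13,
            )


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

coeff = st.floats(min_value=0.0, max_value=10.0, allow_nan=False)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(c10=coeff, c01=coeff, c20=coeff, scale=st.floats(0.01, 100.0))
def test_nominal_stress_linear_in_coefficients(c10, c01, c20, scale):
    params = HyperelasticParams("p", c10, c01, c20)
    lams = np.linspace(1.0, 1.7, 15)
    np.testing.assert_allclose(
        uniaxial_nominal_stress(params.scaled(scale), lams),
        scale * uniaxial_nominal_stress(params, lams),
        rtol=1e-12,
        atol=1e-300,
    )


@settings(max_examples=40, deadline=None, derandomize=True)
@given(c10=coeff, c01=coeff, c20=coeff)
def test_nominal_stress_monotone_for_nonnegative_coefficients(c10, c01, c20):
    if c10 + c01 + c20 == 0.0:
        return
    params = HyperelasticParams("p", c10, c01, c20)
    lams = np.linspace(1.0, 1.7, 200)
    p = uniaxial_nominal_stress(params, lams)
    assert np.all(np.diff(p) > 0.0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    f1=st.floats(0.0, 1.0),
    f2=st.floats(0.0, 1.0),
    lam=st.floats(0.8, 1.7),
)
def test_voigt_uniaxial_stress_is_weighted_sum(f1, f2, lam):
    from pelvifem.materials import load_fascia_constituents

    table = load_fascia_constituents()
    fas = table["collagen_elastin_fascia"]
    ad = table["adipose"]
    sm = table["smooth_muscle"]
    total = f1 + f2
    if total > 1.0:
        f1, f2 = f1 / total, f2 / total
    f3 = 1.0 - f1 - f2
    comp = MixtureComposition(f1, f2, max(f3, 0.0) if f3 > -1e-12 else 0.0)
    mixture = VoigtMixture.from_composition(comp, fas=fas, ad=ad, sm=sm)
    expected = (
        comp.f_fas * uniaxial_nominal_stress(fas, lam)
        + comp.f_ad * uniaxial_nominal_stress(ad, lam)
        + comp.f_sm * uniaxial_nominal_stress(sm, lam)
    )
    assert uniaxial_nominal_stress(mixture, lam) == pytest.approx(
        expected, rel=1e-12, abs=1e-300
    )
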