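"""Unit tests for kinematics, elastic stresses, damage law and moduli."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from renomech import (
    DamageParameters,
    HyperelasticCoefficients,
    compute_invariants,
    damage_growth_increment,
    damage_softening_factor,
    distortional_energy,
    elastic_deviatoric_stress,
    elastic_pressure,
    initial_shear_modulus,
    moduli_from_shear,
    octahedral_shear_strain,
    volumetric_energy,
)
from renomech.exceptions import (
    ConfigurationError,
    DamageValidityWarning,
    InvalidInputError,
)

stretches = st.floats(min_value=0.5, max_value=2.0)


class TestInvariants:
    @pytest.mark.parametrize(
        "lams, J, I1, I2",
        [
            ((1.0, 1.0, 1.0), 1.0, 3.0, 3.0),
            # incompressible uniaxial at lam=1.2: I1 = lam^2+2/lam, I2 = 2 lam + 1/lam^2
            (
                (1.2, 1.2**-0.5, 1.2**-0.5),
                1.0,
                1.2**2 + 2.0 / 1.2,
                2 * 1.2 + 1.2**-2,
            ),
            # pure dilatation leaves the isochoric invariants at 3
            ((1.1, 1.1, 1.1), 1.1**3, 3.0, 3.0),
        ],
    )
    def test_reference_states(self, lams, J, I1, I2):
        state = compute_invariants(lams)
        assert state.J == pytest.approx(J, rel=1e-12)
        assert state.I1_bar == pytest.approx(I1, rel=1e-12)
        assert state.I2_bar == pytest.approx(I2, rel=1e-12)

    def test_rejects_nonpositive_stretch(self):
        with pytest.raises(InvalidInputError):
            compute_invariants((1.0, -0.2, 1.0))
        with pytest.raises(InvalidInputError):
            compute_invariants((0.0, 1.0, 1.0))

    @given(stretches, stretches, stretches)
    def test_isochoric_invariants_bounded_below(self, l1, l2, l3):
        state = compute_invariants((l1, l2, l3))
        assert state.I1_bar >= 3.0 - 1e-12
        assert state.I2_bar >= 3.0 - 1e-12

    @given(stretches, stretches, stretches, st.floats(min_value=0.8, max_value=1.25))
    def test_dilatation_invariance(self, l1, l2, l3, scale):
        a = compute_invariants((l1, l2, l3))
        b = compute_invariants((scale * l1, scale * l2, scale * l3))
        assert b.I1_bar == pytest.approx(a.I1_bar, rel=1e-10)
        assert b.I2_bar == pytest.approx(a.I2_bar, rel=1e-10)


class TestEnergies:
    def test_undeformed_energy_is_zero(self, table_coeffs):
        state = compute_invariants((1.0, 1.0, 1.0))
        assert distortional_energy(state, table_coeffs) == 0.0

    def test_cubic_polynomial_value(self, table_coeffs):
        # direct evaluation at I1 = 3.02818 (uniaxial lam ~ 1.1, incompressible)
        state = compute_invariants((1.1, 1.1**-0.5, 1.1**-0.5))
        x = state.I1_bar - 3.0
        expected = 8.3e-3 * x + 0.8 * x**2 - 0.74 * x**3
        assert distortional_energy(state, table_coeffs) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(8.53e-4, rel=2e-3)

    def test_neo_hookean_reduction(self):
        coeffs = HyperelasticCoefficients(C10=0.37)
        state = compute_invariants((2.0, 2.0**-0.5, 2.0**-0.5))
        x = state.I1_bar - 3.0
        assert distortional_energy(state, coeffs) == pytest.approx(0.37 * x, rel=1e-12)

    def test_volumetric_energy(self):
        assert volumetric_energy(1.0, 5.0) == 0.0
        assert volumetric_energy(1.1, 2.0) == pytest.approx(0.01, rel=1e-12)
        # even in (Je - 1)
        assert volumetric_energy(1.05, 3.0) == pytest.approx(volumetric_energy(0.95, 3.0))
        with pytest.raises(InvalidInputError):
            volumetric_energy(-1.0, 2.0)


class TestDamageSoftening:
    def test_limits_and_monotonicity(self):
        assert damage_softening_factor(0.0) == 1.0
        assert damage_softening_factor(0.1) == pytest.approx(1.0 + math.log(0.9), rel=1e-12)
        cs = np.linspace(0.0, 0.5, 40)
        phis = [damage_softening_factor(c) for c in cs]
        assert np.all(np.diff(phis) < 0.0)

    def test_domain_and_validity_warning(self):
        with pytest.raises(InvalidInputError):
            damage_softening_factor(1.0)
        with pytest.raises(InvalidInputError):
            damage_softening_factor(-0.01)
        with pytest.warns(DamageValidityWarning):
            assert damage_softening_factor(0.99) < 0.0


class TestElasticStresses:
    def test_pressure_reference_values(self, table_coeffs):
        state = compute_invariants((1.001, 1.0, 1.0))
        # K(Je-1) at c=0; K for G=1, mu=0.495 is 99.667
        p = elastic_pressure(state, 0.0, K=99.667)
        assert p == pytest.approx(99.667 * (state.J - 1.0), rel=1e-9)

    def test_damage_volume_carries_no_pressure(self):
        # J = 1.1 entirely due to damage (c = 0.1) leaves Je = 1: no pressure
        state = compute_invariants((1.1 ** (1 / 3),) * 3).with_damage(0.1)
        assert state.Je == pytest.approx(1.0, rel=1e-12)
        assert elastic_pressure(state, 0.1, K=50.0) == pytest.approx(0.0, abs=1e-12)

    def test_deviator_traceless_and_phi_scaling(self, table_coeffs):
        state = compute_invariants((1.15, 0.95, 0.97))
        s0 = elastic_deviatoric_stress(state, 0.0, table_coeffs)
        assert abs(s0.sum()) < 1e-12
        c_half = 1.0 - math.exp(-0.5)  # phi = 0.5
        s_half = elastic_deviatoric_stress(state, c_half, table_coeffs)
        np.testing.assert_allclose(s_half, 0.5 * s0, rtol=1e-9)

    def test_incompressible_uniaxial_stress_difference(self, table_coeffs):
        lam = 1.1
        state = compute_invariants((lam, lam**-0.5, lam**-0.5))
        s = elastic_deviatoric_stress(state, 0.0, table_coeffs)
        x = state.I1_bar - 3.0
        dpsi = 8.3e-3 + 2 * 0.8 * x + 3 * (-0.74) * x**2
        expected = 2.0 * (lam**2 - 1.0 / lam) * dpsi
        assert s[0] - s[1] == pytest.approx(expected, rel=1e-10)
        assert expected == pytest.approx(0.03107, rel=1e-3)


class TestOctahedralShearStrain:
    def test_identity_is_zero(self):
        assert octahedral_shear_strain(compute_invariants((1.0, 1.0, 1.0))) == 0.0

    def test_uniaxial_reference_value(self):
        state = compute_invariants((1.2, 1.2**-0.5, 1.2**-0.5))
        val = octahedral_shear_strain(state)
        rad = 2.0 * state.I1_bar**2 - 6.0 * state.I2_bar
        assert val == pytest.approx(math.sqrt(rad) / 6.0, rel=1e-12)
        assert val == pytest.approx(0.1430, abs=5e-4)

    def test_prefactor_is_configurable(self):
        state = compute_invariants((1.3, 1.3**-0.5, 1.3**-0.5))
        assert octahedral_shear_strain(state, prefactor=1.0 / 3.0) == pytest.approx(
            2.0 * octahedral_shear_strain(state), rel=1e-12
        )

    @given(stretches, stretches, stretches)
    def test_matches_eigenvalue_difference_form(self, l1, l2, l3):
        state = compute_invariants((l1, l2, l3))
        lb2 = np.array([l1, l2, l3]) ** 2 * state.J ** (-2.0 / 3.0)
        eig_form = math.sqrt(
            (lb2[0] - lb2[1]) ** 2 + (lb2[1] - lb2[2]) ** 2 + (lb2[0] - lb2[2]) ** 2
        ) / 6.0
        # the invariant route cancels catastrophically near the identity
        # (radicand ~ eps * I1^2), hence the absolute floor of ~sqrt(eps)/6
        tol = 1e-10 * eig_form + 1e-7
        assert abs(octahedral_shear_strain(state) - eig_form) < tol


class TestDamageGrowth:
    def test_constant_distortion_gives_zero_increment(self):
        params = DamageParameters(alpha=0.5, beta=3e-4, n_exp=2.0)
        assert damage_growth_increment(0.1, 0.1, 1.0, params) == 0.0

    def test_gamma_value_from_reference_constants(self):
        # gamma = beta * Igamma^n = 3.0e-4 * 0.1^2
        params = DamageParameters(alpha=0.0, beta=3.0e-4, n_exp=2.0)
        inc = damage_growth_increment(0.0, 0.1, 0.0, params)
        assert inc == pytest.approx(3.0e-6, rel=1e-12)

    def test_alpha_zero_integrates_to_closed_form(self):
        # summed increments along any monotone path equal beta * Igamma^n
        params = DamageParameters(alpha=0.0, beta=2e-3, n_exp=1.7)
        path = np.linspace(0.0, 0.3, 1500)
        c = 0.0
        for a, b in zip(path[:-1], path[1:]):
            c += damage_growth_increment(a, b, 0.123, params)
        assert c == pytest.approx(2e-3 * 0.3**1.7, rel=1e-12)

    def test_no_healing_on_unloading(self):
        params = DamageParameters(alpha=0.0, beta=1e-3, n_exp=2.0)
        assert damage_growth_increment(0.2, 0.1, 0.0, params) == 0.0

    def test_pressure_factor(self):
        params = DamageParameters(alpha=2.0, beta=1e-3, n_exp=1.0)
        ratio = damage_growth_increment(0.0, 0.1, 1.0, params) / damage_growth_increment(
            0.0, 0.1, 0.0, params
        )
        assert ratio == pytest.approx(math.exp(2.0), rel=1e-12)


class TestModuli:
    def test_initial_shear_modulus_reference(self, table_coeffs):
        assert initial_shear_modulus(table_coeffs) == pytest.approx(0.1366, rel=1e-12)
        assert initial_shear_modulus(HyperelasticCoefficients(C10=0.5)) == 1.0

    def test_nonpositive_shear_modulus_rejected(self):
        with pytest.raises(ConfigurationError):
            HyperelasticCoefficients(C10=0.0, C20=0.0, C30=0.0)

    def test_conversions_at_reference_poisson_ratio(self):
        E, K = moduli_from_shear(1.0, 0.495)
        assert E == pytest.approx(2.99, rel=1e-12)
        assert K == pytest.approx(2.0 * 1.495 / 0.03, rel=1e-12)
        assert moduli_from_shear(0.0, 0.3) == (0.0, 0.0)

    def test_incompressible_limit_rejected(self):
        with pytest.raises(ConfigurationError):
            moduli_from_shear(1.0, 0.5)

    @given(st.floats(min_value=1e-3, max_value=10.0))
    def test_bulk_to_shear_ratio_independent_of_G(self, G):
        _, K = moduli_from_shear(G, 0.495)
        assert K / G == pytest.approx(2.0 * 1.495 / 0.03, rel=1e-12)
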