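"""Generalized Debye–Hückel model: screening lengths, spectral roots,
shell radii, Born scaling, reaction potential, activity coefficients."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pnpbik.constants import bjerrum_length
from pnpbik.errors import ComplexRootError, ValidationError
from pnpbik.gdh import (
    HydrationSpec,
    activity_coefficient,
    binary_composition,
    born_radius,
    excess_chemical_potential,
    fit_activity_parameters,
    gdh_result,
    reaction_potential,
    screening_lengths,
    shell_radius,
    spectral_roots,
    theta_factor,
)
from pnpbik.presets import hydration_spec


def debye_length_si(conc_M, z1, z2, eps=78.45, T=298.15):
    """Independent textbook oracle via SI constants."""
    from scipy import constants as si

    n1 = conc_M * abs(z2) * 1e3 * si.Avogadro  # m^-3
    n2 = conc_M * z1 * 1e3 * si.Avogadro
    k2 = si.e**2 * (n1 * z1**2 + n2 * z2**2) / (si.epsilon_0 * eps * si.k * T)
    return 1.0 / np.sqrt(k2) * 1e10


class TestScreeningLengths:
    def test_debye_length_textbook(self):
        comp = binary_composition("NaCl", 0.1)
        _, lD, _, _, _ = screening_lengths(comp)
        assert lD == pytest.approx(debye_length_si(0.1, 1, -1), rel=1e-10)
        assert lD == pytest.approx(9.63, abs=0.03)

    def test_equal_volumes_reduce_to_debye(self):
        comp = binary_composition(("C+", 1, 2.0, "A-", -1, 2.0), 0.3)
        _, lD, Lam, lD4, _ = screening_lengths(comp)
        assert Lam == 0.0
        assert lD4 == pytest.approx(lD, rel=1e-14)

    def test_point_particles_reduce_to_debye(self):
        comp = binary_composition(("C+", 1, 0.0, "A-", -1, 0.0), 0.3,
                                  water_radius_A=0.0)
        _, lD, Lam, lD4, _ = screening_lengths(comp)
        assert Lam == 0.0
        assert lD4 == pytest.approx(lD, rel=1e-14)

    def test_unequal_volumes_lengthen_screening(self):
        comp = binary_composition("LiCl", 0.5)
        _, lD, Lam, lD4, _ = screening_lengths(comp, ion_index=1)
        assert 0 < Lam < 1
        assert lD4 > lD


class TestSpectralRoots:
    def test_lc_zero_limit(self):
        l1, l2 = spectral_roots(0.0, 5.0)
        assert l1 == pytest.approx(0.2)
        assert np.isinf(l2)

    def test_coalescing_roots(self):
        lc = 1.3
        l1, l2 = spectral_roots(lc, 2 * lc)
        assert l1 == pytest.approx(l2)
        assert l1 == pytest.approx(1.0 / (np.sqrt(2) * lc), rel=1e-12)

    def test_complex_regime_raises(self):
        with pytest.raises(ComplexRootError):
            spectral_roots(3.0, 4.0)

    @given(lc=st.floats(0.05, 3.0), ratio=st.floats(2.001, 50.0))
    @settings(max_examples=200, deadline=None)
    def test_vieta_identities(self, lc, ratio):
        lD4 = lc * ratio
        l1, l2 = spectral_roots(lc, lD4)
        assert l1 <= l2
        assert l1**2 + l2**2 == pytest.approx(1.0 / lc**2, rel=1e-10)
        assert (l1 * l2) ** 2 == pytest.approx(1.0 / (lc * lD4) ** 2, rel=1e-10)


class TestTheta:
    def test_infinite_dilution_is_one(self):
        # both roots -> 0 as the salt vanishes
        comp = binary_composition("NaCl", 1e-12)
        r = gdh_result(hydration_spec("Cl-"), comp)
        assert r.theta == pytest.approx(1.0, abs=1e-5)

    def test_lc_zero_matches_dh_screening(self):
        R = 3.0
        lD = 7.0
        th = theta_factor(1.0 / lD, np.inf, R)
        assert (th - 1.0) / R == pytest.approx(-1.0 / (R + lD), rel=1e-12)

    def test_continuous_through_coalescing_roots(self):
        lc = 1.0
        R = 4.0
        l1a, l2a = spectral_roots(lc, 2 * lc * (1 + 1e-9))
        l1b, l2b = spectral_roots(lc, 2 * lc)
        assert theta_factor(l1a, l2a, R) == pytest.approx(
            theta_factor(l1b, l2b, R), rel=1e-6)


class TestShellRadius:
    def test_chloride_shell_in_dilute_licl(self):
        comp = binary_composition("LiCl", 1e-12)
        _, R = shell_radius(hydration_spec("Cl-", "LiCl"), comp)
        assert R == pytest.approx(5.123, abs=0.05)

    def test_shell_shrinks_with_salt(self):
        spec = hydration_spec("Cl-", "LiCl")
        R0 = shell_radius(spec, binary_composition("LiCl", 1e-12))[1]
        R16 = shell_radius(spec, binary_composition("LiCl", 1.6))[1]
        assert R16 < R0
        assert R16 == pytest.approx(5.083, abs=0.05)

    def test_root_matches_dense_scan(self):
        """Brute-force the residual on a dense volume grid."""
        from pnpbik.constants import MOLAR_TO_PER_A3

        spec = hydration_spec("Cl-")
        comp = binary_composition("LiCl", 0.5)
        v_w = comp.water.volume_A3
        C_w = 55.5 * MOLAR_TO_PER_A3
        O = spec.coordination
        V_grid = np.linspace(v_w * O + 1e-6, 4000.0, 400000)
        res = np.log((V_grid - v_w * O) / (V_grid * comp.gamma_bulk)) - (
            comp.v0 / v_w) * np.log(O / (V_grid * C_w))
        k = np.argmin(np.abs(res))
        V, _ = shell_radius(spec, comp)
        assert V == pytest.approx(V_grid[k], rel=1e-4)

    def test_shell_never_overpacked(self):
        """The solved shell volume always exceeds the packed water volume."""
        comp = binary_composition("LiCl", 0.1)
        v_w = comp.water.volume_A3
        for O in (4, 18, 60):
            spec = HydrationSpec("X-", -1, 1.8, 2.0, coordination=O)
            V, _ = shell_radius(spec, comp)
            assert V > v_w * O

    def test_nonpositive_coordination_raises(self):
        spec = HydrationSpec("X-", -1, 1.8, 2.0, coordination=0)
        with pytest.raises(ValidationError):
            shell_radius(spec, binary_composition("LiCl", 0.1))


class TestBornRadius:
    def test_zero_concentration_identity(self):
        spec = hydration_spec("Cl-", "LiCl")
        assert born_radius(spec, 0.0) == spec.born_radius0_A

    def test_chloride_scaling_at_2p5M(self):
        spec = hydration_spec("Cl-", "LiCl")
        assert born_radius(spec, 2.5) / spec.born_radius0_A == pytest.approx(
            1.044, abs=1e-3)

    def test_null_parameters_stay_unity(self):
        spec = hydration_spec("Na+", "NaF")
        for c in (0.0, 0.5, 1.6, 3.0):
            assert born_radius(spec, c) == spec.born_radius0_A


class TestReactionPotential:
    @pytest.mark.parametrize("salt,conc", [("LiCl", 0.5), ("KBr", 1.0)])
    def test_continuity_at_interfaces(self, salt, conc):
        ion = salt[-3:] if salt.endswith("-") else None
        from pnpbik.presets import SALT_IONS

        ion = SALT_IONS[salt][1]
        r = gdh_result(hydration_spec(ion, salt), binary_composition(salt, conc))
        eps = 1e-9
        for R in (r.R_born, r.R_shell):
            lo = reaction_potential(R * (1 - eps), r)
            hi = reaction_potential(R * (1 + eps), r)
            assert hi == pytest.approx(lo, rel=1e-6)

    def test_continuity_random_draws(self, rng):
        """Potential is continuous across both interfaces for random
        feasible parameter draws."""
        from pnpbik.gdh import GDHResult

        for _ in range(1000):
            lc = rng.uniform(0.05, 2.0)
            lD4 = lc * rng.uniform(2.01, 40.0)
            l1, l2 = spectral_roots(lc, lD4)
            Rb = rng.uniform(0.5, 3.0)
            Rsh = Rb + rng.uniform(0.5, 4.0)
            th = theta_factor(l1, l2, Rsh)
            r = GDHResult("X", 7.0, lD4, 0.0, lD4, lc, l1, l2, th, Rb, Rb,
                          Rsh, 1.0, 0.0, 0.0)
            eps = 1e-9
            for R in (Rb, Rsh):
                lo = reaction_potential(R * (1 - eps), r, z=1)
                hi = reaction_potential(R * (1 + eps), r, z=1)
                assert hi == pytest.approx(lo, rel=1e-5)

    def test_dilution_limit_is_born_potential(self):
        spec = hydration_spec("Cl-", "LiCl")
        r = gdh_result(spec, binary_composition("LiCl", 1e-12))
        lB = r.lB
        assert reaction_potential(0.0, r, z=-1) == pytest.approx(
            -lB / spec.born_radius0_A, rel=1e-4)

    def test_linearized_pb_limit(self):
        """lc -> 0, no volumes, no shell: the screened Coulomb potential."""
        from pnpbik.gdh import GDHResult

        lD = 9.6
        lB = 7.14
        r = GDHResult("X", lB, lD, 0.0, lD, 0.0, 1.0 / lD, np.inf, 1.0,
                      1e-12, 1e-12, 0.0, 0.0, 0.0, 0.0)
        rr = np.array([2.0, 5.0, 12.0])
        expected = lB * np.exp(-rr / lD) / rr
        np.testing.assert_allclose(reaction_potential(rr, r, z=1), expected,
                                   rtol=1e-10)


class TestActivityCoefficients:
    def test_ideal_at_infinite_dilution_all_modes(self):
        spec = hydration_spec("Cl-", "LiCl")
        comp = binary_composition("LiCl", 1e-12)
        for mode in ("generalized", "classical_DH", "extended_DHB"):
            lng = activity_coefficient(spec, comp, mode, eta=(1.0, 0.1))
            assert np.exp(lng) == pytest.approx(1.0, abs=1e-5)

    def test_generalized_collapses_to_classical_dh(self):
        """With Born scaling off, steric volumes zero and lc -> 0, the
        generalized ln gamma equals the 1923 closed form with R = R_sh."""
        z = -1
        conc = 0.2
        comp = binary_composition(("C+", 1, 0.0, "A-", -1, 0.0), conc,
                                  water_radius_A=0.0)
        lB, lD, Lam, lD4, _ = screening_lengths(comp, ion_index=1)
        assert Lam == 0.0 and lD4 == pytest.approx(lD, rel=1e-14)
        Rsh = 3.2
        th = theta_factor(*spectral_roots(0.0, lD4), Rsh)
        ln_gen = z**2 * lB / 2.0 * (th - 1.0) / Rsh
        ln_dh = -(z**2) * lB / (2.0 * (lD + Rsh))
        assert ln_gen == pytest.approx(ln_dh, rel=1e-10)

    def test_dh_limiting_slope(self):
        """d ln gamma / d sqrt(C) at C -> 0 matches the DH limiting law
        within 1% for a 1:1 salt with Born scaling off."""
        spec = HydrationSpec("Cl-", -1, 1.81, 2.266)  # alphas = 0
        c = 1e-8
        lng = activity_coefficient(spec, binary_composition("LiCl", c))
        lB = bjerrum_length(78.45)
        from pnpbik.constants import MOLAR_TO_PER_A3

        kappa = np.sqrt(4 * np.pi * lB * 2 * c * MOLAR_TO_PER_A3)
        slope_dh = -lB / 2.0 * kappa / np.sqrt(c)
        assert lng / np.sqrt(c) == pytest.approx(slope_dh, rel=0.01)

    def test_excess_chemical_potential_identity(self):
        spec = hydration_spec("Cl-", "LiCl")
        comp = binary_composition("LiCl", 0.7)
        assert excess_chemical_potential(spec, comp) == activity_coefficient(
            spec, comp, "generalized")

    def test_unknown_mode_raises(self, nacl_01m):
        with pytest.raises(ValidationError):
            activity_coefficient(hydration_spec("Cl-"), nacl_01m, "pitzer")


class TestParameterFit:
    def test_exact_recovery(self):
        true = (0.052, -0.015, 0.0)
        spec = HydrationSpec("Cl-", -1, 1.81, 2.266, alphas=true)
        concs = np.linspace(0.1, 1.6, 8)
        gammas = [np.exp(activity_coefficient(
            spec, binary_composition("LiCl", c))) for c in concs]
        fitted, resid = fit_activity_parameters(
            np.column_stack([concs, gammas]),
            HydrationSpec("Cl-", -1, 1.81, 2.266), "LiCl")
        np.testing.assert_allclose(fitted, true, atol=1e-6)
        assert resid < 1e-8

    def test_zero_alpha_data_fits_zero(self):
        spec = HydrationSpec("Cl-", -1, 1.81, 2.266)
        concs = np.linspace(0.1, 1.0, 6)
        gammas = [np.exp(activity_coefficient(
            spec, binary_composition("LiCl", c))) for c in concs]
        fitted, _ = fit_activity_parameters(
            np.column_stack([concs, gammas]), spec, "LiCl")
        np.testing.assert_allclose(fitted, 0.0, atol=1e-8)

    def test_noisy_recovery_within_three_sigma(self):
        from pnpbik.fixtures import salt_activity_table

        true = (0.05, -0.01, 0.0)
        spec = HydrationSpec("Cl-", -1, 1.81, 2.266, alphas=true)
        table = salt_activity_table(spec, "LiCl", np.linspace(0.1, 1.6, 12),
                                    noise_sigma=0.01, seed=7)
        fitted, resid = fit_activity_parameters(
            table[["concentration_M", "gamma"]].to_numpy(),
            HydrationSpec("Cl-", -1, 1.81, 2.266), "LiCl")
        # generous three-sigma style envelope for a 12-point fit at sigma=0.01
        np.testing.assert_allclose(fitted, true, atol=0.15)

    def test_underdetermined_raises(self):
        with pytest.raises(ValidationError):
            fit_activity_parameters(np.array([[0.1, 0.9], [0.2, 0.85]]),
                                    hydration_spec("Cl-"), "LiCl")
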