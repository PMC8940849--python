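"""Constitutive model: energies, stresses, and the linear-parameter split."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eyegap.constitutive import (FiberPoint, KinematicState,
                                 MaterialParameters, PlateLayer,
                                 cauchy_stress, modified_invariant,
                                 plate_rigidity, strain_energy,
                                 stress_decomposition)
from conftest import random_states

EX = np.array([1.0, 0.0, 0.0])
EY = np.array([0.0, 1.0, 0.0])
HEALTHY = MaterialParameters(K=10.0, mu=0.275, k1=0.04, k2=200.0)
FIBER = FiberPoint(a1=EX, a2=EY, kappa=0.1)


def state_of(F, fiber=FIBER):
    return KinematicState.from_deformation_gradient(np.asarray(F, float),
                                                    fiber)


class TestModifiedInvariant:
    @pytest.mark.parametrize("i1, i4, kappa, expected", [
        (3.6, 1.2, 1.0 / 3.0, 1.2),     # kappa=1/3: I1t/3 survives
        (3.6, 1.2, 0.0, 1.2),           # kappa=0: pure fiber invariant
        (3.3, 1.2, 0.1, 1.17),          # hand evaluation
    ])
    def test_values(self, i1, i4, kappa, expected):
        assert modified_invariant(i1, i4, kappa) == pytest.approx(expected)

    @pytest.mark.parametrize("kappa", [-0.01, 0.34, 1.0])
    def test_domain(self, kappa):
        with pytest.raises(ValueError):
            modified_invariant(3.0, 1.0, kappa)

    @given(st.floats(3.0, 4.0), st.floats(0.8, 1.5), st.floats(0, 1 / 3))
    @settings(max_examples=50, deadline=None)
    def test_blend_bounds(self, i1, i4, kappa):
        val = modified_invariant(i1, i4, kappa)
        lo, hi = sorted([i4, i1 / 3.0])
        assert lo - 1e-12 <= val <= hi + 1e-12


class TestStrainEnergy:
    def test_reference_state_is_stress_free(self):
        assert strain_energy(state_of(np.eye(3)), HEALTHY, FIBER) == \
            pytest.approx(0.0, abs=1e-14)

    def test_volumetric_penalty_value(self):
        # pure dilatation J=1.1 with mu=k1=0, K=10
        params = MaterialParameters(K=10.0, mu=0.0, k1=0.0, k2=200.0)
        F = 1.1 ** (1.0 / 3.0) * np.eye(3)
        psi = strain_energy(state_of(F), params, FIBER)
        assert psi == pytest.approx(2.5 * (0.21 - 2 * np.log(1.1)),
                                    rel=1e-12)

    def test_fiber_term_value(self):
        # isochoric stretch along family 1 so that I4* = 1.05 (kappa=0);
        # family 2 is compressed and switched off (tension-only)
        params = MaterialParameters(K=0.0, mu=0.0, k1=0.04, k2=200.0)
        fib = FiberPoint(a1=EX, a2=EY, kappa=0.0)
        s = np.sqrt(1.05)
        F = np.diag([s, 1 / np.sqrt(s), 1 / np.sqrt(s)])
        psi = strain_energy(state_of(F, fib), params, fib)
        assert psi == pytest.approx((0.04 / 400.0) * (np.exp(0.5) - 1.0),
                                    rel=1e-12)

    def test_fiber_vanishes_at_unit_invariant(self):
        # volumetric deformation leaves I4* = 1 (isochoric measures)
        params = MaterialParameters(K=0.0, mu=0.0, k1=1.0, k2=200.0)
        F = 1.05 * np.eye(3)
        assert strain_energy(state_of(F), params, FIBER) == \
            pytest.approx(0.0, abs=1e-14)

    def test_variance_correction_factor(self):
        base = MaterialParameters(K=0, mu=0, k1=0.04, k2=200.0)
        corr = MaterialParameters(K=0, mu=0, k1=0.04, k2=200.0,
                                  variance_correction_enabled=True,
                                  Kstar=2.0, sigma2_I4=0.1)
        fib = FiberPoint(a1=EX, a2=EY, kappa=0.0)
        F = np.diag([1.05, 1.05 ** -0.5, 1.05 ** -0.5])
        st_ = state_of(F, fib)
        assert strain_energy(st_, corr, fib) == \
            pytest.approx(1.2 * strain_energy(st_, base, fib), rel=1e-12)


class TestCauchyStress:
    def test_zero_at_identity(self):
        sig = cauchy_stress(state_of(np.eye(3)), HEALTHY, FIBER)
        np.testing.assert_allclose(sig, 0.0, atol=1e-13)

    def test_neo_hookean_uniaxial(self):
        lam = 1.2
        params = MaterialParameters(K=5.0, mu=0.3, k1=0.0, k2=1.0)
        F = np.diag([lam, lam ** -0.5, lam ** -0.5])
        sig = cauchy_stress(state_of(F), params, None)
        assert sig[0, 0] - sig[1, 1] == pytest.approx(
            0.3 * (lam ** 2 - 1.0 / lam), rel=1e-12)

    def test_symmetry_and_volumetric_pressure(self):
        F = random_states(1, seed=3)[0]
        sig = cauchy_stress(state_of(F), HEALTHY, FIBER)
        np.testing.assert_allclose(sig, sig.T, atol=1e-12)
        pure_vol = MaterialParameters(K=7.0, mu=0, k1=0, k2=1.0)
        J = np.linalg.det(F)
        sv = cauchy_stress(state_of(F), pure_vol, None)
        np.testing.assert_allclose(
            sv, 3.5 * (J - 1 / J) * np.eye(3), rtol=1e-10)

    def test_invalid_kinematics(self):
        with pytest.raises(ValueError):
            state_of(np.diag([1.0, 1.0, -1.0]))


def finite_difference_stress(F, params, fiber, h=1e-6):
    """Independent oracle: sigma = (1/J) dpsi/dF F^T by central FD."""
    P = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            Fp, Fm = F.copy(), F.copy()
            Fp[i, j] += h
            Fm[i, j] -= h
            P[i, j] = (strain_energy(state_of(Fp, fiber), params, fiber)
                       - strain_energy(state_of(Fm, fiber), params, fiber)
                       ) / (2 * h)
    J = np.linalg.det(F)
    return P @ F.T / J


class TestEnergyConsistency:
    def test_stress_matches_energy_gradient(self):
        """Analytic Cauchy stress vs FD derivative of the energy on 1000
        random states with J in [0.9, 1.2] (relative 1e-5)."""
        params = HEALTHY.replace(fiber_tension_only=False)
        Fs = random_states(1200, seed=42)[:1000]
        fib = (np.broadcast_to(EX, (len(Fs), 3)),
               np.broadcast_to(EY, (len(Fs), 3)),
               np.full(len(Fs), 0.1))
        sig = cauchy_stress(
            KinematicState.from_deformation_gradient(Fs, fib), params, fib)
        scale = np.abs(sig).max()
        for i in range(0, len(Fs), 25):        # FD-check a subsample densely
            ref = finite_difference_stress(Fs[i], params, FIBER)
            np.testing.assert_allclose(sig[i], ref, atol=1e-5 * scale)

    def test_tension_switch_consistent_away_from_kink(self):
        params = HEALTHY
        Fs = random_states(50, seed=7)
        for F in Fs:
            st_ = state_of(F)
            if np.min(np.abs(st_.I4star - 1.0)) < 1e-3:
                continue
            ref = finite_difference_stress(F, params, FIBER)
            sig = cauchy_stress(st_, params, FIBER)
            assert np.allclose(sig, ref, atol=1e-5 * max(np.abs(ref).max(),
                                                         1e-6))


class TestStressDecomposition:
    def test_exact_linear_reconstruction(self):
        Fs = random_states(100, seed=11)
        fib = (np.broadcast_to(EX, (len(Fs), 3)),
               np.broadcast_to(EY, (len(Fs), 3)), np.full(len(Fs), 0.1))
        st_ = KinematicState.from_deformation_gradient(Fs, fib)
        sK, smu, sk1 = stress_decomposition(st_, fib, k2=200.0)
        rng = np.random.default_rng(0)
        for _ in range(100):
            K, mu, k1 = rng.uniform(0.01, 10.0, 3)
            params = MaterialParameters(K=K, mu=mu, k1=k1, k2=200.0)
            direct = cauchy_stress(st_, params, fib)
            recon = K * sK + mu * smu + k1 * sk1
            np.testing.assert_allclose(recon, direct, rtol=0, atol=1e-12
                                       * max(1.0, np.abs(direct).max()))

    def test_volumetric_piece_vanishes_at_isochoric(self):
        F = np.diag([1.2, 1 / 1.2, 1.0])       # J = 1
        sK, _, _ = stress_decomposition(state_of(F), FIBER, k2=200.0)
        np.testing.assert_allclose(sK, 0.0, atol=1e-12)

    def test_fiber_piece_is_k1_derivative(self):
        F = random_states(1, seed=5)[0]
        st_ = state_of(F)
        p1 = MaterialParameters(K=2.0, mu=0.1, k1=0.04, k2=200.0)
        p2 = p1.replace(k1=0.08)
        diff = cauchy_stress(st_, p2, FIBER) - cauchy_stress(st_, p1, FIBER)
        _, _, sk1 = stress_decomposition(st_, FIBER, k2=200.0)
        np.testing.assert_allclose(diff, 0.04 * sk1, atol=1e-13)


class TestModelLimits:
    def test_isotropy_limit_rotation_invariance(self):
        """With k1 = 0 the stress is independent of fiber orientation."""
        params = MaterialParameters(K=3.0, mu=0.2, k1=0.0, k2=50.0)
        F = random_states(1, seed=9)[0]
        st_ = state_of(F)
        a = np.array([1.0, 2.0, -1.0]) / np.sqrt(6.0)
        rot = FiberPoint(a1=a, a2=np.array([0.0, 0.0, 1.0]), kappa=0.2)
        np.testing.assert_allclose(cauchy_stress(st_, params, FIBER),
                                   cauchy_stress(st_, params, rot),
                                   atol=1e-14)

    def test_full_dispersion_erases_fiber_direction(self):
        """At kappa = 1/3 only the isotropic invariant survives."""
        params = MaterialParameters(K=1.0, mu=0.1, k1=0.05, k2=100.0)
        F = random_states(1, seed=13)[0]
        a = np.array([3.0, 1.0, 2.0]) / np.sqrt(14.0)
        f1 = FiberPoint(a1=EX, a2=EY, kappa=1.0 / 3.0)
        f2 = FiberPoint(a1=a, a2=np.array([0.0, 1.0, 0.0]), kappa=1.0 / 3.0)
        np.testing.assert_allclose(
            cauchy_stress(state_of(F, f1), params, f1),
            cauchy_stress(state_of(F, f2), params, f2), atol=1e-13)

    def test_small_k2_series_limit(self):
        """psi_ti -> (k1/2)(I4*-1)^2 as k2 -> 0, continuous at the branch."""
        fib = FiberPoint(a1=EX, a2=EY, kappa=0.0)
        s = np.sqrt(1.04)
        F = np.diag([s, 1 / np.sqrt(s), 1 / np.sqrt(s)])
        st_ = state_of(F, fib)
        x = 0.04
        lo = strain_energy(st_, MaterialParameters(0, 0, 1.0, 1e-9), fib)
        assert lo == pytest.approx(0.5 * x * x, rel=1e-6)
        below = strain_energy(st_, MaterialParameters(0, 0, 1.0, 9.9e-7), fib)
        above = strain_energy(st_, MaterialParameters(0, 0, 1.0, 1.01e-6),
                              fib)
        assert below == pytest.approx(above, rel=1e-9)


class TestPlateRigidity:
    def test_unit_construction(self):
        assert plate_rigidity(PlateLayer(E=12.0, t=1.0, nu=0.0)) == \
            pytest.approx(1.0)

    def test_bowman_layer(self):
        val = plate_rigidity(PlateLayer(E=17e3, t=10e-6, nu=0.49))
        assert val == pytest.approx(1.864e-12, rel=1e-3)

    def test_poisson_factor_structure(self):
        r = (plate_rigidity(PlateLayer(E=1.0, t=1.0, nu=0.3))
             / plate_rigidity(PlateLayer(E=1.0, t=1.0, nu=0.0)))
        assert r == pytest.approx(1.0 / (1.0 - 0.09), rel=1e-12)

    @pytest.mark.parametrize("nu", [-0.1, 0.5, 1.0])
    def test_poisson_domain(self, nu):
        with pytest.raises(ValueError):
            PlateLayer(E=1.0, t=1.0, nu=nu)


class TestValidation:
    @pytest.mark.parametrize("kw", [
        {"K": -1.0}, {"mu": -0.1}, {"k1": -0.01}, {"k2": -5.0},
    ])
    def test_negative_parameters_rejected(self, kw):
        base = dict(K=1.0, mu=0.1, k1=0.01, k2=100.0)
        base.update(kw)
        with pytest.raises(ValueError):
            MaterialParameters(**base)

    def test_fiber_validation(self):
        with pytest.raises(ValueError):
            FiberPoint(a1=np.array([2.0, 0, 0]), a2=EY, kappa=0.1)
        with pytest.raises(ValueError):
            FiberPoint(a1=EX, a2=EY, kappa=0.5)

    def test_variance_correction_needs_coefficients(self):
        with pytest.raises(ValueError):
            MaterialParameters(K=1, mu=0.1, k1=0.01, k2=10,
                               variance_correction_enabled=True)
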