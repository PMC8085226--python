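"""Stability matrix assembly, mode energies and the quadrature oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tubestab import (
    Environment,
    LoadState,
    Mode,
    ModeAmplitudes,
    ShellMaterial,
    TubeGeometry,
    energy_numeric_oracle,
    homogeneous_strain,
    is_mode_stable,
    mode_energy,
    scan_stability,
    stability_matrix,
)
from tubestab.critical_analysis import (
    corrugation_critical_stress,
    corrugation_wavevector,
)

from conftest import single_mode_field


class TestHomogeneousStrain:
    def test_unloaded(self, unit_material, unit_geometry):
        s = homogeneous_strain(unit_material, unit_geometry, LoadState())
        assert s.eps_phiphi0 == 0.0 and s.eps_zz0 == 0.0

    @pytest.mark.parametrize(
        "deltaP, sigma_zz, eps_phi, eps_z",
        [
            (0.01, 0.0, 3.125e-3, 6.25e-4),
            (0.0, 0.01, -1.25e-3, 3.75e-3),
        ],
    )
    def test_printed_expressions(self, unit_material, unit_geometry, deltaP, sigma_zz, eps_phi, eps_z):
        s = homogeneous_strain(unit_material, unit_geometry, LoadState(deltaP, sigma_zz))
        assert s.eps_phiphi0 == pytest.approx(eps_phi, rel=1e-12)
        assert s.eps_zz0 == pytest.approx(eps_z, rel=1e-12)


class TestStabilityMatrix:
    def test_axisymmetric_entries(self):
        mat = ShellMaterial(lam=1.0, mu=1.0, kappa=0.01)
        geo = TubeGeometry(R=1.0, L=50.0)
        M = stability_matrix(mat, geo, LoadState(), mode=Mode(0, 1.0)).M
        assert M[0, 0] == pytest.approx(3.01)
        assert M[1, 1] == pytest.approx(1.0)
        assert M[2, 2] == pytest.approx(3.0)
        assert M[0, 2] == pytest.approx(-1j)
        assert M[2, 0] == pytest.approx(1j)
        assert M[0, 1] == M[1, 0] == M[1, 2] == M[2, 1] == 0.0

    def test_zero_mode_is_diagonal_with_rigid_rows(self, unit_material, unit_geometry):
        M = stability_matrix(
            unit_material, unit_geometry, LoadState(0.02, -0.01), mode=Mode(0, 0.0)
        ).M
        lam, mu, R = unit_material.lam, unit_material.mu, unit_geometry.R
        expected = np.zeros((3, 3), dtype=complex)
        expected[0, 0] = (lam + 2 * mu) / R**2 + 0.02 * (0 - 2) / (2 * R)
        np.testing.assert_allclose(M, expected, atol=1e-14)

    @pytest.mark.parametrize("loads", [(0.0, 0.0), (0.03, -0.02), (-0.01, 0.05)])
    def test_goldstone_bending_mode(self, unit_material, unit_geometry, loads):
        """det M(n=1, k=0) vanishes at any loads for the free tube and is
        lifted by radial pinning."""
        Mm = stability_matrix(
            unit_material, unit_geometry, LoadState(*loads), mode=Mode(1, 0.0)
        )
        scale = np.max(np.abs(Mm.M)) ** 3
        assert abs(Mm.det) < 1e-12 * scale
        pinned = stability_matrix(
            unit_material, unit_geometry, LoadState(*loads),
            Environment(C=0.05), Mode(1, 0.0),
        )
        assert pinned.det > 1e-6 * scale

    @given(
        lam=st.floats(-0.3, 5.0),
        mu=st.floats(0.1, 5.0),
        kappa=st.floats(0.0, 0.1),
        deltaP=st.floats(-0.1, 0.1),
        sigma=st.floats(-0.1, 0.1),
        C=st.floats(0.0, 0.5),
        n=st.integers(0, 6),
        k=st.floats(0.0, 20.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_hermitian_with_real_det(self, lam, mu, kappa, deltaP, sigma, C, n, k):
        mat = ShellMaterial(lam=lam, mu=mu, kappa=kappa)
        geo = TubeGeometry(R=1.3, L=40.0)
        Mm = stability_matrix(mat, geo, LoadState(deltaP, sigma), Environment(C), Mode(n, k))
        np.testing.assert_array_equal(Mm.M, np.conj(Mm.M.T))
        d = np.linalg.det(Mm.M)
        assert abs(d.imag) <= 1e-10 * max(abs(d), np.max(np.abs(Mm.M)) ** 3)


class TestModeEnergy:
    def test_zero_amplitudes(self, unit_material, unit_geometry):
        Mm = stability_matrix(unit_material, unit_geometry, LoadState(), mode=Mode(0, 1.0))
        assert mode_energy(Mm, ModeAmplitudes((0.0, 0.0, 0.0)), unit_geometry) == 0.0

    def test_radial_unit_amplitude(self):
        mat = ShellMaterial(lam=1.0, mu=1.0, kappa=0.01)
        geo = TubeGeometry(R=1.0, L=50.0)
        Mm = stability_matrix(mat, geo, LoadState(), mode=Mode(0, 1.0))
        e = mode_energy(Mm, ModeAmplitudes((1.0, 0.0, 0.0)), geo)
        assert e == pytest.approx(2 * np.pi * geo.R * geo.L * 3.01, rel=1e-12)

    def test_energy_is_real_for_random_amplitudes(self, unit_material, unit_geometry):
        rng = np.random.default_rng(7)
        Mm = stability_matrix(
            unit_material, unit_geometry, LoadState(0.01, -0.02), mode=Mode(2, 0.7)
        )
        for _ in range(10):
            a = rng.normal(size=3) + 1j * rng.normal(size=3)
            e = mode_energy(Mm, ModeAmplitudes(tuple(a)), unit_geometry)
            assert np.isreal(e)


class TestEnergyOracle:
    def test_zero_field(self, unit_material, unit_geometry):
        field = np.zeros((3, 32, 64))
        e = energy_numeric_oracle(field, unit_material, unit_geometry, LoadState(0.02, -0.01))
        assert e == 0.0

    def test_matches_quadratic_form_on_random_modes(self):
        """Independent surface quadrature of the energy density equals the
        per-mode Hermitian form for random materials, loads and modes."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            mat = ShellMaterial(
                lam=rng.uniform(0.2, 2.0), mu=rng.uniform(0.2, 2.0),
                kappa=rng.uniform(1e-4, 1e-2),
            )
            geo = TubeGeometry(R=rng.uniform(0.5, 2.0), L=rng.uniform(10.0, 40.0))
            load = LoadState(rng.uniform(-0.02, 0.02), rng.uniform(-0.02, 0.02))
            env = Environment(rng.uniform(0.0, 0.05))
            mode = Mode.from_m(int(rng.integers(0, 4)), int(rng.integers(1, 6)), geo)
            amps = tuple(rng.normal(size=3) + 1j * rng.normal(size=3))
            Mm = stability_matrix(mat, geo, load, env, mode)
            expected = mode_energy(Mm, ModeAmplitudes(amps), geo)
            field = single_mode_field(mode, amps, 96, 512, geo.L)
            numeric = energy_numeric_oracle(field, mat, geo, load, env)
            assert numeric == pytest.approx(expected, rel=2e-6, abs=1e-12)

    def test_volume_stretch_coupling_is_the_reported_residual(self, unit_geometry):
        """Dropping the volume-stretch cross term shifts only the
        radial-axial coupling, by deltaP*R/2 worth of M13."""
        mat = ShellMaterial(lam=1.0, mu=1.0, kappa=1e-3)
        geo = unit_geometry
        load = LoadState(deltaP=0.02, sigma_zz=0.0)
        mode = Mode.from_m(0, 3, geo)
        amps = (0.7 + 0.2j, 0.0, 0.3 - 0.5j)
        field = single_mode_field(mode, amps, 32, 256, geo.L)
        full = energy_numeric_oracle(field, mat, geo, load)
        partial = energy_numeric_oracle(
            field, mat, geo, load, include_volume_stretch_coupling=False
        )
        a = np.asarray(amps)
        # missing density term: -(dP/2) u_r dz(u_z); on the conjugate pair it
        # integrates to 2*pi*R*L * dP * k * Im(A_r conj(A_z)) ... sign per the
        # stored-mode convention
        k = mode.k
        delta_expected = (
            -2 * np.pi * geo.R * geo.L * load.deltaP * k * float(np.imag(a[0] * np.conj(a[2])))
        )
        assert full - partial == pytest.approx(delta_expected, rel=1e-6)

    def test_azimuthal_ripple_has_no_linear_pressure_work(self, unit_material, unit_geometry):
        """u_phi = cos(n phi): the pressure work has no linear part, so the
        energy is exactly quadratic in the ripple amplitude."""
        mode = Mode(3, 0.0)
        load = LoadState(deltaP=0.05)
        e1 = energy_numeric_oracle(
            single_mode_field(mode, (0.0, 0.5, 0.0), 64, 64, unit_geometry.L),
            unit_material, unit_geometry, load,
        )
        e2 = energy_numeric_oracle(
            single_mode_field(mode, (0.0, 1.0, 0.0), 64, 64, unit_geometry.L),
            unit_material, unit_geometry, load,
        )
        assert e2 == pytest.approx(4.0 * e1, rel=1e-10)

    def test_rejects_bad_grids(self, unit_material, unit_geometry):
        with pytest.raises(ValueError):
            energy_numeric_oracle(
                np.zeros((2, 32, 32)), unit_material, unit_geometry, LoadState()
            )
        with pytest.raises(ValueError):
            energy_numeric_oracle(
                np.zeros((3, 4, 32)), unit_material, unit_geometry, LoadState()
            )


class TestStabilityScan:
    def test_unloaded_tube_is_stable(self, unit_material, unit_geometry):
        report = scan_stability(unit_material, unit_geometry, LoadState(), n_max=6)
        assert report.stable
        assert report.violating == []

    def test_axial_compression_destabilizes_corrugation_mode(self, unit_material, unit_geometry):
        """Slightly past the corrugation threshold the axisymmetric (n = 0)
        row develops violations with k clustering near the predicted wave
        vector; slightly before it, the row is clean."""
        thr = corrugation_critical_stress(unit_material, unit_geometry).critical_value
        k_star = corrugation_wavevector(unit_material, unit_geometry)
        past = scan_stability(
            unit_material, unit_geometry, LoadState(sigma_zz=1.002 * thr), n_max=4
        )
        assert not past.stable
        ks = np.array([k for n, k in past.violating if n == 0])
        assert len(ks) > 0
        assert np.all(np.abs(ks - k_star) / k_star < 0.5)
        before = scan_stability(
            unit_material, unit_geometry, LoadState(sigma_zz=0.998 * thr), n_max=4
        )
        assert all(n != 0 for n, _ in before.violating)

    def test_external_pressure_ovalizes(self, unit_material, unit_geometry):
        """deltaP below -3 kappa/R^3 violates the (n=2, k=0) mode."""
        kappa, R = unit_material.kappa, unit_geometry.R
        report = scan_stability(
            unit_material, unit_geometry, LoadState(deltaP=-3.3 * kappa / R**3), n_max=6
        )
        assert (2, 0.0) in report.violating

    def test_rigid_modes_never_flagged(self, unit_material, unit_geometry):
        report = scan_stability(
            unit_material, unit_geometry, LoadState(deltaP=0.02, sigma_zz=-0.01), n_max=3
        )
        assert all(not (k == 0.0 and n <= 1) for n, k in report.violating)

    def test_single_mode_stability_predicate(self, unit_material, unit_geometry):
        stable = stability_matrix(unit_material, unit_geometry, LoadState(), mode=Mode(0, 2.0))
        assert is_mode_stable(stable)
        unstable = stability_matrix(
            unit_material, unit_geometry, LoadState(sigma_zz=-0.1),
            mode=Mode(0, corrugation_wavevector(unit_material, unit_geometry)),
        )
        assert not is_mode_stable(unstable)
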