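"""Geometry: coordinates, the volume-preserving mapping, deformation
tensors and volume constructions."""

import numpy as np
import pytest

from lvdyn.geometry import (DomainExitError, KinematicState,
                            ReferenceGeometry, SHAPE_PRESETS,
                            build_matched_shape, cavity_volume,
                            deformation_tensors, jacobian_determinant,
                            material_wall_volume, prolate_to_cartesian,
                            solve_mapped_mu, strain_derivatives, torsion_phi,
                            volume_gradient, wall_volume)

NORMAL = SHAPE_PRESETS["normal"]

# deformation states spanning the range reached during simulated cycles
STATES = [
    KinematicState(),
    KinematicState(a1=-0.4, a2=0.3, a3=-0.2),
    KinematicState(a1=0.3, a2=-0.25, a3=0.15),
    KinematicState(a1=-0.3, a2=0.2, a3=0.0),
]


def _wall_grid(geom, n_mu=9, n_nu=11, nu_eps=0.0):
    mu0 = np.linspace(geom.mu_in0, geom.mu_out0, n_mu)
    nu0 = np.linspace(geom.nu_up, np.pi - nu_eps, n_nu)
    M, N = np.meshgrid(mu0, nu0, indexing="ij")
    return M.ravel(), N.ravel()


class TestCoordinates:
    def test_pole_maps_to_unit_z(self):
        assert prolate_to_cartesian(1.0, 0.0, 0.0, 0.0) == (0.0, 0.0, 1.0)

    def test_equator_has_zero_z(self):
        _, _, z = prolate_to_cartesian(2.0, 0.7, np.pi / 2, 0.0)
        assert z == pytest.approx(0.0, abs=1e-15)

    def test_jacobian_determinant_closed_form(self):
        val = jacobian_determinant(1.0, 1.0, np.pi / 2)
        assert val == pytest.approx(np.sinh(1.0) * np.cosh(1.0) ** 2,
                                    rel=1e-14)


class TestMapping:
    def test_identity_at_zero_state(self):
        mu0, nu0 = _wall_grid(NORMAL)
        mu, dmm, dmn = solve_mapped_mu(NORMAL, KinematicState(), mu0, nu0)
        np.testing.assert_allclose(mu, mu0, rtol=1e-13)
        np.testing.assert_allclose(dmm, 1.0, rtol=1e-12)
        np.testing.assert_allclose(dmn, 0.0, atol=1e-13)

    def test_mapped_mu_strictly_increasing_in_mu0(self):
        state = KinematicState(a1=-0.3, a2=0.2)
        mu0 = np.linspace(NORMAL.mu_in0, NORMAL.mu_out0, 9)
        for nu in np.linspace(NORMAL.nu_up, np.pi - 1e-6, 11):
            mu, _, _ = solve_mapped_mu(NORMAL, state, mu0,
                                       np.full_like(mu0, nu))
            assert np.all(np.diff(mu) > 0)

    def test_torsion_vanishes_at_base_and_without_a3(self):
        st = KinematicState(a3=0.1)
        assert torsion_phi(st, NORMAL.nu_up, 0.3, NORMAL.nu_up) == 0.3
        assert torsion_phi(KinematicState(), 2.0, 0.3, NORMAL.nu_up) == 0.3

    def test_torsion_value_at_apex(self):
        st = KinematicState(a3=0.1)
        expected = 0.3 + 0.1 * (-1.0 - np.cos(1.1112))
        assert torsion_phi(st, np.pi, 0.3, 1.1112) == pytest.approx(
            expected, rel=1e-14)

    def test_domain_exit_reported_for_extreme_contraction(self):
        mu0, nu0 = _wall_grid(NORMAL)
        with pytest.raises(DomainExitError):
            solve_mapped_mu(NORMAL, KinematicState(a2=20.0), mu0, nu0)


class TestDeformationTensors:
    @pytest.mark.parametrize("state", STATES)
    def test_det_F_is_one_everywhere(self, state):
        mu0, nu0 = _wall_grid(NORMAL)
        kin = deformation_tensors(NORMAL, state, mu0, nu0)
        np.testing.assert_allclose(kin["detF"], 1.0, atol=1e-8)

    def test_zero_state_gives_identity_and_zero_strain(self):
        mu0, nu0 = _wall_grid(NORMAL)
        kin = deformation_tensors(NORMAL, KinematicState(), mu0, nu0)
        np.testing.assert_allclose(kin["F"], np.broadcast_to(
            np.eye(3), kin["F"].shape), atol=1e-12)
        np.testing.assert_allclose(kin["E"], 0.0, atol=1e-12)

    def test_F_matches_finite_differences_of_mapped_positions(self):
        """F columns are the derivatives of the deformed position with
        respect to reference arc length along each coordinate."""
        state = KinematicState(a1=-0.4, a2=0.3, a3=-0.2)
        m0, n0, p0 = 0.5, 2.2, 0.3
        h = 1e-6

        def pos(mm, nn, pp):
            mu, _, _ = solve_mapped_mu(NORMAL, state, np.array([mm]),
                                       np.array([nn]))
            phi = torsion_phi(state, nn, pp, NORMAL.nu_up)
            return np.array(prolate_to_cartesian(
                NORMAL.a0 + state.a1, mu[0], nn, phi))

        g0 = NORMAL.a0 * np.sqrt(np.sinh(m0) ** 2 + np.sin(n0) ** 2)
        g0phi = NORMAL.a0 * np.sinh(m0) * np.sin(n0)
        cols = []
        for dm, dn, dp, gref in [(h, 0, 0, g0), (0, h, 0, g0),
                                 (0, 0, h, g0phi)]:
            d = (pos(m0 + dm, n0 + dn, p0 + dp)
                 - pos(m0 - dm, n0 - dn, p0 - dp)) / (2 * h)
            cols.append(d / gref)
        F_cart = np.array(cols).T
        kin = deformation_tensors(NORMAL, state, np.array([m0]),
                                  np.array([n0]))
        # compare the frame-invariant C = F^T F
        np.testing.assert_allclose(F_cart.T @ F_cart, kin["C"][0],
                                   rtol=2e-5, atol=2e-8)

    @pytest.mark.parametrize("i", [0, 1, 2])
    def test_strain_derivatives_match_richardson_differences(self, i):
        state = KinematicState(a1=-0.2, a2=0.15, a3=-0.1)
        mu0, nu0 = _wall_grid(NORMAL, 5, 5)
        dE = strain_derivatives(NORMAL, state, mu0, nu0)[i]

        def E_at(delta):
            s = KinematicState(state.a1, state.a2, state.a3)
            setattr(s, f"a{i + 1}", getattr(s, f"a{i + 1}") + delta)
            return deformation_tensors(NORMAL, s, mu0, nu0)["E"]

        h = 1e-4
        d1 = (E_at(h) - E_at(-h)) / (2 * h)
        d2 = (E_at(h / 2) - E_at(-h / 2)) / h
        rich = (4 * d2 - d1) / 3
        np.testing.assert_allclose(dE, rich, rtol=1e-6, atol=1e-9)


class TestVolumes:
    @pytest.mark.parametrize("name", sorted(SHAPE_PRESETS))
    def test_reference_volumes_match_tabulated(self, name):
        g = SHAPE_PRESETS[name]
        assert cavity_volume(g) == pytest.approx(59.8714, rel=5e-5)
        assert wall_volume(g) == pytest.approx(158.112, rel=5e-5)

    def test_quadrature_matches_closed_form(self):
        g = NORMAL
        closed = (np.pi * g.a0**3 * np.sinh(g.mu_in0) ** 2
                  * np.cosh(g.mu_in0) * g._sin3_integral)
        assert cavity_volume(g) == pytest.approx(closed, rel=1e-7)

    def test_half_spheroid_closed_form(self):
        g = ReferenceGeometry(3.0, 0.5, 0.8, np.pi / 2)
        expected = (2 * np.pi / 3) * 27 * np.sinh(0.5) ** 2 * np.cosh(0.5)
        assert cavity_volume(g) == pytest.approx(expected, rel=1e-7)
        assert g.cavity_volume0() == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("state", STATES[1:])
    def test_material_wall_volume_invariant_under_mapping(self, state):
        ref = material_wall_volume(NORMAL)
        deformed = material_wall_volume(NORMAL, state)
        assert abs(deformed - ref) / ref < 1e-6

    def test_torsion_does_not_change_cavity_volume(self):
        v0 = cavity_volume(NORMAL, KinematicState(a1=-0.2, a2=0.1))
        v3 = cavity_volume(NORMAL, KinematicState(a1=-0.2, a2=0.1, a3=0.5))
        assert v3 == pytest.approx(v0, rel=1e-14)

    def test_volume_gradient_consistent_across_steps(self):
        """dV/da from the default step agrees with a 10x larger step to
        quadratic accuracy (validating the central-difference gradient)."""
        st = KinematicState(a1=-0.2, a2=0.1)
        g1 = volume_gradient(NORMAL, st, h=1e-6)
        g2 = volume_gradient(NORMAL, st, h=1e-5)
        np.testing.assert_allclose(g1, g2, rtol=1e-6)


class TestMatchedShapes:
    @pytest.mark.parametrize("name,mu_in,mu_out", [
        ("spherical", 0.7470308, 1.1173771),
        ("ellipsoidal", 0.235, 0.426),
    ])
    def test_inversion_reproduces_tabulated_coordinates(self, name, mu_in,
                                                        mu_out):
        a0 = SHAPE_PRESETS[name].a0
        g = build_matched_shape(59.8714, 158.112, a0, 1.1112)
        assert g.mu_in0 == pytest.approx(mu_in, abs=5e-5)
        assert g.mu_out0 == pytest.approx(mu_out, abs=5e-5)

    def test_round_trip(self):
        g = build_matched_shape(59.8714, 158.112, 4.0, np.pi / 2)
        assert g.cavity_volume0() == pytest.approx(59.8714, rel=1e-9)
        assert g.wall_volume0() == pytest.approx(158.112, rel=1e-9)

    def test_infeasible_target_raises(self):
        with pytest.raises(ValueError):
            build_matched_shape(-1.0, 10.0, 4.0, 1.1112)


def test_invalid_reference_geometry_rejected():
    with pytest.raises(ValueError):
        ReferenceGeometry(4.6, 0.7, 0.4, 1.1)
    with pytest.raises(ValueError):
        ReferenceGeometry(4.6, 0.4, 0.7, 0.0)
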