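"""Dipole field models and lead-field assembly.

The conducting-sphere field is checked against closed-form properties
(radial-source silence, vanishing radial field over a tangential source,
radial equality with the primary-current term) and against an
independent numerical oracle that reconstructs the full external field
from the magnetic scalar potential (radially integrated primary-current
radial field, differentiated numerically).
"""

import numpy as np
import pytest
from scipy.integrate import quad

from triaxmeg.errors import DomainError
from triaxmeg.forward import (
    MU0,
    CurrentDipole,
    assemble_lead_field,
    dipole_field_freespace,
    dipole_field_sphere,
)
from triaxmeg.geometry import (
    build_sensor_array,
    equidistant_sphere_points,
    erode_source_surface,
)

POINTS = 0.1 * equidistant_sphere_points(24) + np.array([0.0, 0.0, 0.01])


class TestSphereModel:
    def test_radial_dipole_is_silent(self):
        pos = np.array([0.01, 0.02, 0.03])
        dip = CurrentDipole(pos, 2e-6 * pos / np.linalg.norm(pos))
        B = dipole_field_sphere(dip, POINTS)
        assert np.max(np.abs(B)) < 1e-15 * 2e-6 / 0.05**2

    def test_radial_field_zero_directly_above_tangential_dipole(self):
        pos = np.array([0.0, 0.0, 0.03])
        dip = CurrentDipole(pos, [2e-6, 0.0, 0.0])  # tangential
        point = np.array([[0.0, 0.0, 0.09]])  # radially above
        B = dipole_field_sphere(dip, point)[0]
        r_hat = np.array([0.0, 0.0, 1.0])
        assert abs(B @ r_hat) < 1e-15 * np.linalg.norm(B)

    def test_radial_component_matches_freespace_formula(self):
        dip = CurrentDipole([0.01, 0.02, 0.03], [1e-6, -2e-6, 0.5e-6])
        B_sph = dipole_field_sphere(dip, POINTS)
        B_fs = dipole_field_freespace(dip, POINTS)
        r_hat = POINTS / np.linalg.norm(POINTS, axis=1, keepdims=True)
        br_sph = np.einsum("ij,ij->i", B_sph, r_hat)
        br_fs = np.einsum("ij,ij->i", B_fs, r_hat)
        np.testing.assert_allclose(
            br_sph, br_fs, rtol=1e-12, atol=1e-12 * np.abs(br_fs).max()
        )

    def test_dipole_at_center_returns_zero(self):
        dip = CurrentDipole(np.zeros(3), [1e-6, 0, 0])
        assert np.all(dipole_field_sphere(dip, POINTS) == 0)

    def test_point_inside_conductor_rejected(self):
        dip = CurrentDipole([0.0, 0.0, 0.02], [1e-6, 0, 0])
        with pytest.raises(DomainError):
            dipole_field_sphere(
                dip, np.array([[0.0, 0.0, 0.04]]), conductor_radius=0.055
            )

    def test_linearity_and_superposition(self):
        p1 = CurrentDipole([0.01, 0.0, 0.03], [1e-6, 0, 1e-7])
        p2 = CurrentDipole([0.01, 0.0, 0.03], [0, -2e-6, 1e-7])
        both = CurrentDipole([0.01, 0.0, 0.03], p1.moment + p2.moment)
        B = dipole_field_sphere(both, POINTS)
        np.testing.assert_allclose(
            B,
            dipole_field_sphere(p1, POINTS) + dipole_field_sphere(p2, POINTS),
            rtol=1e-12,
        )
        scaled = CurrentDipole(p1.position, 3.0 * p1.moment)
        np.testing.assert_allclose(
            dipole_field_sphere(scaled, POINTS),
            3.0 * dipole_field_sphere(p1, POINTS),
            rtol=1e-12,
        )

    def test_full_field_against_scalar_potential_oracle(self):
        """Independent route: outside the conductor B = -mu0 grad U with
        U obtained by radially integrating the primary-current radial
        field; tangential components follow by numerical
        differentiation.  Agreement within the 5 % oracle tolerance."""
        dip = CurrentDipole([0.01, 0.02, 0.03], [3e-6, -1e-6, 2e-6])

        def U(point):
            point = np.asarray(point, float)
            r = np.linalg.norm(point)
            r_hat = point / r

            def integrand(u):
                s = r / u
                br = dipole_field_freespace(dip, (s * r_hat)[None, :])[0] @ r_hat
                return br * r / u**2

            val, _ = quad(integrand, 0.0, 1.0, limit=200, epsrel=1e-10)
            return val / MU0

        def oracle(point):
            r = np.linalg.norm(point)
            th = np.arccos(point[2] / r)
            ph = np.arctan2(point[1], point[0])

            def cart(r_, th_, ph_):
                return np.array(
                    [
                        r_ * np.sin(th_) * np.cos(ph_),
                        r_ * np.sin(th_) * np.sin(ph_),
                        r_ * np.cos(th_),
                    ]
                )

            h = 1e-6
            br = -MU0 * (U(cart(r + h, th, ph)) - U(cart(r - h, th, ph))) / (2 * h)
            bth = -MU0 * (U(cart(r, th + h, ph)) - U(cart(r, th - h, ph))) / (2 * h * r)
            bph = -MU0 * (
                U(cart(r, th, ph + h)) - U(cart(r, th, ph - h))
            ) / (2 * h * r * np.sin(th))
            r_hat = cart(1.0, th, ph)
            th_hat = np.array(
                [np.cos(th) * np.cos(ph), np.cos(th) * np.sin(ph), -np.sin(th)]
            )
            ph_hat = np.array([-np.sin(ph), np.cos(ph), 0.0])
            return br * r_hat + bth * th_hat + bph * ph_hat

        for pt in ([0.06, 0.02, 0.08], [-0.05, -0.06, 0.07], [0.02, -0.04, 0.09]):
            pt = np.array(pt)
            B = dipole_field_sphere(dip, pt[None, :])[0]
            assert np.linalg.norm(B - oracle(pt)) / np.linalg.norm(B) < 0.05


class TestFreespaceModel:
    def test_perpendicular_amplitude_arithmetic(self):
        # Q = 2 uAm perpendicular to the 5 cm separation: |B| = 1e-7 * Q / r^2
        dip = CurrentDipole(np.zeros(3), [0.0, 0.0, 2e-6])
        B = dipole_field_freespace(dip, np.array([[0.05, 0.0, 0.0]]))[0]
        assert np.linalg.norm(B) == pytest.approx(80e-12, rel=1e-12)

    def test_moment_parallel_to_separation_is_zero(self):
        dip = CurrentDipole(np.zeros(3), [1e-6, 0, 0])
        B = dipole_field_freespace(dip, np.array([[0.07, 0.0, 0.0]]))
        assert np.all(B == 0)

    def test_inverse_square_falloff(self):
        dip = CurrentDipole(np.zeros(3), [0.0, 1e-6, 0.0])
        b1 = np.linalg.norm(dipole_field_freespace(dip, np.array([[0.05, 0, 0]])))
        b2 = np.linalg.norm(dipole_field_freespace(dip, np.array([[0.10, 0, 0]])))
        assert b1 / b2 == pytest.approx(4.0, rel=1e-12)

    def test_coincident_point_rejected(self):
        dip = CurrentDipole(np.zeros(3), [1e-6, 0, 0])
        with pytest.raises(DomainError):
            dipole_field_freespace(dip, np.zeros((1, 3)))


class TestLeadField:
    def test_57_triaxial_sensors_give_171_rows(self, adult_head):
        # the underside cut that retains exactly 57 of the 77 points
        arr = build_sensor_array(adult_head, cut_polar_angle=np.deg2rad(118.5))
        assert arr.n_sensors == 57
        src = erode_source_surface(adult_head, spacing=0.03)
        L = assemble_lead_field(arr, src, center=adult_head.sphere_center)
        assert L.n_channels == 171

    def test_radial_subset_equals_triaxial_radial_rows(self, adult_head):
        arr = build_sensor_array(adult_head, n=20)
        src = erode_source_surface(adult_head, spacing=0.04)
        L_tri = assemble_lead_field(arr, src, center=adult_head.sphere_center)
        L_rad = assemble_lead_field(
            arr.with_axes("r"), src, center=adult_head.sphere_center
        )
        np.testing.assert_array_equal(
            L_tri.select_axes("r").matrix, L_rad.matrix
        )

    def test_beam_displacement_error_grows_for_shallow_sources(self, adult_head):
        arr = build_sensor_array(adult_head, n=30)

        def median_err(depth):
            src = erode_source_surface(adult_head, depth=depth, spacing=0.03)
            L0 = assemble_lead_field(arr, src, center=adult_head.sphere_center)
            L1 = assemble_lead_field(
                arr, src, beam_displacement=True, center=adult_head.sphere_center
            )
            err = np.linalg.norm(L1.matrix - L0.matrix, axis=0) / np.linalg.norm(
                L0.matrix, axis=0
            )
            return np.median(err)

        shallow = median_err(5e-3)
        deep = median_err(25e-3)
        assert shallow > deep > 0

    def test_lead_field_scales_with_moment(self, adult_head):
        arr = build_sensor_array(adult_head, n=12)
        src = erode_source_surface(adult_head, spacing=0.05)
        L = assemble_lead_field(arr, src, center=adult_head.sphere_center)
        # unit moment convention: field of a 2 uAm dipole is 2e-6 * column
        j = 0
        dip = CurrentDipole(src.positions[j], 2e-6 * src.frames[j, 1, :])
        B = dipole_field_sphere(dip, arr.positions, center=adult_head.sphere_center)
        pairs = arr.channel_index()
        proj = np.array([B[i] @ arr.frames[i, k, :] for i, k in pairs])
        np.testing.assert_allclose(proj, 2e-6 * L.matrix[:, j, 0], rtol=1e-12)
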