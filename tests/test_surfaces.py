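"""Surface-geometry tests: sag against exact conics, vector Snell refraction,
thin-element OPD maps of posed lenses, paraxial powers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from iolbench.surfaces import (ConicAsphericSurface, LensElement,
                               element_opd_map, interface_eikonal_profile,
                               interface_opd_map, paraxial_power,
                               refract_direction, sag, surface_power)


class TestSag:
    def test_vertex_sag_is_zero(self):
        s = ConicAsphericSurface(7.814, -0.26)
        assert sag(s, 0.0, 0.0) == 0.0

    def test_sphere_matches_exact_circle(self):
        R = 7.814
        s = ConicAsphericSurface(R, 0.0)
        expected = R - np.sqrt(R**2 - 9.0)      # r = 3 mm
        assert abs(sag(s, 3.0, 0.0) - expected) < 1e-12
        assert abs(expected - 0.5989) < 2e-4    # frozen value

    def test_paraboloid_is_exactly_quadratic(self):
        R = 10.0
        s = ConicAsphericSurface(R, -1.0)
        for r in (0.5, 2.0, 5.0, 9.0):
            assert abs(sag(s, r, 0.0) - r**2 / (2 * R)) < 1e-12

    def test_domain_violation_names_max_radius(self):
        s = ConicAsphericSurface(5.0, 0.5, semi_aperture=10.0)
        with pytest.raises(ValueError, match="r ="):
            sag(s, 6.0, 0.0)


class TestRefraction:
    def test_normal_incidence_unchanged(self):
        d = np.array([0.0, 0.0, 1.0])
        out, tir = refract_direction(d, np.array([0.0, 0.0, 1.0]), 1.0, 1.5)
        np.testing.assert_allclose(out, d, atol=1e-14)
        assert not tir

    def test_plane_snell_30_degrees(self):
        th = np.deg2rad(30.0)
        d = np.array([np.sin(th), 0.0, np.cos(th)])
        out, _ = refract_direction(d, np.array([0.0, 0.0, 1.0]), 1.0, 1.5)
        angle = np.rad2deg(np.arcsin(out[0]))
        assert abs(angle - 19.47) < 0.01

    def test_snell_invariant_random_rays(self):
        """n1 sin(theta1) = n2 sin(theta2) to 1e-12 for 10^4 random rays."""
        rng = np.random.default_rng(42)
        d = rng.normal(size=(10_000, 3))
        d[:, 2] = np.abs(d[:, 2]) + 0.5
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        nrm = rng.normal(size=(10_000, 3))
        nrm[:, 2] = np.abs(nrm[:, 2]) + 1.0
        nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
        n1, n2 = 1.336, 1.47
        out, tir = refract_direction(d, nrm, n1, n2)
        cos1 = np.abs(np.sum(d * nrm, axis=1))
        cos2 = np.abs(np.sum(out * nrm, axis=1))
        s1 = n1 * np.sqrt(1 - cos1[~tir]**2)
        s2 = n2 * np.sqrt(1 - cos2[~tir]**2)
        assert np.abs(s1 - s2).max() < 1e-12

    @given(st.floats(0.0, 60.0), st.floats(1.0, 1.8), st.floats(1.0, 1.8))
    @settings(max_examples=50, deadline=None)
    def test_snell_scalar_property(self, deg, n1, n2):
        th = np.deg2rad(deg)
        d = np.array([np.sin(th), 0.0, np.cos(th)])
        out, tir = refract_direction(d, np.array([0.0, 0.0, 1.0]), n1, n2)
        if not tir:
            assert abs(n1 * np.sin(th) - n2 * abs(out[0])) < 1e-10


def make_iol(a4=0.0, decenter=0.0, tilt=0.0):
    R = 13.3589
    return LensElement(ConicAsphericSurface(R, a4=a4, semi_aperture=3.5),
                       ConicAsphericSurface(-R, semi_aperture=3.5),
                       center_thickness=0.9, material_index=1.47,
                       decenter_y=decenter, tilt_y=tilt)


class TestElementOPD:
    def test_plane_plate_constant_opd(self):
        plate = LensElement(ConicAsphericSurface(np.inf, semi_aperture=5.0),
                            ConicAsphericSurface(np.inf, semi_aperture=5.0),
                            center_thickness=1.0, material_index=1.5195)
        x = np.linspace(-3, 3, 41)
        m = element_opd_map(plate, x[None, :], np.zeros((1, len(x))),
                            1.336, 1.336, pitch=x[1] - x[0])
        expected = (1.5195 - 1.336) * 1.0 * 1e3
        np.testing.assert_allclose(m.opd, expected, atol=1e-9)

    def test_decenter_is_translation(self):
        d_um = 300.0
        x = np.linspace(-3.3, 3.3, 221)          # 30-um pitch, multiple of d
        xx, yy = np.meshgrid(x, x)
        pitch = x[1] - x[0]
        m0 = element_opd_map(make_iol(), xx, yy, 1.336, 1.336, pitch=pitch)
        m1 = element_opd_map(make_iol(decenter=d_um), xx, yy, 1.336, 1.336,
                             pitch=pitch)
        shift = int(round(d_um * 1e-3 / pitch))
        rolled = np.roll(m0.opd, shift, axis=0)
        both = np.isfinite(rolled) & np.isfinite(m1.opd)
        both[:shift + 2] = False
        assert np.abs(rolled[both] - m1.opd[both]).max() < 1e-6

    def test_unposed_map_is_rotationally_symmetric(self):
        x = np.linspace(-3.0, 3.0, 201)
        xx, yy = np.meshgrid(x, x)
        m = element_opd_map(make_iol(a4=-2.6e-3), xx, yy, 1.336, 1.336,
                            pitch=x[1] - x[0])
        assert np.nanmax(np.abs(m.opd - m.opd.T)) < 1e-8
        assert np.nanmax(np.abs(m.opd - m.opd[::-1, ::-1])) < 1e-8

    def test_paraxial_quadratic_matches_gullstrand_power(self):
        """The OPD map's paraxial curvature gives the thick-lens power to
        0.5% (the thin-projection omits only the internal-transfer term)."""
        iol = make_iol()
        x = np.linspace(-0.5, 0.5, 101)
        m = element_opd_map(iol, x[None, :], np.zeros((1, len(x))),
                            1.336, 1.336, pitch=x[1] - x[0])
        w = (m.opd[0] - m.opd[0][50]) * 1e-3     # mm
        coef = np.polyfit(x, w, 2)[0]            # = -P/2
        P_fit = -2 * coef * 1e3                  # diopters
        P_ref = paraxial_power(iol, 1.336, 1.336)
        assert abs(P_fit - P_ref) / P_ref < 0.005

    def test_pose_envelope_enforced(self):
        with pytest.raises(ValueError, match="envelope"):
            make_iol(decenter=2500.0)
        with pytest.raises(ValueError, match="envelope"):
            make_iol(tilt=16.0)
        make_iol(decenter=800.0, tilt=8.0)       # accepted


class TestParaxialPower:
    def test_cornea_single_surface_power(self):
        radius = (1.336 - 1.0) / 0.043
        assert abs(surface_power(radius, 1.0, 1.336) - 43.0) < 1e-9

    def test_plane_plate_zero_power(self):
        plate = LensElement(ConicAsphericSurface(np.inf),
                            ConicAsphericSurface(np.inf), 1.0, 1.5195)
        assert paraxial_power(plate, 1.336, 1.336) == 0.0

    def test_iol_design_power(self):
        assert abs(paraxial_power(make_iol(), 1.336, 1.336) - 20.0) < 0.1


class TestEikonalScreen:
    def test_matches_projection_screen_paraxially(self):
        """At small radius the eikonal screen reduces to -(n2-n1) sag."""
        cornea = ConicAsphericSurface((1.336 - 1) / 0.043, -0.26,
                                      semi_aperture=5.8)
        r0, w0 = interface_eikonal_profile(cornea, 1.0, 1.336, 5.8)
        r_small = np.linspace(0.01, 0.4, 20)
        proj = interface_opd_map(cornea, r_small, np.zeros_like(r_small),
                                 1.0, 1.336)
        eik = np.interp(r_small, r0, w0)
        assert np.abs(eik - proj).max() < 5e-3   # um (~lambda/100)

    def test_deviates_from_projection_at_the_margin(self):
        """At the stop edge the finite corneal sag matters (tens of um)."""
        cornea = ConicAsphericSurface((1.336 - 1) / 0.043, -0.26,
                                      semi_aperture=5.8)
        r0, w0 = interface_eikonal_profile(cornea, 1.0, 1.336, 5.8)
        proj = interface_opd_map(cornea, np.array([4.5]), np.array([0.0]),
                                 1.0, 1.336)
        eik = np.interp(4.5, r0, w0)
        assert abs(eik - proj[0]) > 1.0          # um
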