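"""Geometry: superellipse profiles, section properties, loft, cement rings
and clinical admissibility."""

import numpy as np
import pytest
import trimesh
from scipy.special import gamma

from stemopt.errors import (ConstraintError, GeometryViolationError,
                            InvalidParameterError)
from stemopt.geometry import (Bounds, CanalSection, CrossSectionParams,
                              DesignVector, SkeletonConfig, build_stem,
                              cement_sections, cement_thickness_profile,
                              check_constraints, default_bounds,
                              default_canal_profile, export_stl,
                              make_skeleton, polar_radius, profile_point,
                              sample_surface, section_properties,
                              superellipse_area)


def two_half_area(a1, a2, b, p):
    """Independent closed form: half-superellipse areas via the gamma function."""
    g = gamma(1.0 + 1.0 / p) ** 2 / gamma(1.0 + 2.0 / p)
    return 2.0 * (a1 + a2) * b * g


class TestProfile:
    def test_circle_case_radius(self):
        cs = CrossSectionParams(6, 6, 6, 2)
        ang = np.linspace(0, 2 * np.pi, 37)
        pts = profile_point(cs, ang)
        assert np.allclose(np.linalg.norm(pts, axis=1), 6.0)

    def test_curve_closed(self):
        cs = CrossSectionParams(8, 5, 7, 3)
        p0 = profile_point(cs, 0.0)
        p1 = profile_point(cs, 2.0 * np.pi)
        assert np.linalg.norm(p0 - p1) < 1e-9

    def test_halves_join_continuously(self):
        # x ~ a*eps^(2/p) near the junction, so the gap closes like sqrt(eps)
        cs = CrossSectionParams(10, 4, 7, 4)
        eps = 1e-12
        up = profile_point(cs, np.pi / 2 - eps)
        dn = profile_point(cs, np.pi / 2 + eps)
        assert np.linalg.norm(up - dn) < 1e-4
        assert abs(profile_point(cs, np.pi / 2)[0]) < 1e-6

    def test_invalid_parameters_raise(self):
        with pytest.raises(InvalidParameterError):
            CrossSectionParams(-1, 5, 5, 2)
        with pytest.raises(InvalidParameterError):
            CrossSectionParams(5, 5, 5, 1)
        with pytest.raises(InvalidParameterError):
            CrossSectionParams(5, 5, 0, 2)

    def test_polar_radius_matches_parametric_curve(self):
        cs = CrossSectionParams(9, 6, 7, 3)
        pts = profile_point(cs, np.linspace(0, 2 * np.pi, 200, endpoint=False))
        phi = np.arctan2(pts[:, 1], pts[:, 0])
        r = np.linalg.norm(pts, axis=1)
        assert np.allclose(polar_radius(cs, phi), r, rtol=1e-10)


class TestSectionProperties:
    @pytest.mark.parametrize("cs, expected", [
        (CrossSectionParams(10, 10, 8, 2), np.pi * 10 * 8),
        (CrossSectionParams(12, 8, 8, 2), 80 * np.pi),         # two half-ellipses
        (CrossSectionParams(1, 1, 1, 4), 4 * gamma(1.25) ** 2 / gamma(1.5)),
    ])
    def test_area_examples(self, cs, expected):
        assert section_properties(cs).area == pytest.approx(expected, rel=1e-4)

    @pytest.mark.parametrize("a, b, p", [(5, 5, 2), (5, 5, 3), (7, 4, 4), (6, 9, 6)])
    def test_area_gamma_closed_form(self, a, b, p):
        cs = CrossSectionParams(a, a, b, p)
        assert section_properties(cs).area == pytest.approx(
            superellipse_area(a, b, p), rel=1e-4)

    def test_mixed_halves_area_closed_form(self):
        cs = CrossSectionParams(11, 7, 6, 3)
        assert section_properties(cs).area == pytest.approx(
            two_half_area(11, 7, 6, 3), rel=1e-4)

    def test_circle_second_moment(self):
        r = 6.0
        props = section_properties(CrossSectionParams.circle(r))
        assert props.ixx == pytest.approx(np.pi * r ** 4 / 4, rel=1e-4)
        assert props.iyy == pytest.approx(np.pi * r ** 4 / 4, rel=1e-4)
        assert props.centroid == pytest.approx((0.0, 0.0), abs=1e-9)

    def test_high_exponent_approaches_rectangle(self):
        area = section_properties(CrossSectionParams(5, 5, 5, 9)).area
        assert area < 100.0
        assert area == pytest.approx(100.0, rel=0.02)

    def test_area_monotone_in_each_parameter(self):
        base = dict(a1=6.0, a2=7.0, b=5.0, p=2)
        for key, values in [("a1", [4, 6, 8]), ("a2", [5, 7, 9]),
                            ("b", [3, 5, 7]), ("p", [2, 3, 4, 6, 9])]:
            areas = [section_properties(CrossSectionParams(**{**base, key: v})).area
                     for v in values]
            assert np.all(np.diff(areas) > 0), key

    def test_asymmetric_centroid_offset_along_frontal_axis(self):
        props = section_properties(CrossSectionParams(12, 6, 7, 2))
        assert props.centroid[0] > 0.5       # toward the larger a1 half
        assert props.centroid[1] == pytest.approx(0.0, abs=1e-9)


class TestBuildStem:
    def test_determinism_bit_identical(self, mid_design):
        s1 = build_stem(mid_design)
        s2 = build_stem(mid_design)
        assert np.array_equal(s1.profiles, s2.profiles)
        assert np.array_equal(sample_surface(s1, 48, 60), sample_surface(s2, 48, 60))

    def test_out_of_bounds_raises_with_names(self):
        b = default_bounds()
        vals = np.asarray(b.lower).copy()
        vals[0] = b.lower[0] - 1.0
        dv = DesignVector.from_array(np.maximum(vals, 0.1), b)
        with pytest.raises(ConstraintError) as exc:
            build_stem(dv)
        assert any("s2_a1" in v for v in exc.value.violations)

    @pytest.mark.parametrize("factory", [DesignVector.at_lower, DesignVector.at_upper])
    def test_extreme_configurations_loft_watertight(self, factory, tmp_path):
        stem = build_stem(factory())
        mesh = export_stl(stem, tmp_path / "stem.stl", n_u=48, n_v=80)
        assert mesh.is_watertight
        assert mesh.volume > 0

    def test_station_normals_unit_and_oriented(self):
        skel = make_skeleton()
        for st in skel.stations:
            assert np.linalg.norm(st.normal) == pytest.approx(1.0)
        # distal stations normal to the prosthesis axis direction
        for st in skel.stations[:3]:
            assert np.allclose(st.normal, [0, 0, 1])
        # neck stations share the neck direction
        for st in skel.stations[4:]:
            assert np.allclose(st.normal, skel.neck_direction)


@pytest.fixture(scope="module")
def cylinder():
    cfg = SkeletonConfig(straight=True, distal_radius=6.0)
    bounds = Bounds((1,) * 20, (50,) * 20)
    dv = DesignVector((CrossSectionParams.circle(6.0),) * 5, bounds)
    return build_stem(dv, cfg)


class TestSurfaceAndStl:
    def test_cylinder_points_on_radius(self, cylinder):
        pts = sample_surface(cylinder, 32, 50)
        r = np.linalg.norm(pts[..., :2], axis=-1)
        assert np.allclose(r, 6.0, atol=1e-8)

    def test_stl_volume_matches_analytic(self, cylinder, tmp_path):
        mesh = export_stl(cylinder, tmp_path / "cyl.stl", n_u=128, n_v=200)
        reread = trimesh.load(tmp_path / "cyl.stl")
        analytic = np.pi * 36.0 * 185.0
        assert reread.is_watertight
        assert reread.volume == pytest.approx(analytic, rel=0.01)

    def test_minimal_sampling_valid_mesh(self, cylinder, tmp_path):
        mesh = export_stl(cylinder, tmp_path / "coarse.stl", n_u=4, n_v=4)
        assert mesh.is_watertight

    def test_too_coarse_rejected(self, cylinder):
        with pytest.raises(InvalidParameterError):
            sample_surface(cylinder, 3, 10)


class TestCement:
    def test_concentric_circles_uniform_thickness(self):
        ring = cement_thickness_profile(CrossSectionParams.circle(6.0),
                                        CanalSection(8.5, 8.5))
        assert np.allclose(ring.thickness, 2.5)

    def test_ellipse_in_circle_min_at_b_axis(self):
        # dense angular sampling: min radial gap where the stem is widest
        ring = cement_thickness_profile(CrossSectionParams(6, 6, 7, 2),
                                        CanalSection(9.5, 9.5), n=4 * 720)
        assert ring.min_thickness == pytest.approx(2.5, abs=1e-6)
        k = int(np.argmin(ring.thickness))
        phi_min = ring.phi[k] % np.pi
        assert phi_min == pytest.approx(np.pi / 2, abs=0.02)

    def test_touching_canal_raises(self, mid_design):
        canal = (CanalSection(6.0, 6.0),) + default_canal_profile()[1:]
        with pytest.raises(GeometryViolationError):
            cement_sections(mid_design, canal)

    def test_rotation_invariance(self, mid_design):
        cs = mid_design.sections[0]
        canal = CanalSection(10.5, 10.5)
        base = cement_thickness_profile(cs, canal)
        rot = cement_thickness_profile(cs, canal, rotation=0.7)
        assert rot.min_thickness == pytest.approx(base.min_thickness, abs=1e-9)
        assert rot.max_thickness == pytest.approx(base.max_thickness, abs=1e-9)


class TestConstraints:
    def test_mid_design_admissible(self, mid_design):
        rep = check_constraints(mid_design)
        assert rep.admissible
        assert rep.violations == ()
        assert 2.0 <= rep.min_cement_thickness <= rep.max_cement_thickness <= 3.0

    def test_thin_cement_flagged(self, mid_design):
        canal = (CanalSection(7.2, 7.2),) + default_canal_profile()[1:]
        rep = check_constraints(mid_design, canal)     # station 1: 7.2 - 6 = 1.2 mm
        assert not rep.admissible
        assert any(v.startswith("cement_too_thin") for v in rep.violations)
        assert rep.min_cement_thickness == pytest.approx(1.2)

    def test_thick_cement_flagged(self, mid_design):
        canal = (CanalSection(9.6, 9.6),) + default_canal_profile()[1:]
        rep = check_constraints(mid_design, canal)     # station 1: 3.6 mm
        assert not rep.admissible
        assert any(v.startswith("cement_too_thick") for v in rep.violations)

    def test_taper_rule_flags_distal_bulge(self):
        b = default_bounds()
        vals = DesignVector.mid(b).to_array()
        # shrink section 3 far below section 2 -> nonmonotone areas
        vals[4:7] = [7.6, 7.6, 7.6]
        bounds = Bounds(tuple(np.minimum(b.lower, 7.0)), b.upper)
        rep = check_constraints(DesignVector.from_array(vals, bounds),
                                thickness_limits=(0.0, 99.0))
        assert any(v.startswith("taper_violation") for v in rep.violations)

    def test_report_always_returned_for_out_of_bounds(self):
        b = default_bounds()
        vals = DesignVector.mid(b).to_array()
        vals[0] += 100.0
        rep = check_constraints(DesignVector.from_array(vals, b))
        assert not rep.admissible
        assert rep.violation_magnitude > 0
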