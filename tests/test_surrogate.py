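"""Composite-beam surrogate solver: closed-form limits, composite-section
oracles, equilibrium and the CSV stress-field interface."""

import numpy as np
import pytest

from stemopt.errors import InvalidParameterError, ParseError
from stemopt.fixtures import make_surrogate_femur
from stemopt.geometry import (Bounds, CanalSection, CrossSectionParams,
                              DesignVector, SkeletonConfig)
from stemopt.materials import Material, builtin_catalog, default_fgm_layout
from stemopt.surrogate import (CementStressField, Load, LoadCase,
                               StressSamples, default_femur,
                               export_cement_field, export_stress_samples,
                               import_stress_field, make_assembly,
                               point_loads, solve_implanted, solve_intact)

BONE = builtin_catalog()["bone"]


def uniform_tube(ro=14.0, rc=7.0, length=250.0):
    return make_surrogate_femur(outer_radius=ro, canal_radius=rc, length=length)


class TestIntact:
    def test_zero_loads_zero_field(self):
        s = solve_intact(uniform_tube(), [], grid=(10, 8))
        assert np.all(s.sigma == 0.0)

    def test_pure_axial_force_over_area(self):
        femur = uniform_tube()
        F = 1000.0
        s = solve_intact(femur, [Load(0.0, femur.length, 0.0, -F)], grid=(10, 8))
        area = np.pi * (14.0 ** 2 - 7.0 ** 2)
        assert np.allclose(s.sigma, F / area, rtol=1e-12)

    def test_tip_moment_closed_form(self):
        femur = uniform_tube()
        M = 5.0e4  # N mm
        s = solve_intact(femur, [Load(0.0, femur.length, 0.0, 0.0, mx=M)],
                         grid=(10, 16))
        inertia = np.pi / 4 * (14.0 ** 4 - 7.0 ** 4)
        expected = M * 14.0 * np.abs(np.sin(s.theta)) / inertia
        assert np.allclose(s.sigma, expected[None, :], rtol=1e-10)

    def test_default_load_case_produces_bending_gradient(self):
        s = solve_intact(default_femur(), LoadCase(), grid=(20, 16))
        assert s.sigma.max() > s.sigma.min() >= 0.0
        assert s.n == 20 * 16

    def test_grid_too_coarse_rejected(self):
        with pytest.raises(InvalidParameterError):
            solve_intact(uniform_tube(), LoadCase(), grid=(3, 8))


def circular_assembly(r_stem=7.0, rc=10.0, e_stem=110.0, e_cem=2.28,
                      femur=None):
    """Concentric circular composite: stem r_stem in canal rc, uniform tube."""
    femur = femur or uniform_tube(ro=14.0, rc=rc)
    bounds = Bounds((1,) * 20, (50,) * 20)
    dv = DesignVector((CrossSectionParams.circle(r_stem),) * 5, bounds)
    return make_assembly(
        dv, femur=femur,
        skel_config=SkeletonConfig(straight=True, distal_radius=r_stem),
        canal_profile=(CanalSection(rc, rc),) * 4,
        stem_material=Material("stem", e_stem),
        cement=Material("cem", e_cem),
        insertion_depth=150.0)


class TestImplanted:
    def test_homogeneous_limit_matches_intact(self, mid_design):
        femur = default_femur(core_modulus=18.6)
        bone_like = Material("bonelike", 18.6)
        asm = make_assembly(mid_design, femur=femur,
                            stem_material=bone_like, cement=bone_like)
        res = solve_implanted(asm, LoadCase())
        intact = solve_intact(femur, LoadCase())
        denom = np.abs(intact.sigma) + 1e-300
        assert np.max(np.abs(res.bone.sigma - intact.sigma) / denom) < 1e-8

    def test_composite_circular_section_closed_form(self):
        asm = circular_assembly()
        femur = asm.femur
        M = 8.0e4
        res = solve_implanted(asm, [Load(0.0, femur.length, 0.0, 0.0, mx=M)],
                              grid=(20, 16), n_profile=1 << 16)
        i_bone = np.pi / 4 * (14.0 ** 4 - 10.0 ** 4)
        i_cem = np.pi / 4 * (10.0 ** 4 - 7.0 ** 4)
        i_stem = np.pi / 4 * 7.0 ** 4
        ei = 18.6e3 * i_bone + 2.28e3 * i_cem + 110.0e3 * i_stem
        expected = 18.6e3 * M * 14.0 / ei   # peak bone fiber stress
        in_span = res.bone.z >= asm.tip_z
        peak = res.bone.sigma[in_span].max(axis=1)
        assert np.allclose(peak, expected, rtol=1e-8)

    def test_stiff_stem_shields_throughout_span(self, mid_design):
        """Ti stem: every axial station in the implanted span is shielded
        (mean stress strictly reduced), and pointwise reduction holds away
        from the bending neutral axis (where the combined axial + bending
        zero crossing shifts slightly between the two models)."""
        femur = default_femur()
        asm = make_assembly(mid_design, femur=femur)
        res = solve_implanted(asm, LoadCase())
        intact = solve_intact(femur, LoadCase())
        in_span = res.bone.z >= asm.tip_z
        m_int = intact.sigma[in_span].mean(axis=1)
        m_imp = res.bone.sigma[in_span].mean(axis=1)
        assert np.all(m_imp < m_int)
        away = intact.sigma[in_span] > 0.1 * m_int[:, None]
        assert np.all(res.bone.sigma[in_span][away] <
                      intact.sigma[in_span][away])

    def test_increasing_stem_modulus_never_raises_bone_stress(self, mid_design):
        r1 = solve_implanted(make_assembly(mid_design,
                                           stem_material=Material("a", 60.0)),
                             LoadCase(), grid=(30, 16))
        r2 = solve_implanted(make_assembly(mid_design,
                                           stem_material=Material("b", 140.0)),
                             LoadCase(), grid=(30, 16))
        tip = make_assembly(mid_design).tip_z
        span = r1.bone.z >= tip
        assert np.all(r2.bone.sigma[span] <= r1.bone.sigma[span] + 1e-12)

    def test_equilibrium_resultants(self, mid_design):
        """Numerically integrate sigma over each section; must recover N, M."""
        asm = make_assembly(mid_design)
        loads = point_loads(LoadCase(), asm.femur.length)
        res = solve_implanted(asm, loads, grid=(12, 8))
        for k in range(res.z.size):
            z = res.z[k]
            acting = [ld for ld in loads if ld.z >= z]
            n_applied = sum(ld.fz for ld in acting)
            m_applied = sum(ld.mx + ld.y * ld.fz - (ld.z - z) * ld.fy
                            for ld in acting)
            n_back = m_back = 0.0
            for name in ("bone", "cement", "stem", "core"):
                e, a, i = res.parts[name]
                e_k = e[k] if np.ndim(e) else e
                # sigma = E (eps0 + kappa y): N = E(eps0 A), M = E(kappa I)
                # with all sections symmetric about the bending axis
                n_back += e_k * res.eps0[k] * a[k]
                m_back += e_k * res.kappa[k] * i[k]
            assert n_back == pytest.approx(n_applied, rel=1e-6)
            assert m_back == pytest.approx(m_applied, rel=1e-6)

    def test_cement_field_zero_to_peak_cycle(self, implanted_result):
        cem = implanted_result.cement
        assert cem.imax == 40 * 16
        assert np.allclose(cem.sigma_a, cem.sigma_m)
        assert np.all(cem.sigma_a >= 0.0)

    def test_fgm_stem_shields_less_than_titanium(self, mid_design, intact_field):
        ti = solve_implanted(make_assembly(mid_design), LoadCase())
        fgm = solve_implanted(
            make_assembly(mid_design, stem_material=default_fgm_layout()),
            LoadCase())
        span = ti.bone.z >= make_assembly(mid_design).tip_z
        assert np.mean(fgm.bone.sigma[span]) > np.mean(ti.bone.sigma[span])


class TestFieldIO:
    def test_surface_round_trip(self, tmp_path, intact_field):
        path = tmp_path / "surface.csv"
        export_stress_samples(intact_field, path)
        back = import_stress_field(path, kind="surface")
        assert back.aligned_with(intact_field)
        assert np.allclose(back.sigma, intact_field.sigma)

    def test_cement_round_trip(self, tmp_path, implanted_result):
        path = tmp_path / "cement.csv"
        export_cement_field(implanted_result.cement, path)
        back = import_stress_field(path, kind="cement")
        assert back.imax == implanted_result.cement.imax
        assert np.allclose(back.sigma_a, implanted_result.cement.sigma_a)

    def test_negative_stress_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("node_id,z_mm,angle_rad,sigma_a_MPa,sigma_m_MPa\n"
                        "0,10.0,0.0,-1.0,2.0\n")
        with pytest.raises(ParseError, match="negative"):
            import_stress_field(path, kind="cement")

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("node_id,z_mm,sigma_MPa\n0,10.0,1.0\n")
        with pytest.raises(ParseError, match="angle_rad"):
            import_stress_field(path, kind="surface")


class TestValidation:
    def test_femur_requires_outer_gt_canal(self):
        with pytest.raises(InvalidParameterError):
            make_surrogate_femur(outer_radius=7.0, canal_radius=7.0)

    def test_stress_samples_reject_negative(self):
        with pytest.raises(InvalidParameterError):
            StressSamples([0.0, 1.0], [0.0], [[1.0], [-0.5]])

    def test_cement_field_shape_checked(self):
        with pytest.raises(InvalidParameterError):
            CementStressField([0.0, 1.0], [0.0], [1.0, 2.0], [1.0, 2.0])
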